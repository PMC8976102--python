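"""Readers and writers for the plain-text formats the pipeline exchanges.

Reading of FASTA/FASTQ delegates to Biopython; the writers are simple
line-oriented emitters (FASTA, FASTQ, GFF3, PAF, TSV) so that outputs stay
byte-deterministic.
"""

from __future__ import annotations

import gzip
from typing import Iterable, Iterator


def _open(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path) -> list[tuple[str, str]]:
    from Bio import SeqIO

    with _open(path) as fh:
        return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(fh, "fasta")]


def iter_fastq_sequences(path) -> Iterator[str]:
    from Bio import SeqIO

    with _open(path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            yield str(rec.seq).upper()


def write_fasta(path, records: Iterable[tuple[str, str]], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gff3(path, rows: Iterable[tuple]) -> None:
    """Rows are (seqid, source, type, start_1based, end, score, strand,
    phase, attributes)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def write_paf(path, hits, query_lengths: dict[str, int],
              ref_lengths: dict[str, int]) -> None:
    """Minimal 12-column PAF (minimap2 dialect) from MappingHit records."""
    with open(path, "w") as fh:
        for h in hits:
            matches = int(round(h.identity * h.alignment_columns))
            fh.write("\t".join(map(str, [
                h.query_id, query_lengths[h.query_id], h.query_start, h.query_end,
                h.strand, h.ref_id, ref_lengths[h.ref_id], h.ref_start, h.ref_end,
                matches, h.alignment_columns, 255])) + "\n")


def write_tsv(path, header: list[str], rows: Iterable[Iterable]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def write_histogram_tsv(path, histogram: dict[int, int]) -> None:
    """jellyfish-histo dialect: 'depth<space>count' lines, depth ascending."""
    with open(path, "w") as fh:
        for depth in sorted(histogram):
            fh.write(f"{depth} {histogram[depth]}\n")


def read_histogram_tsv(path) -> dict[int, int]:
    hist: dict[int, int] = {}
    with _open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            d, c = line.split()
            hist[int(d)] = int(c)
    return hist
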