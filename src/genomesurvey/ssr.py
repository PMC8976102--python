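"""Microsatellite (SSR) detection with MISA-compatible semantics.

Perfect tandem runs of 1-6-base motifs are reported when they meet the
per-unit minimum repeat counts (default 12, 7, 5, 5, 5, 5 for mono- through
hexanucleotides).  Two SSRs separated by at most ``max_interrupt`` bases
merge into one compound record.  Motifs are grouped under a canonical form:
the lexicographic minimum over all rotations of the motif and of its
reverse complement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _seq
from .simulate import ParameterError

DEFAULT_THRESHOLDS = (12, 7, 5, 5, 5, 5)
DEFAULT_MAX_INTERRUPT = 100


@dataclass
class SSRRecord:
    seq_id: str
    motif: str               # canonical motif; '+'-joined motifs for compounds
    unit: int | None         # None for compound records
    repeats: int | None
    start: int               # 0-based half-open
    end: int
    cls: str = "perfect"     # 'perfect' | 'compound'
    members: list["SSRRecord"] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start


def canonical_motif(motif: str) -> str:
    rc = _seq.revcomp(motif)
    forms = [motif[i:] + motif[:i] for i in range(len(motif))]
    forms += [rc[i:] + rc[:i] for i in range(len(rc))]
    return min(forms)


def _is_subperiodic(motif: np.ndarray) -> bool:
    u = motif.size
    for p in range(1, u):
        if u % p == 0 and np.array_equal(motif, np.tile(motif[:p], u // p)):
            return True
    return False


def _perfect_runs(codes: np.ndarray, seq: str, seq_id: str,
                  thresholds) -> list[SSRRecord]:
    records: list[SSRRecord] = []
    n = codes.size
    ok = codes <= 3
    for u in range(1, 7):
        thr = thresholds[u - 1]
        if n < u * thr:
            continue
        eq = (codes[u:] == codes[:-u]) & ok[u:] & ok[:-u]
        padded = np.concatenate(([False], eq, [False]))
        edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
        for i, j in zip(edges[::2], edges[1::2]):
            m = j - i                       # matched positions; region m + u
            reps = (m + u) // u
            if reps < thr:
                continue
            motif = codes[i : i + u]
            if _is_subperiodic(motif):
                continue                    # reported at the shorter unit
            records.append(SSRRecord(
                seq_id=seq_id, motif=canonical_motif(seq[i : i + u]),
                unit=u, repeats=int(reps), start=int(i), end=int(i + reps * u)))
    records.sort(key=lambda r: (r.start, r.unit))
    # suppress a longer-unit run fully contained in a shorter-unit run
    kept: list[SSRRecord] = []
    for r in records:
        contained = any(o.start <= r.start and r.end <= o.end and o.unit < r.unit
                        for o in records if o is not r)
        if not contained:
            kept.append(r)
    return kept


def _merge_compound(records: list[SSRRecord], max_interrupt: int) -> list[SSRRecord]:
    if not records:
        return []
    out: list[SSRRecord] = []
    group = [records[0]]
    for r in records[1:]:
        if r.start - group[-1].end <= max_interrupt:
            group.append(r)
        else:
            out.append(_finalize(group))
            group = [r]
    out.append(_finalize(group))
    return out


def _finalize(group: list[SSRRecord]) -> SSRRecord:
    if len(group) == 1:
        return group[0]
    return SSRRecord(
        seq_id=group[0].seq_id,
        motif="+".join(g.motif for g in group),
        unit=None, repeats=None,
        start=group[0].start, end=max(g.end for g in group),
        cls="compound", members=list(group))


def find_ssrs(sequence: str, thresholds=DEFAULT_THRESHOLDS,
              max_interrupt: int = DEFAULT_MAX_INTERRUPT,
              seq_id: str = "seq") -> list[SSRRecord]:
    """Scan one sequence for perfect and compound SSRs, sorted by start.

    Non-ACGT stretches break runs.  ``max_interrupt=None`` disables
    compound merging and returns the perfect records only.
    """
    if len(thresholds) != 6 or any(t < 1 for t in thresholds):
        raise ParameterError("thresholds must be six positive repeat minima")
    codes = _seq.encode(sequence)
    perfect = _perfect_runs(codes, sequence.upper(), seq_id, thresholds)
    if max_interrupt is None:
        return perfect
    return _merge_compound(perfect, max_interrupt)


@dataclass
class SSRSummary:
    sequences_examined: int
    total_bases: int
    total_ssrs: int
    sequences_with_ssrs: int
    sequences_with_multiple: int
    compound_ssrs: int
    counts_per_unit: dict[int, int]

    def __post_init__(self):
        assert self.sequences_with_multiple <= self.sequences_with_ssrs \
            <= self.sequences_examined
        assert self.compound_ssrs <= self.total_ssrs

    def unit_fractions(self) -> dict[int, float]:
        if self.total_ssrs == 0:
            return {u: 0.0 for u in range(1, 7)}
        return {u: c / self.total_ssrs for u, c in self.counts_per_unit.items()}

    def to_rows(self) -> list[tuple[str, int]]:
        return [
            ("Total number of sequences examined", self.sequences_examined),
            ("Total size of examined sequences (bp)", self.total_bases),
            ("Total number of identified SSRs", self.total_ssrs),
            ("Number of SSR containing sequences", self.sequences_with_ssrs),
            ("Number of sequences containing more than one SSR",
             self.sequences_with_multiple),
            ("Number of SSRs present in compound formation", self.compound_ssrs),
        ]


def _flatten(records: list[SSRRecord]):
    for r in records:
        if r.cls == "compound":
            yield from r.members
        else:
            yield r


def summarize_ssrs(records_by_seq: dict[str, list[SSRRecord]],
                   sequences_examined: int | None = None,
                   total_bases: int = 0) -> SSRSummary:
    """Table-style summary.  Individual perfect SSRs inside compounds count
    toward the total; 'compound formation' counts those members."""
    n_seq = (sequences_examined if sequences_examined is not None
             else len(records_by_seq))
    total = 0
    compound = 0
    with_ssr = 0
    with_multi = 0
    per_unit = {u: 0 for u in range(1, 7)}
    for _sid, recs in records_by_seq.items():
        flat = list(_flatten(recs))
        total += len(flat)
        compound += sum(len(r.members) for r in recs if r.cls == "compound")
        if flat:
            with_ssr += 1
        if len(flat) > 1:
            with_multi += 1
        for r in flat:
            per_unit[r.unit] += 1
    return SSRSummary(sequences_examined=n_seq, total_bases=total_bases,
                      total_ssrs=total, sequences_with_ssrs=with_ssr,
                      sequences_with_multiple=with_multi,
                      compound_ssrs=compound, counts_per_unit=per_unit)


def scan_sequences(named_seqs, thresholds=DEFAULT_THRESHOLDS,
                   max_interrupt: int = DEFAULT_MAX_INTERRUPT
                   ) -> tuple[dict[str, list[SSRRecord]], SSRSummary]:
    """Scan (name, sequence) pairs; returns per-sequence records + summary."""
    by_seq = {}
    total_bases = 0
    for name, seq in named_seqs:
        by_seq[name] = find_ssrs(seq, thresholds, max_interrupt, seq_id=name)
        total_bases += len(seq)
    return by_seq, summarize_ssrs(by_seq, total_bases=total_bases)


def write_misa_tsv(path, records_by_seq: dict[str, list[SSRRecord]]) -> None:
    """MISA-dialect per-SSR table (1-based inclusive coordinates)."""
    from .io import write_tsv
    rows = []
    for sid, recs in records_by_seq.items():
        for nr, r in enumerate(recs, 1):
            if r.cls == "compound":
                ssr_type = "c"
                ssr = "".join(f"({m.motif}){m.repeats}" for m in r.members)
            else:
                ssr_type = f"p{r.unit}"
                ssr = f"({r.motif}){r.repeats}"
            rows.append((sid, nr, ssr_type, ssr, r.length, r.start + 1, r.end))
    write_tsv(path, ["ID", "SSR nr", "SSR type", "SSR", "size", "start", "end"],
              rows)
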