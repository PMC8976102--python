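"""Subtractive discovery of W-chromosome-specific markers.

The workflow mirrors the standard NGS approach for heterogametic-sex marker
discovery: map female reads to the male assembly, assemble the unmapped
remainder, drop short contigs (< 200 bp), drop contigs that still match the
male assembly, keep those that match the female assembly — then design PCR
primer pairs on the survivors and classify each pair by in-silico PCR
against both assemblies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from Bio.SeqUtils import MeltingTemp

from . import _seq
from .align import (DEFAULT_MIN_COV, DEFAULT_MIN_IDENTITY, MappingHit,
                    ReferenceIndex, build_index, classify_reads_mapped,
                    locate_primer, map_query)
from .assemble import Contig, assemble, filter_contigs
from .simulate import ParameterError, ReadSet

MIN_CONTIG_LENGTH = 200
DEFAULT_PRODUCT_WINDOW = (150, 700)
MAX_PRODUCT_SIZE = 2000


@dataclass
class CandidateFragment:
    """A contig absent from the male assembly but present in the female's."""

    contig: Contig
    male_hits: list[MappingHit]
    female_hits: list[MappingHit]
    stage_trace: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if any(h.mapped for h in self.male_hits):
            raise ValueError("candidate fragment has a mapped male hit")
        if not any(h.mapped for h in self.female_hits):
            raise ValueError("candidate fragment lacks a mapped female hit")
        if self.contig.length < MIN_CONTIG_LENGTH:
            raise ValueError("candidate fragment shorter than 200 bases")


def identify_w_candidates(female_reads: ReadSet, male_ref, female_ref,
                          k: int = 55, min_kmer_count: int = 2,
                          min_identity: float = DEFAULT_MIN_IDENTITY,
                          min_cov: float = DEFAULT_MIN_COV,
                          seed_length: int = 15
                          ) -> tuple[list[CandidateFragment], dict[str, int]]:
    """Run the subtractive pipeline; returns candidates plus the per-stage
    survivor counts (reads in, unmapped reads, contigs, length-filtered,
    male-excluded, female-matched)."""
    male_idx = male_ref if isinstance(male_ref, ReferenceIndex) \
        else build_index(male_ref, seed_length)
    female_idx = female_ref if isinstance(female_ref, ReferenceIndex) \
        else build_index(female_ref, seed_length)

    mat = female_reads.sequences()
    mapped = classify_reads_mapped(mat, male_idx, min_identity, min_cov)
    unmapped_seqs = [_seq.decode(mat[i]) for i in np.flatnonzero(~mapped)]
    trace = {"reads_total": int(mat.shape[0]),
             "reads_unmapped": len(unmapped_seqs)}

    contigs = assemble(unmapped_seqs, k=k, min_kmer_count=min_kmer_count)
    trace["contigs_assembled"] = len(contigs)
    contigs = filter_contigs(contigs, MIN_CONTIG_LENGTH)
    trace["contigs_length_filtered"] = len(contigs)

    survivors = []
    for c in contigs:
        mhits = map_query(c.sequence, male_idx, min_identity, min_cov,
                          query_id=c.id)
        if not any(h.mapped for h in mhits):
            survivors.append((c, mhits))
    trace["contigs_male_excluded"] = len(survivors)

    out = []
    for c, mhits in survivors:
        fhits = map_query(c.sequence, female_idx, min_identity, min_cov,
                          query_id=c.id)
        if any(h.mapped for h in fhits):
            out.append(CandidateFragment(c, mhits, fhits, dict(trace)))
    trace["candidates_female_mapped"] = len(out)
    for cand in out:
        cand.stage_trace = dict(trace)
    return out, trace


# ---------------------------------------------------------------------------
# primer design


@dataclass
class PrimerPair:
    name: str
    forward: str             # 5'->3' on the fragment's + strand
    reverse: str             # 5'->3' on the - strand
    tm_forward: float
    tm_reverse: float
    gc_forward: float
    gc_reverse: float
    product_size: int
    fragment_id: str
    forward_start: int       # 0-based on the fragment
    reverse_end: int         # 0-based exclusive: 5' end of reverse primer + 1
    penalty: float = 0.0

    def __post_init__(self):
        for p in (self.forward, self.reverse):
            if not 18 <= len(p) <= 27:
                raise ValueError("primer length out of [18, 27]")
        if self.product_size != self.reverse_end - self.forward_start:
            raise ValueError("product size inconsistent with coordinates")


@dataclass
class PrimerConstraints:
    length_range: tuple[int, int] = (18, 27)
    gc_range: tuple[float, float] = (0.40, 0.60)
    tm_range: tuple[float, float] = (57.0, 63.0)
    tm_optimal: float = 60.0
    length_optimal: int = 20
    max_tm_diff: float = 3.0
    max_homopolymer: int = 4
    max_3prime_gc_run: int = 3
    product_window: tuple[int, int] = DEFAULT_PRODUCT_WINDOW
    salt_mM: float = 50.0
    oligo_nM: float = 250.0


def primer_tm(seq: str, constraints: PrimerConstraints | None = None) -> float:
    """Nearest-neighbor (SantaLucia) melting temperature."""
    c = constraints or PrimerConstraints()
    return float(MeltingTemp.Tm_NN(seq, Na=c.salt_mM, dnac1=c.oligo_nM, dnac2=0))


def _max_run(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def _gc_run_3prime(seq: str) -> int:
    n = 0
    for ch in reversed(seq):
        if ch in "GC":
            n += 1
        else:
            break
    return n


def _admissible_windows(frag: str, c: PrimerConstraints) -> list[tuple[int, int, float, float]]:
    """(start, length, tm, gc) for windows passing single-primer constraints;
    the window sequence is frag[start:start+length] read 5'->3'."""
    out = []
    n = len(frag)
    for ln in range(c.length_range[0], c.length_range[1] + 1):
        for st in range(0, n - ln + 1):
            w = frag[st : st + ln]
            gc = (w.count("G") + w.count("C")) / ln
            if not c.gc_range[0] <= gc <= c.gc_range[1]:
                continue
            if _max_run(w) > c.max_homopolymer:
                continue
            if _gc_run_3prime(w) > c.max_3prime_gc_run:
                continue
            tm = primer_tm(w, c)
            if not c.tm_range[0] <= tm <= c.tm_range[1]:
                continue
            out.append((st, ln, tm, gc))
    return out


def design_primers(fragment, constraints: PrimerConstraints | None = None,
                   max_pairs: int = 20, name_prefix: str | None = None
                   ) -> list[PrimerPair]:
    """Enumerate admissible primer pairs on a candidate fragment, ranked by
    penalty (deviation from optimal Tm and length).

    The forward primer is a fragment window read 5'->3'; the reverse primer
    is the reverse complement of a downstream window.  Product size is the
    5'-to-5' span on the fragment.
    """
    if isinstance(fragment, CandidateFragment):
        frag = fragment.contig.sequence
        frag_id = fragment.contig.id
    elif isinstance(fragment, Contig):
        frag, frag_id = fragment.sequence, fragment.id
    else:
        frag, frag_id = str(fragment), name_prefix or "fragment"
    if len(frag) < 150:
        raise ParameterError("fragment must be at least 150 bases")
    c = constraints or PrimerConstraints()
    windows = _admissible_windows(frag, c)
    if not windows:
        return []
    # 3'-anchored reverse windows: reverse complement must itself pass
    rc_frag = _seq.revcomp(frag)
    n = len(frag)
    rev_windows = [(n - st - ln, ln, tm, gc)      # start on the + strand
                   for st, ln, tm, gc in _admissible_windows(rc_frag, c)]

    def pen(tm: float, ln: int) -> float:
        return abs(tm - c.tm_optimal) + 0.5 * abs(ln - c.length_optimal)

    pairs = []
    for fst, fln, ftm, fgc in windows:
        for rst, rln, rtm, rgc in rev_windows:
            size = rst + rln - fst
            if not c.product_window[0] <= size <= c.product_window[1]:
                continue
            if rst < fst + fln:       # overlapping primers
                continue
            if abs(ftm - rtm) > c.max_tm_diff:
                continue
            pairs.append((pen(ftm, fln) + pen(rtm, rln),
                          fst, fln, ftm, fgc, rst, rln, rtm, rgc, size))
    pairs.sort(key=lambda t: (t[0], t[1], t[5]))
    out = []
    prefix = name_prefix or frag_id
    for rank, (p, fst, fln, ftm, fgc, rst, rln, rtm, rgc, size) in \
            enumerate(pairs[:max_pairs], 1):
        fwd = frag[fst : fst + fln]
        rev = _seq.revcomp(frag[rst : rst + rln])
        out.append(PrimerPair(
            name=f"{prefix}_p{rank}", forward=fwd, reverse=rev,
            tm_forward=ftm, tm_reverse=rtm, gc_forward=fgc, gc_reverse=rgc,
            product_size=size, fragment_id=frag_id,
            forward_start=fst, reverse_end=rst + rln, penalty=p))
    return out


# ---------------------------------------------------------------------------
# in-silico PCR


FEMALE_SPECIFIC = "FEMALE_SPECIFIC"
BOTH_SEXES = "BOTH_SEXES"
MALE_ONLY = "MALE_ONLY"
ONE_SIDED_FEMALE = "ONE_SIDED_FEMALE"
NO_PRODUCT = "NO_PRODUCT"


@dataclass
class PcrClassification:
    category: str
    female_products: list[tuple[str, int, int]]   # (seq, start, size)
    male_products: list[tuple[str, int, int]]
    female_sites: int
    male_sites: int


def _products(fwd_sites, rev_sites, max_size: int):
    """Convergent forward/reverse placements on the same sequence within
    ``max_size``; product size is the outermost-coordinate span."""
    prods = []
    for f in fwd_sites:
        for r in rev_sites:
            if f.ref_id != r.ref_id or f.strand == r.strand:
                continue
            left, right = (f, r) if f.strand == "+" else (r, f)
            if left.start > right.start:
                continue
            size = right.end - left.start
            if size <= max_size:
                prods.append((f.ref_id, left.start, size))
    return prods


def classify_primer_pair(pair: PrimerPair, male_ref, female_ref,
                         max_product_size: int = MAX_PRODUCT_SIZE,
                         max_mismatches: int = 1) -> PcrClassification:
    """In-silico PCR of one primer pair against both assemblies.

    FEMALE_SPECIFIC requires a convergent product on the female assembly and
    *no placement of either primer* on the male assembly.  A female product
    with any male placement counts as BOTH_SEXES (the discard rule of the
    subtractive workflow).  ONE_SIDED_FEMALE marks product-less pairs with a
    female placement of only one side.
    """
    male_idx = male_ref if isinstance(male_ref, ReferenceIndex) \
        else build_index(male_ref)
    female_idx = female_ref if isinstance(female_ref, ReferenceIndex) \
        else build_index(female_ref)

    out = {}
    for label, idx in (("female", female_idx), ("male", male_idx)):
        f_sites = locate_primer(pair.forward, idx, max_mismatches)
        r_sites = locate_primer(pair.reverse, idx, max_mismatches)
        out[label] = (f_sites, r_sites,
                      _products(f_sites, r_sites, max_product_size))
    f_sites, r_sites, f_prods = out["female"]
    mf_sites, mr_sites, m_prods = out["male"]
    n_f = len(f_sites) + len(r_sites)
    n_m = len(mf_sites) + len(mr_sites)

    if f_prods and n_m == 0:
        cat = FEMALE_SPECIFIC
    elif f_prods and n_m > 0:
        cat = BOTH_SEXES
    elif m_prods:
        cat = MALE_ONLY
    elif (len(f_sites) > 0) != (len(r_sites) > 0):
        cat = ONE_SIDED_FEMALE
    else:
        cat = NO_PRODUCT
    return PcrClassification(category=cat, female_products=f_prods,
                             male_products=m_prods, female_sites=n_f,
                             male_sites=n_m)


# ---------------------------------------------------------------------------
# end-to-end


def run_sexmarker(female_reads: ReadSet, male_ref, female_ref,
                  n_candidates: int = 50, seed: int = 0,
                  constraints: PrimerConstraints | None = None,
                  outdir=None, **pipeline_kw) -> dict:
    """Full marker workflow: subtractive candidates -> sample up to
    ``n_candidates`` -> primer design -> in-silico PCR classification.

    Returns a JSON-serializable report; with ``outdir`` also writes
    candidate FASTA/BED, primer TSV and classification TSV.
    """
    male_idx = male_ref if isinstance(male_ref, ReferenceIndex) \
        else build_index(male_ref)
    female_idx = female_ref if isinstance(female_ref, ReferenceIndex) \
        else build_index(female_ref)
    candidates, trace = identify_w_candidates(
        female_reads, male_idx, female_idx, **pipeline_kw)

    rng = np.random.default_rng([seed, 3])
    if len(candidates) > n_candidates:
        pick = sorted(rng.choice(len(candidates), n_candidates, replace=False))
        sampled = [candidates[i] for i in pick]
    else:
        sampled = list(candidates)
    trace["candidates_sampled"] = len(sampled)

    primer_rows = []
    classifications = []
    for ci, cand in enumerate(sampled):
        if cand.contig.length < 150:
            continue
        pairs = design_primers(cand, constraints, max_pairs=3,
                               name_prefix=f"FM{ci+1}")
        for pair in pairs[:1]:        # one best pair per candidate
            cls = classify_primer_pair(pair, male_idx, female_idx)
            primer_rows.append(pair)
            classifications.append((pair, cls))

    cat_counts: dict[str, int] = {}
    for _p, cls in classifications:
        cat_counts[cls.category] = cat_counts.get(cls.category, 0) + 1

    report = {
        "seed": seed,
        "stage_trace": trace,
        "n_candidates": len(candidates),
        "n_primer_pairs": len(primer_rows),
        "classification_counts": cat_counts,
        "female_specific": [
            {"pair": p.name, "fragment": p.fragment_id,
             "forward": p.forward, "reverse": p.reverse,
             "product_size": p.product_size,
             "female_products": cls.female_products}
            for p, cls in classifications if cls.category == FEMALE_SPECIFIC],
        "pairs": [
            {"pair": p.name, "fragment": p.fragment_id,
             "forward": p.forward, "reverse": p.reverse,
             "tm_forward": round(p.tm_forward, 2),
             "tm_reverse": round(p.tm_reverse, 2),
             "product_size": p.product_size, "category": cls.category}
            for p, cls in classifications],
    }

    if outdir is not None:
        from pathlib import Path
        from .io import write_fasta, write_tsv
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(outdir / "candidates.fasta",
                    [(c.contig.id, c.contig.sequence) for c in candidates])
        with open(outdir / "candidates.bed", "w") as fh:
            for c in candidates:
                for h in c.female_hits:
                    if h.mapped:
                        fh.write(f"{h.ref_id}\t{h.ref_start}\t{h.ref_end}\t"
                                 f"{c.contig.id}\t{h.identity:.4f}\t{h.strand}\n")
        write_tsv(outdir / "primers.tsv",
                  ["name", "forward", "reverse", "tm_forward", "tm_reverse",
                   "gc_forward", "gc_reverse", "product_size", "fragment"],
                  [(p.name, p.forward, p.reverse, f"{p.tm_forward:.2f}",
                    f"{p.tm_reverse:.2f}", f"{100*p.gc_forward:.0f}",
                    f"{100*p.gc_reverse:.0f}", p.product_size, p.fragment_id)
                   for p in primer_rows])
        write_tsv(outdir / "classification.tsv",
                  ["name", "category", "female_products", "male_products"],
                  [(p.name, cls.category, len(cls.female_products),
                    len(cls.male_products)) for p, cls in classifications])
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
    return report
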