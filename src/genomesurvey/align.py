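"""Shared alignment machinery: canonical-seed reference index, seed-and-extend
read/contig mapping, strict primer placement, and affine-gap global alignment.

The mapper is deliberately simple — canonical s-mer seeds at every reference
position, diagonal clustering, then banded extension with Biopython's
PairwiseAligner — but its contracts (identity definition, mapped thresholds,
strand symmetry) are what the subtractive sex-marker pipeline depends on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import Align

from . import _seq
from .simulate import ParameterError

DEFAULT_SEED_LENGTH = 15
DEFAULT_MIN_IDENTITY = 0.90
DEFAULT_MIN_COV = 0.80

# scoring convention: a gap of length g costs open + (g-1)*extend
DEFAULT_SCORES = {"match": 1, "mismatch": -2, "gap_open": 4, "gap_extend": 1}


class StructuralError(ValueError):
    pass


@dataclass
class MappingHit:
    query_id: str
    ref_id: str
    query_start: int
    query_end: int
    ref_start: int
    ref_end: int
    strand: str
    identity: float
    alignment_columns: int
    mapped: bool

    def __post_init__(self):
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError("identity out of [0, 1]")


class ReferenceIndex:
    """Canonical s-mer index over a set of reference sequences.

    Seeds are stored as sorted packed codes with global positions, so seed
    lookup is a binary search and batch lookups vectorize.
    """

    def __init__(self, reference, seed_length: int = DEFAULT_SEED_LENGTH):
        if not 11 <= seed_length <= 31:
            raise ParameterError("seed_length must lie in [11, 31]")
        if isinstance(reference, dict):
            items = list(reference.items())
        else:
            items = list(reference)
        if not items:
            raise StructuralError("empty reference")
        self.s = seed_length
        self.names = [n for n, _ in items]
        self.seqs = {n: (s if isinstance(s, np.ndarray) else _seq.encode(s))
                     for n, s in items}
        self.lengths = {n: len(self.seqs[n]) for n in self.names}
        self.offsets = np.zeros(len(items) + 1, dtype=np.int64)
        for i, n in enumerate(self.names):
            self.offsets[i + 1] = self.offsets[i] + self.lengths[n]

        codes_parts, pos_parts, fwd_parts = [], [], []
        for i, n in enumerate(self.names):
            kc, valid = _seq.kmer_codes_1d(self.seqs[n], seed_length)
            rc = _seq.revcomp_kmer_codes(kc, seed_length)
            fwd = kc <= rc
            canon = np.minimum(kc, rc)
            pos = np.arange(kc.size, dtype=np.int64) + self.offsets[i]
            codes_parts.append(canon[valid])
            pos_parts.append(pos[valid])
            fwd_parts.append(fwd[valid])
        codes = np.concatenate(codes_parts)
        order = np.argsort(codes, kind="stable")
        self.sorted_codes = codes[order]
        self.sorted_gpos = np.concatenate(pos_parts)[order]
        self.sorted_fwd = np.concatenate(fwd_parts)[order]

    def seq_of_gpos(self, gpos: int) -> int:
        return int(np.searchsorted(self.offsets, gpos, side="right") - 1)

    def lookup(self, canon_code: int):
        """All (global position, is_forward) entries for a canonical seed."""
        lo = int(np.searchsorted(self.sorted_codes, canon_code, side="left"))
        hi = int(np.searchsorted(self.sorted_codes, canon_code, side="right"))
        return self.sorted_gpos[lo:hi], self.sorted_fwd[lo:hi]


def build_index(reference, seed_length: int = DEFAULT_SEED_LENGTH) -> ReferenceIndex:
    return ReferenceIndex(reference, seed_length)


def _make_aligner(scores=None, semiglobal: bool = False) -> Align.PairwiseAligner:
    sc = dict(DEFAULT_SCORES)
    if scores:
        sc.update(scores)
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = sc["match"]
    al.mismatch_score = sc["mismatch"]
    al.open_gap_score = -sc["gap_open"]
    al.extend_gap_score = -sc["gap_extend"]
    if semiglobal:
        # the query floats inside the longer reference window: terminal
        # query-row gaps (deletions relative to the target) are free
        try:
            al.open_end_deletion_score = 0
            al.extend_end_deletion_score = 0
        except AttributeError:  # Biopython < 1.86 naming
            al.query_end_open_gap_score = 0
            al.query_end_extend_gap_score = 0
    return al


@dataclass
class GlobalAlignment:
    score: float
    identity: float
    aligned_a: str
    aligned_b: str
    matches: int
    columns: int


def global_align(a: str, b: str, scores: dict | None = None) -> GlobalAlignment:
    """Optimal global alignment under affine gap scoring.

    Identity = matches / alignment columns (end gaps included).
    """
    if not a or not b:
        raise ParameterError("global_align requires nonempty sequences")
    al = _make_aligner(scores)
    aln = al.align(a, b)[0]
    sa, sb = str(aln[0]), str(aln[1])
    matches = sum(1 for x, y in zip(sa, sb) if x == y and x != "-")
    cols = len(sa)
    return GlobalAlignment(score=float(aln.score), identity=matches / cols,
                           aligned_a=sa, aligned_b=sb, matches=matches,
                           columns=cols)


def _aligned_stats(aln) -> tuple[int, int, int, int, int, int]:
    """(matches, columns, tstart, tend, qstart, qend) over the aligned core
    of a semi-global alignment (terminal target-only gaps trimmed)."""
    tblocks, qblocks = aln.aligned
    if len(tblocks) == 0:
        return 0, 1, 0, 0, 0, 0
    t = str(aln.target)
    q = str(aln.query)
    matches = 0
    cols = 0
    prev_t = prev_q = None
    for (ts, te), (qs, qe) in zip(tblocks, qblocks):
        if prev_t is not None:
            cols += max(ts - prev_t, qs - prev_q)
        seg_t = t[ts:te]
        seg_q = q[qs:qe]
        matches += sum(1 for x, y in zip(seg_t, seg_q) if x == y)
        cols += te - ts
        prev_t, prev_q = te, qe
    tstart, tend = int(tblocks[0][0]), int(tblocks[-1][1])
    qstart, qend = int(qblocks[0][0]), int(qblocks[-1][1])
    return matches, cols, tstart, tend, qstart, qend


def _cluster_diagonals(diags: np.ndarray, band: int = 24):
    """Group sorted diagonal values into clusters within ``band``; returns
    list of (votes, dmin, dmax) sorted by votes desc then dmin."""
    diags = np.sort(diags)
    clusters = []
    start = 0
    for i in range(1, diags.size + 1):
        if i == diags.size or diags[i] - diags[i - 1] > band:
            clusters.append((i - start, int(diags[start]), int(diags[i - 1])))
            start = i
    clusters.sort(key=lambda c: (-c[0], c[1]))
    return clusters


def _map_oriented(qcodes: np.ndarray, index: ReferenceIndex, query_id: str,
                  strand: str, n_query: int, min_identity: float,
                  min_cov: float, aligner, max_chains: int) -> list[MappingHit]:
    s = index.s
    n = qcodes.size
    if n < s:
        return []
    offs = list(range(0, n - s + 1, s))
    if offs[-1] != n - s:
        offs.append(n - s)
    kc, valid = _seq.kmer_codes_1d(qcodes, s)
    hits_diag = []
    for off in offs:
        if not valid[off]:
            continue
        code = kc[off]
        rc = _seq.revcomp_kmer_codes(np.array([code], dtype=np.uint64), s)[0]
        canon = min(int(code), int(rc))
        q_fwd = code <= rc
        gpos, ref_fwd = index.lookup(canon)
        same = ref_fwd == q_fwd
        for g in gpos[same]:
            hits_diag.append(int(g) - off)
    if not hits_diag:
        return []

    out = []
    pad = 24
    for votes, dmin, dmax in _cluster_diagonals(np.array(hits_diag))[:max_chains]:
        si = index.seq_of_gpos(min(max(dmin, 0), index.offsets[-1] - 1))
        seq_name = index.names[si]
        base = int(index.offsets[si])
        seq = index.seqs[seq_name]
        wlo = max(0, dmin - pad - base)
        whi = min(len(seq), dmax + n + pad - base)
        if whi - wlo < s:
            continue
        window = seq[wlo:whi]
        # fast path: single diagonal, exact window match
        if dmin == dmax:
            rst = dmin - base
            if 0 <= rst and rst + n <= len(seq) and np.array_equal(seq[rst:rst + n], qcodes):
                qs_, qe_ = 0, n
                if strand == "-":
                    qs_, qe_ = 0, n
                out.append(MappingHit(query_id, seq_name, qs_, qe_, rst, rst + n,
                                      strand, 1.0, n, True))
                continue
        aln = aligner.align(_seq.decode(window), _seq.decode(qcodes))[0]
        matches, cols, ts, te, qs_, qe_ = _aligned_stats(aln)
        if cols <= 0 or te <= ts:
            continue
        identity = matches / cols
        if strand == "-":
            qs_, qe_ = n - qe_, n - qs_
        mapped = identity >= min_identity and (qe_ - qs_) / n >= min_cov
        out.append(MappingHit(query_id, seq_name, qs_, qe_, wlo + ts, wlo + te,
                              strand, identity, cols, mapped))
    return out


def map_query(query: str | np.ndarray, index: ReferenceIndex,
              min_identity: float = DEFAULT_MIN_IDENTITY,
              min_cov: float = DEFAULT_MIN_COV,
              query_id: str = "query", scores: dict | None = None,
              max_chains: int = 4) -> list[MappingHit]:
    """Seed-and-extend mapping of one query against the index.

    Returns hits sorted by identity (desc); an unmapped query returns an
    empty list or hits with ``mapped=False`` only.
    """
    qcodes = _seq.encode(query) if isinstance(query, str) else query
    if qcodes.size < index.s:
        return []
    aligner = _make_aligner(scores, semiglobal=True)
    hits = _map_oriented(qcodes, index, query_id, "+", qcodes.size,
                         min_identity, min_cov, aligner, max_chains)
    hits += _map_oriented(_seq.revcomp_codes(qcodes), index, query_id, "-",
                          qcodes.size, min_identity, min_cov, aligner, max_chains)
    hits.sort(key=lambda h: (-h.identity, h.ref_id, h.ref_start, h.strand))
    return hits


def is_mapped(query, index: ReferenceIndex, **kw) -> bool:
    return any(h.mapped for h in map_query(query, index, **kw))


def classify_reads_mapped(mat: np.ndarray, index: ReferenceIndex,
                          min_identity: float = DEFAULT_MIN_IDENTITY,
                          min_cov: float = DEFAULT_MIN_COV) -> np.ndarray:
    """Vectorized mapped/unmapped classification of a (reads x L) code matrix.

    Stage 1 batch-looks-up a handful of seeds per read; reads with zero seed
    hits are unmapped outright.  Stage 2 verifies candidates by direct window
    comparison (exact matches) and falls back to full seed-and-extend mapping
    only where needed.
    """
    n_reads, L = mat.shape
    s = index.s
    offs = list(range(0, L - s + 1, s))
    if offs[-1] != L - s:
        offs.append(L - s)
    kc = _seq.kmer_codes_2d(mat, s)
    seeds = kc[:, offs]                       # (reads x nseeds)
    canon = _seq.canonical_kmer_codes(seeds.ravel(), s).reshape(seeds.shape)
    lo = np.searchsorted(index.sorted_codes, canon)
    hi = np.searchsorted(index.sorted_codes, canon, side="right")
    nhits = hi - lo
    any_hit = nhits.any(axis=1)

    mapped = np.zeros(n_reads, dtype=bool)
    cand = np.flatnonzero(any_hit)
    max_mm = int(np.floor((1.0 - min_identity) * L))
    for i in cand:
        row = mat[i]
        row_rc = None
        done = False
        # gapless-placement fast path: a diagonal placement within the
        # mismatch budget is an optimal alignment for substitution-only reads
        for j, off in enumerate(offs):
            if nhits[i, j] == 0 or nhits[i, j] > 50:
                continue
            code = seeds[i, j]
            rc = _seq.revcomp_kmer_codes(np.array([code], dtype=np.uint64), s)[0]
            q_fwd = code <= rc
            for t in range(lo[i, j], hi[i, j]):
                g = int(index.sorted_gpos[t])
                si = index.seq_of_gpos(g)
                seq = index.seqs[index.names[si]]
                base = int(index.offsets[si])
                if index.sorted_fwd[t] == q_fwd:
                    st = g - base - off
                    probe = row
                else:
                    st = g - base - (L - s - off)
                    if row_rc is None:
                        row_rc = _seq.revcomp_codes(row)
                    probe = row_rc
                if 0 <= st and st + L <= len(seq) and \
                        int(np.count_nonzero(seq[st:st + L] != probe)) <= max_mm:
                    mapped[i] = True
                    done = True
                    break
            if done:
                break
        if not done:
            mapped[i] = is_mapped(row, index, min_identity=min_identity,
                                  min_cov=min_cov)
    return mapped


# ---------------------------------------------------------------------------
# strict primer placement (in-silico PCR chemistry)


@dataclass
class PrimerSite:
    ref_id: str
    start: int          # 0-based position of the primer's 5' end on + strand
    end: int
    strand: str         # '+': primer anneals to - strand, extends rightward
    mismatches: int


def locate_primer(primer: str, index: ReferenceIndex,
                  max_mismatches: int = 1, exact_3prime: int = 5) -> list[PrimerSite]:
    """Full-length, indel-free primer placements with at most
    ``max_mismatches`` mismatches and an exact 3'-terminal ``exact_3prime``
    bases, on both strands of every reference sequence."""
    p = _seq.encode(primer)
    Lp = p.size
    sites = []
    for name in index.names:
        seq = index.seqs[name]
        if len(seq) < Lp:
            continue
        win = np.lib.stride_tricks.sliding_window_view(seq, Lp)
        # forward placement: primer equals the + strand, extends 3'-rightward
        mm = (win != p).sum(axis=1)
        for pos in np.flatnonzero(mm <= max_mismatches):
            if (win[pos, -exact_3prime:] == p[-exact_3prime:]).all():
                sites.append(PrimerSite(name, int(pos), int(pos) + Lp, "+",
                                        int(mm[pos])))
        # reverse placement: primer equals the - strand (revcomp on +)
        prc = _seq.revcomp_codes(p)
        mm = (win != prc).sum(axis=1)
        for pos in np.flatnonzero(mm <= max_mismatches):
            if (win[pos, :exact_3prime] == prc[:exact_3prime]).all():
                sites.append(PrimerSite(name, int(pos), int(pos) + Lp, "-",
                                        int(mm[pos])))
    return sites
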