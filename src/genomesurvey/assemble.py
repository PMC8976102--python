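"""Desk-scale De Bruijn graph assembly of read subsets, plus assembly
statistics (contig count, total bases, N50, GC).

The assembler builds a canonical k-mer graph from k-mers seen at least
``min_kmer_count`` times, clips short dead-end tips, and emits maximal
non-branching paths (unitigs).  It is meant for the small read subsets the
subtractive sex-marker pipeline produces (unmapped reads), not whole-genome
assembly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _seq
from .align import StructuralError
from .simulate import ParameterError, ReadSet

_COMP = str.maketrans("ACGT", "TGCA")


def _rc(s: str) -> str:
    return s.translate(_COMP)[::-1]


def _canon(s: str) -> str:
    r = _rc(s)
    return s if s <= r else r


@dataclass
class Contig:
    id: str
    sequence: str
    coverage: float

    @property
    def length(self) -> int:
        return len(self.sequence)

    def __post_init__(self):
        if self.coverage <= 0:
            raise ValueError("contig coverage must be positive")


@dataclass
class AssemblyStats:
    contig_count: int
    total_bases: int
    n50: int
    gc_percent: float
    min_length: int
    max_length: int

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def _count_kmer_strings(seqs, k: int) -> dict[str, int]:
    counts: dict[str, int] = {}
    for s in seqs:
        if len(s) < k:
            continue
        r = _rc(s)
        L = len(s)
        for i in range(L - k + 1):
            km = s[i : i + k]
            if "N" in km:
                continue
            rkm = r[L - i - k : L - i]
            key = km if km <= rkm else rkm
            counts[key] = counts.get(key, 0) + 1
    return counts


class _Graph:
    """Canonical k-mer set with oriented-extension queries."""

    def __init__(self, kmers: dict[str, int], k: int):
        self.counts = kmers
        self.k = k

    def has(self, km: str) -> bool:
        return _canon(km) in self.counts

    def fwd(self, km: str) -> list[str]:
        suf = km[1:]
        return [suf + b for b in "ACGT" if _canon(suf + b) in self.counts]

    def bwd(self, km: str) -> list[str]:
        pre = km[:-1]
        return [b + pre for b in "ACGT" if _canon(b + pre) in self.counts]


def _unitigs(graph: _Graph) -> list[tuple[str, float]]:
    """Maximal non-branching paths over the canonical k-mer set."""
    k = graph.k
    visited: set[str] = set()
    out: list[tuple[str, float]] = []

    def walk(start: str) -> tuple[str, list[str]]:
        path = [start]
        seen = {_canon(start)}
        cur = start
        while True:
            nxt = graph.fwd(cur)
            if len(nxt) != 1:
                break
            nx = nxt[0]
            if len(graph.bwd(nx)) != 1:
                break
            if _canon(nx) in seen:
                break  # cycle
            path.append(nx)
            seen.add(_canon(nx))
            cur = nx
        seq = path[0] + "".join(p[-1] for p in path[1:])
        return seq, path

    # starts: oriented k-mers whose backward extension is not a simple chain
    starts = []
    for cj in graph.counts:
        for km in (cj, _rc(cj)):
            b = graph.bwd(km)
            if len(b) != 1 or len(graph.fwd(b[0])) != 1:
                starts.append(km)
    for km in sorted(starts):
        if _canon(km) in visited:
            continue
        seq, path = walk(km)
        canons = {_canon(p) for p in path}
        if canons & visited:
            continue
        visited |= canons
        cov = float(np.mean([graph.counts[_canon(p)] for p in path]))
        out.append((seq, cov))

    # isolated perfect cycles: everything not yet visited
    for cj in sorted(graph.counts):
        if cj in visited:
            continue
        seq, path = walk(cj)
        canons = {_canon(p) for p in path}
        visited |= canons
        cov = float(np.mean([graph.counts[_canon(p)] for p in path]))
        out.append((seq, cov))
    return out


def _clip_tips(graph: _Graph, unitig_list, max_tip_len: int) -> bool:
    """Remove short dead-end unitigs whose attached end joins a junction."""
    removed = False
    for seq, _cov in unitig_list:
        if len(seq) >= max_tip_len:
            continue
        k = graph.k
        first, last = seq[:k], seq[-k:]
        dead_start = len(graph.bwd(first)) == 0
        dead_end = len(graph.fwd(last)) == 0
        if dead_start == dead_end:    # keep islands and through-paths
            continue
        junction = graph.fwd(last) if dead_start else graph.bwd(first)
        branchy = any(len(graph.bwd(j)) > 1 or len(graph.fwd(j)) > 1
                      for j in junction)
        if not branchy:
            continue
        for i in range(len(seq) - k + 1):
            graph.counts.pop(_canon(seq[i : i + k]), None)
        removed = True
    return removed


def assemble(reads, k: int = 55, min_kmer_count: int = 2) -> list[Contig]:
    """Assemble reads into unitig contigs.

    ``reads`` may be a ReadSet or an iterable of sequence strings.  Contigs
    are emitted in canonical orientation, sorted by length (desc) then
    sequence, so output is deterministic.
    """
    if k % 2 == 0 or not 21 <= k <= 63:
        raise ParameterError("k must be odd and lie in [21, 63]")
    if isinstance(reads, ReadSet):
        seqs = [_seq.decode(row) for row in reads.sequences()]
    else:
        seqs = list(reads)
    if not seqs:
        return []
    counts = {km: c for km, c in _count_kmer_strings(seqs, k).items()
              if c >= min_kmer_count}
    if not counts:
        return []
    graph = _Graph(counts, k)
    for _round in range(4):
        unis = _unitigs(graph)
        if not _clip_tips(graph, unis, 2 * k):
            break
    unis = _unitigs(graph)
    unis = [( _canon_seq(s), c) for s, c in unis]
    unis.sort(key=lambda u: (-len(u[0]), u[0]))
    return [Contig(id=f"contig_{i+1}", sequence=s, coverage=c)
            for i, (s, c) in enumerate(unis)]


def _canon_seq(s: str) -> str:
    r = _rc(s)
    return s if s <= r else r


def filter_contigs(contigs: list[Contig], min_length: int = 200) -> list[Contig]:
    """Keep contigs with length >= min_length, order preserved."""
    if min_length < 0:
        raise ParameterError("min_length must be >= 0")
    return [c for c in contigs if c.length >= min_length]


def assembly_stats(contigs) -> AssemblyStats:
    """Contig count, total bases, N50 and GC percent.

    ``contigs`` may be Contig records or plain sequence strings.  N50 is the
    length at which the cumulative length of descending-sorted contigs first
    reaches half the total.
    """
    seqs = [c.sequence if isinstance(c, Contig) else str(c) for c in contigs]
    if not seqs:
        raise StructuralError("assembly_stats requires at least one contig")
    lengths = sorted((len(s) for s in seqs), reverse=True)
    total = sum(lengths)
    acc = 0
    n50 = lengths[-1]
    for L in lengths:
        acc += L
        if acc * 2 >= total:
            n50 = L
            break
    counts = {b: 0 for b in "ACGT"}
    for s in seqs:
        for b in "ACGT":
            counts[b] += s.count(b)
    acgt = sum(counts.values())
    gc = 100.0 * (counts["G"] + counts["C"]) / acgt if acgt else 0.0
    return AssemblyStats(contig_count=len(seqs), total_bases=total, n50=n50,
                         gc_percent=gc, min_length=lengths[-1],
                         max_length=lengths[0])
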