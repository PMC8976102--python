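"""Mitogenome comparison from first principles: ANI matrix, progressive
multiple alignment, p-distances, neighbor-joining and bootstrap supports.

The aligner is a banded progressive profile aligner — adequate for the
high-identity (>90%) regime of congeneric mitogenomes, and checked through
its invariants (degap round trip, planted-indel placement) rather than
against any particular external aligner's output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _seq
from .align import StructuralError, global_align
from .tree import PhyloTree, TreeNode

GAP = 4  # code for '-' in alignment matrices


class DistanceError(RuntimeError):
    """A pairwise distance is undefined (no shared ungapped column)."""


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise StructuralError("distance matrix shape mismatch")
        if not np.allclose(v, v.T, atol=1e-12):
            raise StructuralError("distance matrix must be symmetric")
        if np.abs(np.diag(v)).max(initial=0.0) > 1e-12:
            raise StructuralError("distance matrix diagonal must be zero")
        if (v < -1e-12).any():
            raise StructuralError("distances must be nonnegative")
        self.values = v

    def to_tsv(self, path) -> None:
        from .io import write_tsv
        rows = [[lab] + [f"{x:.6g}" for x in row]
                for lab, row in zip(self.labels, self.values)]
        write_tsv(path, ["taxon"] + self.labels, rows)


# ---------------------------------------------------------------------------
# ANI


def ani_matrix(named_seqs) -> tuple[list[str], np.ndarray]:
    """Pairwise average nucleotide identity (percent) from full-length
    global alignments; gap columns count in the denominator."""
    items = list(named_seqs)
    if len(items) < 2:
        raise StructuralError("ani_matrix requires at least 2 sequences")
    labels = [n for n, _ in items]
    n = len(items)
    ani = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            ga = global_align(items[i][1], items[j][1])
            ani[i, j] = ani[j, i] = 100.0 * ga.identity
    return labels, ani


# ---------------------------------------------------------------------------
# multiple sequence alignment


class Msa:
    """Aligned rows: (taxa x columns) uint8 matrix with GAP=4."""

    def __init__(self, labels: list[str], matrix: np.ndarray):
        self.labels = labels
        self.matrix = matrix

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    def row(self, label: str) -> str:
        i = self.labels.index(label)
        out = np.full(self.n_columns, ord("-"), dtype=np.uint8)
        r = self.matrix[i]
        ok = r != GAP
        out[ok] = np.frombuffer(b"ACGT", dtype=np.uint8)[r[ok]]
        return out.tobytes().decode()

    def degapped_row(self, label: str) -> str:
        i = self.labels.index(label)
        r = self.matrix[i]
        return _seq.decode(r[r != GAP])

    def to_fasta(self, path) -> None:
        from .io import write_fasta
        write_fasta(path, [(l, self.row(l)) for l in self.labels])


def _profile(mat: np.ndarray) -> np.ndarray:
    """(columns x 5) frequency profile of an alignment block."""
    prof = np.zeros((mat.shape[1], 5), dtype=np.float32)
    for s in range(5):
        prof[:, s] = (mat == s).mean(axis=0)
    return prof


# substitution scores between symbols (gap column chars score 0)
_SUBS = np.full((5, 5), -1.0, dtype=np.float32)
np.fill_diagonal(_SUBS, 2.0)
_SUBS[4, :] = 0.0
_SUBS[:, 4] = 0.0
_GAP_PEN = -3.0


def _align_profiles(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Banded global DP between two alignment blocks; returns the two
    gap-insertion index lists (columns of new gaps in a and in b)."""
    pa, pb = _profile(a), _profile(b)
    na, nb = pa.shape[0], pb.shape[0]
    w = max(60, abs(na - nb) + 40, int(0.02 * max(na, nb)))
    NEG = -1e9

    # score[i, j] over band |j - i*nb/na| <= w ; store rows as offset windows
    lo = np.zeros(na + 1, dtype=np.int64)
    hi = np.zeros(na + 1, dtype=np.int64)
    for i in range(na + 1):
        c = int(round(i * nb / max(na, 1)))
        lo[i] = max(0, c - w)
        hi[i] = min(nb, c + w)
    prev = np.full(nb + 1, NEG)
    prev[lo[0] : hi[0] + 1] = np.arange(lo[0], hi[0] + 1) * _GAP_PEN
    bw = int((hi - lo).max()) + 1
    ptr = np.zeros((na + 1, bw), dtype=np.uint8)  # 0 diag, 1 up(a), 2 left(b)
    ptr[0, :] = 2
    sa = pa @ _SUBS  # (na x 5)
    for i in range(1, na + 1):
        cur = np.full(nb + 1, NEG)
        l, h = lo[i], hi[i]
        js = np.arange(l, h + 1)
        # score of aligning a's column i-1 with b's columns js-1
        col_scores = np.full(js.size, NEG)
        nz = js > 0
        if nz.any():
            col_scores[nz] = sa[i - 1] @ pb[js[nz] - 1].T
        diag = np.full(js.size, NEG)
        dvalid = nz & (js - 1 >= lo[i - 1]) & (js - 1 <= hi[i - 1])
        diag[dvalid] = prev[js[dvalid] - 1] + col_scores[dvalid]
        up = np.full(js.size, NEG)
        uvalid = (js >= lo[i - 1]) & (js <= hi[i - 1])
        up[uvalid] = prev[js[uvalid]] + _GAP_PEN
        seg = np.maximum(diag, up)
        p_seg = np.where(diag >= up, 0, 1).astype(np.uint8)
        # left moves are a prefix-max chain: cur[j] = max over j' <= j of
        # seg[j'] + (j - j') * gap, computed via maximum.accumulate
        off = js * (-_GAP_PEN)
        adjusted = seg + off
        m = np.maximum.accumulate(adjusted)
        cur_seg = m - off
        left_better = m > adjusted
        p_seg[left_better] = 2
        cur[l : h + 1] = cur_seg
        ptr[i, : h + 1 - l] = p_seg
        prev = cur
    # traceback
    i, j = na, nb
    gaps_a, gaps_b = [], []
    while i > 0 or j > 0:
        p = ptr[i, j - lo[i]]
        if i > 0 and j > 0 and p == 0:
            i -= 1
            j -= 1
        elif i > 0 and p == 1:
            gaps_b.append(j)
            i -= 1
        else:
            gaps_a.append(i)
            j -= 1
    return np.array(gaps_a[::-1], dtype=np.int64), np.array(gaps_b[::-1], dtype=np.int64)


def _insert_gaps(mat: np.ndarray, positions: np.ndarray) -> np.ndarray:
    if positions.size == 0:
        return mat
    n, m = mat.shape
    out = np.full((n, m + positions.size), GAP, dtype=np.uint8)
    keep = np.ones(m + positions.size, dtype=bool)
    idx = positions + np.arange(positions.size)
    keep[idx] = False
    out[:, keep] = mat
    return out


def _kmer_profile_distance(seqs: list[np.ndarray], k: int = 8) -> np.ndarray:
    """Jaccard-style k-mer set distance used only for the guide tree."""
    sets = []
    for s in seqs:
        kc, valid = _seq.kmer_codes_1d(s, k)
        sets.append(np.unique(_seq.canonical_kmer_codes(kc[valid], k)))
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            inter = np.intersect1d(sets[i], sets[j], assume_unique=True).size
            union = sets[i].size + sets[j].size - inter
            d[i, j] = d[j, i] = 1.0 - (inter / union if union else 0.0)
    return d


def progressive_msa(named_seqs) -> Msa:
    """Progressive alignment along an NJ guide tree built from k-mer
    distances; profiles merge leaf-to-root.  Removing gaps from any output
    row reproduces the corresponding input sequence exactly."""
    items = [(n, _seq.encode(s) if isinstance(s, str) else s)
             for n, s in named_seqs]
    if len(items) < 2:
        raise StructuralError("progressive_msa requires at least 2 sequences")
    labels = [n for n, _ in items]
    seqs = [s for _, s in items]
    if len(items) == 2:
        order_children = [TreeNode(name=labels[0]), TreeNode(name=labels[1])]
        guide = PhyloTree(TreeNode(children=order_children))
    else:
        d = _kmer_profile_distance(seqs)
        guide = nj_tree(DistanceMatrix(labels, d))
    idx = {l: i for i, l in enumerate(labels)}

    def merge(node: TreeNode) -> tuple[list[str], np.ndarray]:
        if node.is_leaf:
            return [node.name], seqs[idx[node.name]][None, :].copy()
        blocks = [merge(c) for c in node.children]
        cur_labels, cur_mat = blocks[0]
        for nxt_labels, nxt_mat in blocks[1:]:
            ga, gb = _align_profiles(cur_mat, nxt_mat)
            cur_mat = _insert_gaps(cur_mat, ga)
            nxt_mat = _insert_gaps(nxt_mat, gb)
            cur_mat = np.vstack([cur_mat, nxt_mat])
            cur_labels = cur_labels + nxt_labels
        return cur_labels, cur_mat

    out_labels, mat = merge(guide.root)
    order = [out_labels.index(l) for l in labels]
    return Msa(labels, mat[order])


# ---------------------------------------------------------------------------
# distances and trees


def p_distance(msa: Msa) -> DistanceMatrix:
    """Pairwise mismatches / shared ungapped columns."""
    mat = msa.matrix
    n = mat.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = (mat[i] != GAP) & (mat[j] != GAP)
            ns = int(shared.sum())
            if ns == 0:
                raise DistanceError(
                    f"no shared ungapped column between {msa.labels[i]} "
                    f"and {msa.labels[j]}")
            mm = int((mat[i][shared] != mat[j][shared]).sum())
            d[i, j] = d[j, i] = mm / ns
    return DistanceMatrix(msa.labels, d)


def jukes_cantor(d: DistanceMatrix) -> DistanceMatrix:
    """Jukes-Cantor correction of p-distances."""
    p = np.clip(d.values, 0.0, 0.7499)
    jc = -0.75 * np.log1p(-4.0 * p / 3.0)
    np.fill_diagonal(jc, 0.0)
    return DistanceMatrix(d.labels, jc)


def nj_tree(d: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining.

    Negative branch lengths are clamped to zero with the excess shifted to
    the sibling edge; the unrooted result is returned with a trifurcating
    root (bifurcating for the final pair when only two nodes remain).
    """
    n = len(d.labels)
    if n < 3:
        raise StructuralError("nj_tree requires at least 3 taxa")
    D = d.values.copy()
    nodes: list[TreeNode] = [TreeNode(name=l) for l in d.labels]
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        ai, aj = np.unravel_index(np.argmin(q), q.shape)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        li = 0.5 * sub[ai, aj] + (r[ai] - r[aj]) / (2 * (m - 2))
        lj = sub[ai, aj] - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        nodes[i].length = float(max(li, 0.0))
        nodes[j].length = float(max(lj, 0.0))
        parent = TreeNode(children=[nodes[i], nodes[j]])
        newd = 0.5 * (D[i, active] + D[j, active] - D[i, j])
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, : len(nodes)] = 0.0
        for ak, kk in enumerate(active):
            D[-1, kk] = D[kk, -1] = newd[ak]
        D[-1, -1] = 0.0
        nodes.append(parent)
        active = [x for x in active if x not in (i, j)] + [len(nodes) - 1]
    # resolve the last three nodes around a trifurcating root
    a, b, c = active
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    for x, lx in zip((a, b, c), (la, lb, lc)):
        nodes[x].length = float(max(lx, 0.0))
    root = TreeNode(children=[nodes[a], nodes[b], nodes[c]])
    return PhyloTree(root)


def bootstrap_supports(msa: Msa, replicates: int = 1000,
                       seed: int = 0) -> PhyloTree:
    """NJ tree from the full alignment with bootstrap supports: percentage
    of column-resampled replicates whose NJ tree contains each split."""
    if replicates < 1:
        raise StructuralError("replicates must be >= 1")
    full = nj_tree(p_distance(msa))
    mat = msa.matrix
    n, ncol = mat.shape
    # per-pair column-wise mismatch / shared masks, for fast resampled distances
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    shared = np.zeros((len(pairs), ncol), dtype=bool)
    mism = np.zeros((len(pairs), ncol), dtype=bool)
    for t, (i, j) in enumerate(pairs):
        sh = (mat[i] != GAP) & (mat[j] != GAP)
        shared[t] = sh
        mism[t] = sh & (mat[i] != mat[j])
    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {sp: 0 for sp in full.bipartitions()}
    for _ in range(replicates):
        cols = rng.integers(0, ncol, ncol)
        ns = shared[:, cols].sum(axis=1)
        mm = mism[:, cols].sum(axis=1)
        if (ns == 0).any():
            continue
        dv = np.zeros((n, n))
        for t, (i, j) in enumerate(pairs):
            dv[i, j] = dv[j, i] = mm[t] / ns[t]
        rep = nj_tree(DistanceMatrix(msa.labels, dv))
        for sp in rep.bipartitions():
            if sp in counts:
                counts[sp] += 1
    supports = {sp: int(round(100.0 * c / replicates)) for sp, c in counts.items()}
    all_leaves = frozenset(msa.labels)
    for node in full.root.walk():
        if node is full.root or node.is_leaf:
            continue
        side = frozenset(x.name for x in node.walk() if x.is_leaf)
        other = all_leaves - side
        if len(side) < 2 or len(other) < 2:
            continue
        key = min(side, other, key=lambda s: (len(s), sorted(s)))
        node.support = supports.get(key)
    return full
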