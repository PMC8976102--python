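"""Distance matrices, NJ trees, bootstrap, progressive MSA, ANI."""

import numpy as np
import pytest

from genomesurvey import _seq
from genomesurvey.align import StructuralError
from genomesurvey.mito import MitoGenome, mito_feature_counts
from genomesurvey.phylo import (GAP, DistanceError, DistanceMatrix, Msa,
                                ani_matrix, bootstrap_supports, jukes_cantor,
                                nj_tree, p_distance, progressive_msa)
from genomesurvey.simulate import simulate_mitogenome_set
from genomesurvey.tree import PhyloTree, TreeNode, random_tree
from tests.conftest import random_dna


def evolve_alignment(tree: PhyloTree, n_sites: int, seed: int) -> Msa:
    """Gapless alignment evolved along a tree (substitutions only)."""
    rng = np.random.default_rng(seed)
    root = rng.integers(0, 4, n_sites).astype(np.uint8)
    rows, labels = [], []

    def walk(node, seq):
        p = min(1.0, node.length)
        m = rng.random(n_sites) < p
        seq = seq.copy()
        seq[m] = (seq[m] + rng.integers(1, 4, int(m.sum())).astype(np.uint8)) % 4
        if node.is_leaf:
            labels.append(node.name)
            rows.append(seq)
        else:
            for c in node.children:
                walk(c, seq)

    for c in tree.root.children:
        walk(c, root)
    return Msa(labels, np.vstack(rows))


class TestNj:
    def test_four_taxon_additive_example(self):
        # distances from the tree ((A:1,B:2):1,(C:3,D:4))
        D = np.array([[0, 3, 5, 6], [3, 0, 6, 7],
                      [5, 6, 0, 7], [6, 7, 7, 0]], float)
        t = nj_tree(DistanceMatrix(list("ABCD"), D))
        assert t.bipartitions() == {frozenset({"A", "B"})}
        labels, pm = t.path_length_matrix()
        order = [labels.index(x) for x in "ABCD"]
        assert np.allclose(pm[np.ix_(order, order)], D, atol=1e-9)

    def test_three_taxa_closed_form(self):
        D = np.array([[0, 2, 3], [2, 0, 5], [3, 5, 0]], float)
        t = nj_tree(DistanceMatrix(list("XYZ"), D))
        labels, pm = t.path_length_matrix()
        order = [labels.index(x) for x in "XYZ"]
        assert np.allclose(pm[np.ix_(order, order)], D, atol=1e-12)

    @pytest.mark.parametrize("n_taxa,seed", [(5, 0), (6, 1), (7, 2), (8, 3),
                                             (8, 4), (8, 5)])
    def test_recovers_topology_of_additive_matrices(self, n_taxa, seed):
        rng = np.random.default_rng(seed)
        gen = random_tree([f"t{i}" for i in range(n_taxa)], rng,
                          mean_branch=0.5)
        # strictly positive branch lengths so every split is recoverable
        for node in gen.root.walk():
            node.length = float(node.length) + 0.05
        labels, D = gen.path_length_matrix()
        rec = nj_tree(DistanceMatrix(labels, D))
        assert rec.bipartitions() == gen.bipartitions()
        _lab, pm = rec.path_length_matrix()
        order = [rec.leaf_labels().index(x) for x in labels]
        assert np.abs(pm[np.ix_(order, order)] - D).max() <= 1e-9

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(StructuralError):
            DistanceMatrix(list("ABC"), np.array([[0, 1, 2], [9, 0, 1],
                                                  [2, 1, 0]], float))

    def test_too_few_taxa_rejected(self):
        with pytest.raises(StructuralError):
            nj_tree(DistanceMatrix(["a", "b"], np.zeros((2, 2))))


class TestPDistance:
    def test_quarter_divergence(self):
        m = Msa(["x", "y"], np.array([_seq.encode("ACGT"),
                                      _seq.encode("ACGA")]))
        assert p_distance(m).values[0, 1] == 0.25

    def test_identical_rows_are_zero(self):
        m = Msa(["x", "y"], np.tile(_seq.encode("ACGTACGT"), (2, 1)))
        assert p_distance(m).values[0, 1] == 0.0

    def test_matches_column_count_oracle(self):
        rng = np.random.default_rng(9)
        mat = rng.integers(0, 5, size=(4, 300)).astype(np.uint8)  # with gaps
        labels = list("abcd")
        d = p_distance(Msa(labels, mat)).values
        for i in range(4):
            for j in range(i + 1, 4):
                shared = mm = 0
                for col in range(300):
                    x, y = mat[i, col], mat[j, col]
                    if x != GAP and y != GAP:
                        shared += 1
                        mm += x != y
                assert d[i, j] == pytest.approx(mm / shared)

    def test_disjoint_gap_patterns_raise(self):
        a = np.array([0, 1, GAP, GAP], dtype=np.uint8)
        b = np.array([GAP, GAP, 2, 3], dtype=np.uint8)
        with pytest.raises(DistanceError):
            p_distance(Msa(["a", "b"], np.vstack([a, b])))

    def test_jukes_cantor_exceeds_p(self):
        m = Msa(["x", "y"], np.array([_seq.encode("ACGTACGTAC"),
                                      _seq.encode("ACGAACGTAC")]))
        d = p_distance(m)
        assert jukes_cantor(d).values[0, 1] > d.values[0, 1]


class TestMsa:
    def test_identical_sequences_align_gapless(self):
        s = random_dna(500, seed=20)
        msa = progressive_msa([("a", s), ("b", s), ("c", s)])
        assert msa.n_columns == 500
        assert (msa.matrix != GAP).all()

    def test_planted_insertion_gives_single_gap_block(self):
        base = random_dna(600, seed=21)
        ins = base[:300] + "TTT" + base[300:]
        msa = progressive_msa([("a", base), ("b", ins), ("c", base)])
        row_a = msa.row("a")
        assert row_a.count("-") == 3
        i = row_a.index("-")
        assert row_a[i : i + 3] == "---"

    def test_degap_round_trip(self):
        recs = simulate_mitogenome_set(4, None, subs_rate=1.0, seed=22)
        named = [(r.name, r.sequence()) for r in recs]
        msa = progressive_msa(named)
        for name, seq in named:
            assert msa.degapped_row(name) == seq


class TestBootstrap:
    def make_clade_tree(self):
        def leaf(n, l):
            return TreeNode(name=n, length=l)
        return PhyloTree(TreeNode(children=[
            TreeNode(children=[leaf("A", 0.01), leaf("B", 0.01)], length=0.12),
            TreeNode(children=[leaf("C", 0.01), leaf("D", 0.01)], length=0.12),
            leaf("E", 0.15)]))

    def test_deep_clades_get_high_support(self):
        msa = evolve_alignment(self.make_clade_tree(), 2000, seed=23)
        t = bootstrap_supports(msa, replicates=200, seed=24)
        sup = t.support_of_splits()
        assert sup[frozenset({"A", "B"})] >= 95
        assert sup[frozenset({"C", "D"})] >= 95

    def test_single_replicate_supports_are_binary(self):
        msa = evolve_alignment(self.make_clade_tree(), 500, seed=25)
        t = bootstrap_supports(msa, replicates=1, seed=26)
        assert set(t.support_of_splits().values()) <= {0, 100}

    def test_fixed_seed_is_deterministic(self):
        msa = evolve_alignment(self.make_clade_tree(), 800, seed=27)
        t1 = bootstrap_supports(msa, replicates=50, seed=28)
        t2 = bootstrap_supports(msa, replicates=50, seed=28)
        assert t1.to_newick() == t2.to_newick()

    def test_supports_within_range_and_stable_across_seeds(self):
        msa = evolve_alignment(self.make_clade_tree(), 2000, seed=29)
        vals = []
        for seed in (30, 31):
            t = bootstrap_supports(msa, replicates=100, seed=seed)
            sup = t.support_of_splits()
            assert all(0 <= v <= 100 for v in sup.values())
            vals.append(sup[frozenset({"A", "B"})])
        assert abs(vals[0] - vals[1]) <= 10  # Monte-Carlo SE at n=100


class TestAni:
    def test_identical_sequences_are_100(self):
        s = random_dna(1500, seed=32)
        labels, ani = ani_matrix([("a", s), ("b", s)])
        assert ani[0, 1] == 100.0

    def test_planted_8pct_divergence_reads_92(self):
        rng = np.random.default_rng(33)
        s = random_dna(2000, seed=33)
        arr = _seq.encode(s).copy()
        sites = rng.choice(2000, 160, replace=False)
        arr[sites] = (arr[sites] + rng.integers(1, 4, 160).astype(np.uint8)) % 4
        _labels, ani = ani_matrix([("a", s), ("b", _seq.decode(arr))])
        assert ani[0, 1] == pytest.approx(92.0, abs=1.0)

    def test_matrix_symmetric_with_100_diagonal(self):
        seqs = [(f"s{i}", random_dna(1200, seed=40 + i)) for i in range(3)]
        _labels, ani = ani_matrix(seqs)
        assert np.allclose(ani, ani.T)
        assert np.allclose(np.diag(ani), 100.0)

    def test_consistent_with_p_distance_on_gapless_pair(self):
        msa = evolve_alignment(self.make_two_taxon_tree(), 1500, seed=41)
        d = p_distance(msa).values[0, 1]
        named = [(l, msa.degapped_row(l)) for l in msa.labels]
        _labels, ani = ani_matrix(named)
        assert abs(ani[0, 1] - 100 * (1 - d)) <= 0.5

    @staticmethod
    def make_two_taxon_tree():
        return PhyloTree(TreeNode(children=[TreeNode(name="a", length=0.02),
                                            TreeNode(name="b", length=0.02)]))


class TestMitoFeatures:
    def test_canonical_complement_unflagged(self):
        rec = simulate_mitogenome_set(2, None, subs_rate=0.0, seed=50)[0]
        out = mito_feature_counts(rec)
        assert out["counts"] == {"CDS": 13, "tRNA": 22, "rRNA": 2, "D-loop": 1}
        assert out["canonical"]

    def test_missing_trna_is_flagged(self):
        rec = simulate_mitogenome_set(2, None, subs_rate=0.0, seed=50)[0]
        feats = [f for f in rec.features if f[0] != "tRNA-Phe"]
        broken = MitoGenome(rec.name, rec.seq, feats, circular=True)
        assert not mito_feature_counts(broken)["canonical"]

    def test_counts_invariant_under_rotation(self):
        rec = simulate_mitogenome_set(2, None, subs_rate=0.0, seed=51)[0]
        base = mito_feature_counts(rec)["counts"]
        for origin in (1, 137, len(rec) // 2, len(rec) - 5):
            rotated = rec.rotate(origin)
            assert mito_feature_counts(rotated)["counts"] == base
            assert len(rotated) == len(rec)

    def test_rotation_preserves_feature_sequences(self):
        rec = simulate_mitogenome_set(2, None, subs_rate=0.0, seed=52)[0]
        rot = rec.rotate(len(rec) // 3)
        for name in ("COX1", "CYTB", "D-loop"):
            assert rot.feature_sequence(name) == rec.feature_sequence(name)


class TestNewick:
    def test_round_trip_through_biopython(self):
        rng = np.random.default_rng(60)
        t = random_tree([f"x{i}" for i in range(6)], rng)
        back = PhyloTree.from_newick(t.to_newick())
        assert back.bipartitions() == t.bipartitions()
        assert sorted(back.leaf_labels()) == sorted(t.leaf_labels())
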