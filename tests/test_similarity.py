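"""Descriptors, Tanimoto, single linkage, MDS and matrix correlation."""

import networkx as nx
import numpy as np
import pytest
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import cdist, squareform

from flavopred import (
    DissimilarityMatrix,
    aglycones,
    atom_pair_descriptor,
    classical_mds,
    cocluster_candidates,
    compound,
    dissimilarity_correlation,
    pairwise_dissimilarity,
    pathway_reaction_pairs,
    reaction_profile,
    single_linkage,
    tanimoto,
)
from flavopred.similarity import AtomPairDescriptor, SimilarityError
from conftest import benzene, make_graph


class TestDescriptors:
    def test_single_atom_empty(self):
        g = make_graph({1: "O"}, [])
        assert atom_pair_descriptor(g).features == frozenset()

    def test_two_atom_single_feature(self):
        g = make_graph({1: "C", 2: "O"}, [(1, 2, "single")])
        assert atom_pair_descriptor(g).features == {("C.sp3", "O.oh", 1)}

    def test_benzene_cap3_brute_force(self):
        d = atom_pair_descriptor(benzene(), cap=3)
        assert d.features == {("C.ar.h", "C.ar.h", k) for k in (1, 2, 3)}
        # brute force: all-pairs shortest paths
        g = benzene().to_networkx()
        sp = dict(nx.all_pairs_shortest_path_length(g))
        brute = {
            ("C.ar.h", "C.ar.h", sp[i][j])
            for i in g
            for j in g
            if i < j and sp[i][j] <= 3
        }
        assert d.features == brute

    def test_disconnected_rejected(self):
        g = make_graph({1: "C", 2: "C"}, [])
        with pytest.raises(SimilarityError):
            atom_pair_descriptor(g)


class TestTanimoto:
    def test_identical(self):
        d = atom_pair_descriptor(compound("quercetin"))
        assert tanimoto(d, d) == 1.0

    def test_disjoint(self):
        a = AtomPairDescriptor(frozenset({("a", "b", 1)}), 7)
        b = AtomPairDescriptor(frozenset({("c", "d", 1)}), 7)
        assert tanimoto(a, b) == 0.0

    def test_half_overlap(self):
        a = AtomPairDescriptor(frozenset({"x", "y", "z"}), 7)
        b = AtomPairDescriptor(frozenset({"y", "z", "w"}), 7)
        assert tanimoto(a, b) == 0.5

    def test_both_empty(self):
        e = AtomPairDescriptor(frozenset(), 7)
        assert tanimoto(e, e) == 1.0

    def test_cap_mismatch(self):
        with pytest.raises(SimilarityError):
            tanimoto(
                AtomPairDescriptor(frozenset(), 7),
                AtomPairDescriptor(frozenset(), 5),
            )


class TestPairwise:
    def test_duplicate_item_zero_offdiagonal(self):
        d = pairwise_dissimilarity(
            [benzene(), compound("phenol"), benzene()],
            labels=["b1", "ph", "b2"],
        )
        assert d[("b1", "b2")] == 0.0
        assert np.allclose(d.values, d.values.T)
        assert np.allclose(d.values[0], d.values[2])

    def test_panel_equals_brute_force(self):
        items = [compound(n) for n in
                 ["benzene", "phenol", "catechol", "guaiacol", "naringenin"]]
        d = pairwise_dissimilarity(items)
        descs = [atom_pair_descriptor(g) for g in items]
        for i in range(5):
            for j in range(5):
                expect = 0.0 if i == j else 1.0 - tanimoto(descs[i], descs[j])
                assert d.values[i, j] == pytest.approx(expect)

    def test_aglycone_panel_is_valid_matrix(self):
        d = pairwise_dissimilarity(aglycones())
        assert len(d.labels) == 15
        assert d.values.max() <= 1.0 and d.values.min() >= 0.0


class TestSingleLinkage:
    def test_two_items(self):
        d = DissimilarityMatrix(["a", "b"], np.array([[0, 0.3], [0.3, 0]]))
        dendro = single_linkage(d)
        assert dendro.merges == [(0, 1, 0.3, 2)]

    def test_hand_agglomeration(self):
        # 1-D points {0, 1, 10} scaled into [0,1]: merges at 0.1 then 0.9
        pts = np.array([0.0, 1.0, 10.0]) / 10.0
        v = np.abs(pts[:, None] - pts[None, :])
        dendro = single_linkage(DissimilarityMatrix(["a", "b", "c"], v))
        heights = [m[2] for m in dendro.merges]
        assert heights == pytest.approx([0.1, 0.9])

    @pytest.mark.parametrize("seed", range(30))
    def test_mst_and_scipy_oracles(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 8))
        m = rng.random((n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        m /= max(m.max(), 1.0)
        d = DissimilarityMatrix([str(i) for i in range(n)], m)
        heights = [mg[2] for mg in single_linkage(d).merges]
        # oracle 1: sorted MST edge weights
        mst = nx.minimum_spanning_tree(nx.from_numpy_array(m))
        weights = sorted(w for _, _, w in mst.edges.data("weight"))
        assert heights == pytest.approx(weights)
        # oracle 2: scipy single linkage heights
        z = linkage(squareform(m), method="single")
        assert heights == pytest.approx(list(z[:, 2]))

    def test_newick_export_parses(self):
        from flavopred.homologs import newick_to_tree

        d = pairwise_dissimilarity(
            [compound(n) for n in ["benzene", "phenol", "catechol"]]
        )
        tree = newick_to_tree(single_linkage(d).to_newick())
        assert {t.name for t in tree.tips()} == {"benzene", "phenol", "catechol"}


class TestCocluster:
    def test_cut_zero_only_duplicates(self):
        pairs = list(pathway_reaction_pairs().values())
        # naringenin is the reactant of two fixture pairs: exact-descriptor
        # duplicates co-cluster even at height zero
        hits = cocluster_candidates(compound("naringenin"), pairs, 0.0)
        assert set(hits) == {"C-ring-opening", "direct-flavanone-reduction"}

    def test_cut_one_everything(self):
        pairs = list(pathway_reaction_pairs().values())
        hits = cocluster_candidates(compound("naringenin"), pairs, 1.0)
        assert set(hits) == {rp.id for rp in pairs}

    def test_near_duplicate_found_at_intermediate_cut(self):
        pairs = list(pathway_reaction_pairs().values())
        hits = cocluster_candidates(compound("naringenin"), pairs, 0.35)
        assert "C-ring-opening" in hits
        assert "hydroxyl-O-methylation" not in hits  # catechol is far


class TestReactionProfile:
    def test_extremes_and_example(self):
        d = reaction_profile(
            {"a": {"op1", "op2"}, "b": {"op1", "op2"}, "c": {"op3"},
             "d": {"op2", "op3"}}
        )
        assert d[("a", "b")] == 0.0
        assert d[("a", "c")] == 1.0
        assert d[("a", "d")] == pytest.approx(1 - 1 / 3)


class TestMDS:
    def test_all_zero_matrix_embeds_at_origin(self):
        d = DissimilarityMatrix(["a", "b", "c"], np.zeros((3, 3)))
        emb = classical_mds(d, 2)
        assert np.allclose(emb.coordinates, 0.0)

    def test_collinear_points(self):
        pts = np.array([0.0, 3.0, 7.0]) / 7.0
        v = np.abs(pts[:, None] - pts[None, :])
        emb = classical_mds(DissimilarityMatrix(["a", "b", "c"], v), 1)
        got = cdist(emb.coordinates, emb.coordinates)
        assert np.allclose(got, v, atol=1e-9)

    def test_recovers_euclidean_configuration(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(50, 2))
        dist = cdist(pts, pts)
        scale = dist.max()
        d = DissimilarityMatrix(
            [f"p{i}" for i in range(50)], dist / scale
        )
        emb = classical_mds(d, 2)
        from scipy.linalg import orthogonal_procrustes

        target = (pts / scale) - (pts / scale).mean(axis=0)
        rot, _ = orthogonal_procrustes(emb.coordinates, target)
        rmsd = np.sqrt(
            np.mean(np.sum((emb.coordinates @ rot - target) ** 2, axis=1))
        )
        assert rmsd < 1e-8

    def test_dim_exceeding_positive_eigenvalues_rejected(self):
        pts = np.array([0.0, 3.0, 7.0]) / 7.0  # collinear: 1 positive axis
        v = np.abs(pts[:, None] - pts[None, :])
        with pytest.raises(SimilarityError):
            classical_mds(DissimilarityMatrix(["a", "b", "c"], v), 2)


class TestCorrelation:
    def _random(self, seed, n=8):
        rng = np.random.default_rng(seed)
        m = rng.random((n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        return DissimilarityMatrix([str(i) for i in range(n)], m / m.max())

    def test_perfect_correlation(self):
        a = self._random(0)
        res = dissimilarity_correlation(a, a, n_permutations=99, seed=1)
        assert res["r"] == pytest.approx(1.0)
        assert res["slope"] == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        a = self._random(1)
        flipped = 1.0 - a.values
        np.fill_diagonal(flipped, 0.0)
        b = DissimilarityMatrix(a.labels, flipped)
        res = dissimilarity_correlation(a, b, n_permutations=99, seed=1)
        assert res["r"] == pytest.approx(-1.0)

    def test_label_mismatch_rejected(self):
        a, b = self._random(2), self._random(3)
        b.labels = [f"x{i}" for i in range(len(b.labels))]
        with pytest.raises(SimilarityError):
            dissimilarity_correlation(a, b, seed=0)

    def test_seeded_runs_reproducible(self):
        a, b = self._random(4), self._random(5)
        r1 = dissimilarity_correlation(a, b, n_permutations=199, seed=9)
        r2 = dissimilarity_correlation(a, b, n_permutations=199, seed=9)
        assert r1 == r2

    def test_null_pvalues_spread_over_unit_interval(self):
        # independent random matrices: p-values should look uniform-ish
        ps = []
        for seed in range(40):
            a = self._random(100 + seed)
            b = self._random(200 + seed)
            res = dissimilarity_correlation(a, b, n_permutations=99, seed=seed)
            ps.append(res["p_value"])
        ps = np.array(ps)
        # loose declared tolerance on the null: mean near 0.5, spread wide
        assert 0.3 < ps.mean() < 0.7
        assert (ps < 0.25).mean() < 0.55 and (ps > 0.75).mean() < 0.55
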