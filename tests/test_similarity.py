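"""Tanimoto network similarity, UPGMA clustering, consensus ranking."""

import numpy as np
import pytest

import tetranet as tn
from tetranet.grn import MRIRecord
from tetranet.similarity import SimilarityMatrix

from helpers import make_grn, random_grn


def grn_from_edges(edges):
    nodes = {g: (0, 1) for e in edges for g in e[:2]}
    return make_grn(nodes, edges)


class TestTanimoto:
    def test_identity_and_disjoint(self):
        a = grn_from_edges([("A", "B", 1)])
        b = grn_from_edges([("C", "D", 1)])
        assert tn.tanimoto(a, a) == 1.0
        assert tn.tanimoto(a, b) == 0.0

    def test_partial_overlap_is_intersection_over_union(self):
        a = grn_from_edges([("A", "B", 1), ("B", "C", 1), ("C", "D", 1)])
        b = grn_from_edges([("B", "C", 1), ("C", "D", 1), ("D", "E", 1)])
        assert tn.tanimoto(a, b) == pytest.approx(2 / 4)

    def test_sign_is_part_of_the_edge_feature(self):
        a = grn_from_edges([("A", "B", 1)])
        b = grn_from_edges([("A", "B", -1)])
        assert tn.tanimoto(a, b, on="edges") == 0.0
        assert tn.tanimoto(a, b, on="nodes") == 1.0

    def test_empty_feature_sets_are_hard_error(self):
        with pytest.raises(ValueError):
            tn.tanimoto(tn.TemporalGRN(), tn.TemporalGRN())

    def test_jaccard_distance_triangle_inequality_fuzzed(self):
        rng = np.random.default_rng(13)
        grns = [random_grn(rng, max_nodes=8) for _ in range(12)]
        for _ in range(300):
            a, b, c = (grns[i] for i in rng.choice(len(grns), 3, replace=False))
            dab = 1 - tn.tanimoto(a, b)
            dbc = 1 - tn.tanimoto(b, c)
            dac = 1 - tn.tanimoto(a, c)
            assert dac <= dab + dbc + 1e-12

    def test_cosine_alternative_matches_set_formula(self):
        a = grn_from_edges([("A", "B", 1), ("B", "C", 1)])
        b = grn_from_edges([("B", "C", 1)])
        assert tn.cosine_similarity(a, b) == pytest.approx(1 / np.sqrt(2))


class TestClusterGRNs:
    def test_identical_pair_merges_first_at_height_zero(self):
        g1 = grn_from_edges([("A", "B", 1)])
        g3 = grn_from_edges([("X", "Y", 1)])
        sim = tn.similarity_matrix({"a": g1, "b": g1, "c": g3})
        dend = tn.cluster_grns(sim)
        first = dend.linkage[0]
        assert {int(first[0]), int(first[1])} == {0, 1}
        assert first[2] == pytest.approx(0.0)

    def test_three_item_average_linkage_matches_hand_computation(self):
        # distances: d(a,b)=0.1, d(a,c)=0.8, d(b,c)=0.9
        # UPGMA: merge {a,b} at 0.1; then d({a,b},c) = (0.8+0.9)/2 = 0.85
        sim = SimilarityMatrix(
            labels=["a", "b", "c"],
            values=np.array([[1.0, 0.9, 0.2],
                             [0.9, 1.0, 0.1],
                             [0.2, 0.1, 1.0]]))
        dend = tn.cluster_grns(sim)
        assert {int(dend.linkage[0][0]), int(dend.linkage[0][1])} == {0, 1}
        assert dend.linkage[0][2] == pytest.approx(0.1)
        assert dend.linkage[1][2] == pytest.approx(0.85)
        assert dend.newick.count("(") == 2 and dend.newick.endswith(";")

    def test_topology_invariant_under_label_permutation(self):
        g = [grn_from_edges([("A", "B", 1), ("B", "C", 1)]),
             grn_from_edges([("A", "B", 1), ("C", "D", 1)]),
             grn_from_edges([("X", "Y", 1)])]
        d1 = tn.cluster_grns(tn.similarity_matrix(
            {"g0": g[0], "g1": g[1], "g2": g[2]}))
        d2 = tn.cluster_grns(tn.similarity_matrix(
            {"g2": g[2], "g0": g[0], "g1": g[1]}))
        # first merge joins the same pair of networks in both orderings
        pair1 = {d1.labels[int(i)] for i in d1.linkage[0][:2]}
        pair2 = {d2.labels[int(i)] for i in d2.linkage[0][:2]}
        assert pair1 == pair2 == {"g0", "g1"}

    def test_fewer_than_two_networks_is_hard_error(self):
        sim = SimilarityMatrix(labels=["a"], values=np.array([[1.0]]))
        with pytest.raises(ValueError):
            tn.cluster_grns(sim)

    def test_matrix_validation_rejects_asymmetry(self):
        with pytest.raises(ValueError):
            SimilarityMatrix(labels=["a", "b"],
                             values=np.array([[1.0, 0.3], [0.6, 1.0]]))


def rec(tf, mri, count=1):
    return MRIRecord(tf=tf, mri=mri, regulated_count=count, population_size=10)


class TestConsensusRank:
    def test_mean_over_transitions(self):
        out = tn.consensus_rank({
            "b->mac": [rec("CEBPA", 0.4)],
            "fib->mac": [rec("CEBPA", 0.6)],
        }, target_label="mac")
        assert out[0].tf == "CEBPA"
        assert out[0].mean_mri == pytest.approx(0.5)
        assert out[0].n_transitions == 2

    def test_absent_tf_contributes_zero(self):
        out = tn.consensus_rank({
            "b->mac": [rec("SPI1", 0.8)],
            "fib->mac": [rec("CEBPA", 0.1)],
        })
        spi1 = next(r for r in out if r.tf == "SPI1")
        assert spi1.mean_mri == pytest.approx(0.4)
        assert spi1.n_transitions == 1

    def test_target_label_filters_transitions(self):
        out = tn.consensus_rank({
            "b->mac": [rec("A", 0.8)],
            "b->neuron": [rec("B", 0.9)],
        }, target_label="mac")
        assert [r.tf for r in out] == ["A"]
        with pytest.raises(ValueError):
            tn.consensus_rank({"b->mac": [rec("A", 0.8)]}, target_label="x")

    def test_shared_planted_regulator_ranks_first_across_transitions(self):
        """Three synthetic transitions with the same planted TF: the
        consensus puts it on top."""
        tables = {}
        for i in range(3):
            ds = tn.generate(tn.SyntheticSpec(seed=100 + i, n_tfs=10,
                                              n_targets=40))
            traj = tn.discretize(ds.expression)
            grn = tn.reconstruct(ds.priors, traj, tf_list=set(ds.tf_list))
            pop = tn.target_population(grn, "terminal")
            tables[f"src{i}->dest"] = [
                tn.mri_score(grn, tf, pop) for tf in sorted(grn.seed_eligible())]
        out = tn.consensus_rank(tables, target_label="dest")
        assert out[0].tf == "MR1" and out[0].n_transitions == 3
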