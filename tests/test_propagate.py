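"""Coherence rule, temporal rule, and traversal vs the exhaustive-path oracle."""

import itertools

import numpy as np
import pytest

import tetranet as tn
from tetranet.grn import UNSIGNED

from helpers import make_grn, oracle_regulated, random_grn


class TestCoherent:
    def test_full_truth_table(self):
        """All 12 sign/state combinations against the defining relation."""
        for sign, s_u, s_v in itertools.product((1, -1, UNSIGNED), (1, -1),
                                                (1, -1)):
            expected = True if sign == UNSIGNED else (s_v == sign * s_u)
            assert tn.coherent(sign, s_u, s_v) is expected

    def test_induced_activator_explains_induced_target(self):
        assert tn.coherent(1, 1, 1)

    def test_repressor_cannot_explain_co_induction(self):
        assert not tn.coherent(-1, 1, 1)

    def test_zero_state_violates_contract(self):
        with pytest.raises(ValueError):
            tn.coherent(1, 0, 1)
        with pytest.raises(ValueError):
            tn.coherent(1, 1, 0)

    def test_effective_sign_inferred_for_unsigned_edges(self):
        assert tn.effective_sign(UNSIGNED, 1, -1) == -1
        assert tn.effective_sign(-1, 1, -1) == -1


CHAIN = {"A": (0, 1, 1, 1), "B": (0, 0, 1, 1), "C": (0, 0, 0, 1)}


class TestPropagate:
    def test_coherent_chain_is_fully_regulated(self):
        grn = make_grn(CHAIN, [("A", "B", 1), ("B", "C", 1)])
        res = tn.propagate(grn, "A")
        assert res.regulated == {"A": 1, "B": 2, "C": 3}
        assert res.retained_edges == {("A", "B", 1), ("B", "C", 1)}

    def test_target_changing_before_source_is_temporal_violation(self):
        grn = make_grn({"A": (0, 0, 0, 1), "B": (0, 1, 1, 1)},
                       [("A", "B", 1)])
        res = tn.propagate(grn, "A")
        assert res.regulated == {"A": 3}
        assert res.excluded_edges[("A", "B", 1)] == "temporal_order"

    def test_non_strict_allows_same_timepoint_regulation(self):
        grn = make_grn({"A": (0, 1), "B": (0, 1)}, [("A", "B", 1)])
        assert "B" in tn.propagate(grn, "A").regulated
        assert "B" not in tn.propagate(grn, "A", temporal_rule="strict").regulated

    def test_incoherent_edge_blocks_and_downstream_is_excluded(self):
        # A ->+ B ->+ D and A ->+ C ->- D: C->D incoherent (repression of a
        # co-induced gene); B responsive route retained.
        nodes = {"A": (0, 1, 1), "B": (0, 1, 1), "C": (0, 1, 1),
                 "D": (0, 0, 1)}
        grn = make_grn(nodes, [("A", "B", 1), ("B", "D", 1),
                               ("A", "C", 1), ("C", "D", -1)])
        res = tn.propagate(grn, "A")
        assert set(res.regulated) == {"A", "B", "C", "D"}
        assert res.excluded_edges[("C", "D", -1)] == "incoherent_sign"
        # cut the coherent route: D now only reachable through the
        # incoherent edge, so downstream exclusion removes it
        grn2 = make_grn(nodes, [("A", "C", 1), ("C", "D", -1)])
        assert "D" not in tn.propagate(grn2, "A").regulated

    def test_edges_from_unreached_nodes_reported_as_unreachable(self):
        grn = make_grn({"A": (0, 1), "B": (0, -1), "C": (0, 1)},
                       [("A", "B", 1), ("B", "C", 1)])
        res = tn.propagate(grn, "A")
        assert res.excluded_edges[("B", "C", 1)] == "unreachable_downstream"

    def test_self_loops_reported_but_never_traversed(self):
        grn = make_grn({"A": (0, 1), "B": (0, 1)},
                       [("A", "A", 1), ("A", "B", 1)])
        res = tn.propagate(grn, "A")
        assert res.self_loops == {("A", "A", 1)}
        assert ("A", "A", 1) not in res.retained_edges

    def test_unknown_seed_or_rule_is_hard_error(self):
        grn = make_grn({"A": (0, 1), "B": (0, 1)}, [("A", "B", 1)])
        with pytest.raises(KeyError):
            tn.propagate(grn, "ZZZ")
        with pytest.raises(ValueError):
            tn.propagate(grn, "B")  # no out-edges: not seed-eligible
        with pytest.raises(ValueError):
            tn.propagate(grn, "A", temporal_rule="sometimes")

    @pytest.mark.parametrize("rule", ["non_strict", "strict"])
    def test_matches_exhaustive_path_oracle_on_random_networks(self, rule):
        rng = np.random.default_rng(42)
        checked = 0
        while checked < 60:
            grn = random_grn(rng)
            seeds = sorted(grn.seed_eligible())
            if not seeds:
                continue
            seed = seeds[int(rng.integers(len(seeds)))]
            res = tn.propagate(grn, seed, temporal_rule=rule)
            assert set(res.regulated) == oracle_regulated(grn, seed, rule)
            checked += 1

    def test_removing_an_edge_never_enlarges_the_regulated_set(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            grn = random_grn(rng)
            seeds = sorted(grn.seed_eligible())
            if not seeds:
                continue
            seed = seeds[0]
            full = set(tn.propagate(grn, seed).regulated)
            edges = sorted(grn.edge_triples())
            u, v, s = edges[int(rng.integers(len(edges)))]
            grn.graph.remove_edge(u, v, key=s)
            if seed not in grn.seed_eligible():
                continue
            assert set(tn.propagate(grn, seed).regulated) <= full

    def test_result_invariants_on_random_networks(self):
        """Seed self-activation time, parent ordering, subgraph closure."""
        rng = np.random.default_rng(9)
        for _ in range(30):
            grn = random_grn(rng)
            seeds = sorted(grn.seed_eligible())
            if not seeds:
                continue
            res = tn.propagate(grn, seeds[0])
            assert res.regulated[res.seed] == \
                grn.trajectory(res.seed).first_change
            assert res.retained_edges <= grn.edge_triples()
            for u, v, s in res.retained_edges:
                assert u in res.regulated and v in res.regulated
                assert res.regulated[v] >= res.regulated[u]
            for n in set(res.regulated) - {res.seed}:
                assert any(v == n for _, v, _ in res.retained_edges)
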