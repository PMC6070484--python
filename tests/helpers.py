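"""Shared builders and the independent propagation oracle used by the tests."""

from __future__ import annotations

import networkx as nx
import numpy as np

from tetranet import StateTrajectory, TemporalGRN, UNSIGNED


def make_grn(nodes: dict[str, tuple[int, ...]],
             edges: list[tuple[str, str, int]],
             tfs: set[str] | None = None,
             sources: str = "test") -> TemporalGRN:
    """Build a network directly from state tuples and (tf, target, sign)."""
    grn = TemporalGRN()
    for gene, states in nodes.items():
        grn.add_node(StateTrajectory(gene, tuple(states)))
    for u, v, sign in edges:
        grn.add_edge(u, v, sign, [sources])
    if tfs is not None:
        grn.tfs = set(tfs)
    return grn


def random_grn(rng: np.random.Generator, max_nodes: int = 12,
               n_timepoints: int = 5, p_edge: float = 0.2) -> TemporalGRN:
    """Random small network with responsive nodes and mixed edge signs."""
    n = int(rng.integers(3, max_nodes + 1))
    names = [f"G{i}" for i in range(n)]
    grn = TemporalGRN()
    for name in names:
        fc = int(rng.integers(1, n_timepoints))
        s = int(rng.choice([-1, 1]))
        states = [0] * n_timepoints
        stop = n_timepoints if (rng.random() < 0.7 or fc == n_timepoints - 1) \
            else n_timepoints - 1
        for i in range(fc, stop):
            states[i] = s
        grn.add_node(StateTrajectory(name, tuple(states)))
    for u in names:
        for v in names:
            if u == v:
                continue
            if rng.random() < p_edge:
                sign = int(rng.choice([1, -1, UNSIGNED]))
                grn.add_edge(u, v, sign, ["fuzz"])
    return grn


def oracle_regulated(grn: TemporalGRN, seed: str,
                     temporal_rule: str = "non_strict") -> set[str]:
    """Exhaustive-path oracle: a node is regulated iff at least one simple
    path from the seed exists along which every edge is coherent and
    first-change times respect the temporal rule. Independent of the
    package's traversal: enumerates all simple paths per target."""

    def edge_ok(u: str, v: str) -> bool:
        tu, tv = grn.trajectory(u), grn.trajectory(v)
        if temporal_rule == "strict":
            if not tv.first_change > tu.first_change:
                return False
        elif not tv.first_change >= tu.first_change:
            return False
        for sign in grn.graph[u][v]:
            if sign == UNSIGNED or tv.first_state == sign * tu.first_state:
                return True
        return False

    regulated = {seed}
    for target in grn.graph.nodes:
        if target == seed:
            continue
        for path in nx.all_simple_paths(grn.graph, seed, target):
            if all(edge_ok(a, b) for a, b in zip(path, path[1:])):
                regulated.add(target)
                break
    return regulated
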