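"""Temporal propagation of transcription-regulatory signal through a GRN.

Starting from a seed TF, regulation flows along directed edges subject to
three logical rules:

(i)   unresponsive nodes terminate propagation — already enforced at network
      construction, so every node here is responsive;
(ii)  *coherence*: the edge's regulation sign must agree with the discretized
      states of its endpoints (an induced activator can explain an induced
      target; an induced repressor can explain a repressed target; etc.);
(iii) *temporal order*: a target's first expression change may not precede
      its regulator's (non-strict by default — equality is allowed because
      coarsely sampled time courses often place regulator and target in the
      same interval; ``strict`` requires a strictly later change).

Nodes downstream of excluded edges are dropped implicitly: a node is
regulated only if at least one fully coherent, temporally ordered path
connects it to the seed. Coherence is evaluated on each node's first
non-zero state; later sign reversals do not retroactively invalidate edges.
"""

from __future__ import annotations

from collections import deque

from .grn import UNSIGNED, PropagationResult, TemporalGRN


def coherent(edge_sign: int, source_state: int, target_state: int) -> bool:
    """Rule (ii): does the edge sign explain the endpoint states?

    For signed edges this is ``target_state == edge_sign * source_state``.
    Unsigned (binding-only) edges always pass; their effective sign is the
    product of the endpoint states. Zero states are a contract violation —
    rule (i) removes unresponsive nodes before propagation.
    """
    if source_state not in (-1, 1) or target_state not in (-1, 1):
        raise ValueError(
            f"coherence is defined on non-zero states, got "
            f"source={source_state}, target={target_state}")
    if edge_sign == UNSIGNED:
        return True
    return target_state == edge_sign * source_state


def effective_sign(edge_sign: int, source_state: int, target_state: int) -> int:
    """Sign actually acting along a traversed edge (inferred for unsigned)."""
    if edge_sign == UNSIGNED:
        return source_state * target_state
    return edge_sign


def propagate(grn: TemporalGRN, seed: str,
              temporal_rule: str = "non_strict") -> PropagationResult:
    """Simulate regulatory signal flow from ``seed`` across the network.

    Returns the set of coherently regulated nodes with their activation
    times (each node's own first-change timepoint), the retained edge set,
    and every excluded edge with its reason. Self-loops are never traversed
    (a node cannot temporally precede itself) and are reported apart.
    """
    if temporal_rule not in ("strict", "non_strict"):
        raise ValueError(f"unknown temporal rule {temporal_rule!r}")
    if seed not in grn.graph:
        raise KeyError(f"seed {seed!r} is not a node of the network")
    if seed not in grn.seed_eligible():
        raise ValueError(f"seed {seed!r} is not seed-eligible (not a TF)")

    def ok_time(fc_u: int, fc_v: int) -> bool:
        return fc_v > fc_u if temporal_rule == "strict" else fc_v >= fc_u

    # Reachability search. A node's activation time is its own first-change
    # index, which is fixed, so any admissible walk can be shortened to a
    # simple path and plain BFS suffices: an edge u->v is traversable iff u
    # is regulated, the edge is coherent on the first-change states, and
    # first_change(v) respects the temporal rule relative to first_change(u).
    regulated: dict[str, int] = {seed: grn.trajectory(seed).first_change}
    queue = deque([seed])
    while queue:
        u = queue.popleft()
        t_u = grn.trajectory(u)
        for v in grn.graph.successors(u):
            if v == u or v in regulated:
                continue
            t_v = grn.trajectory(v)
            if not ok_time(t_u.first_change, t_v.first_change):
                continue
            for sign in grn.graph[u][v]:
                if coherent(sign, t_u.first_state, t_v.first_state):
                    regulated[v] = t_v.first_change
                    queue.append(v)
                    break

    # Classify every edge of the network for reporting.
    retained: set[tuple[str, str, int]] = set()
    excluded: dict[tuple[str, str, int], str] = {}
    self_loops: set[tuple[str, str, int]] = set()
    for u, v, sign, _ in grn.edges():
        triple = (u, v, sign)
        if u == v:
            self_loops.add(triple)
            continue
        if u not in regulated:
            excluded[triple] = "unreachable_downstream"
            continue
        t_u, t_v = grn.trajectory(u), grn.trajectory(v)
        if not coherent(sign, t_u.first_state, t_v.first_state):
            excluded[triple] = "incoherent_sign"
        elif not ok_time(t_u.first_change, t_v.first_change):
            excluded[triple] = "temporal_order"
        else:
            retained.add(triple)

    return PropagationResult(seed=seed, regulated=regulated,
                             retained_edges=retained,
                             excluded_edges=excluded,
                             self_loops=self_loops)
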