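"""Master Regulator Index: scoring, randomized nulls and TF ranking.

The MRI of a TF is the fraction of a defined node population that the TF
coherently regulates — directly or through cascades — after temporal signal
propagation. The population is typically the *terminal* set (nodes still
differentially expressed at the last timepoint, i.e., defining the end state
of the transition), but any responsive subset can be used.

Confidence comes from an edge-randomization null: networks with the same
nodes (and trajectories) and the same number of edges, but rewired
connectivity, over which the same TF is re-scored. Both an add-one empirical
p-value (resolution-limited to 1/(R+1)) and a parametric upper-tail p under
a normal fit to the null are reported; only the parametric value can reach
the extreme magnitudes a large network may warrant.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .grn import MRIRecord, TemporalGRN
from .propagate import propagate

log = logging.getLogger(__name__)

_REWIRE_RETRIES = 100


def target_population(grn: TemporalGRN, mode: str = "terminal",
                      custom: Optional[set[str]] = None) -> set[str]:
    """Select the MRI denominator population.

    ``terminal``: nodes with a non-zero state at the last timepoint.
    ``all_responsive``: every node of the network (all are responsive).
    ``custom``: user-supplied set, intersected with the network's nodes.
    """
    if mode == "terminal":
        pop = {n for n in grn.nodes if grn.trajectory(n).terminal_state != 0}
    elif mode == "all_responsive":
        pop = set(grn.nodes)
    elif mode == "custom":
        if custom is None:
            raise ValueError("custom population mode requires a gene set")
        requested = {g.strip().upper() for g in custom}
        pop = requested & set(grn.nodes)
        missing = requested - pop
        if missing:
            log.warning("%d custom population genes absent from the network: %s",
                        len(missing), sorted(missing)[:10])
    else:
        raise ValueError(f"unknown population mode {mode!r}")
    if not pop:
        raise ValueError(f"population mode {mode!r} selected no genes")
    return pop


def mri_score(grn: TemporalGRN, tf: str, population: set[str],
              temporal_rule: str = "non_strict") -> MRIRecord:
    """Score one TF: fraction of the population it coherently regulates.

    The TF is excluded from its own numerator (a regulator does not regulate
    itself by fiat), but stays in the denominator if it belongs to the
    population.
    """
    if not population:
        raise ValueError("population must be non-empty")
    result = propagate(grn, tf, temporal_rule=temporal_rule)
    regulated = (set(result.regulated) - {tf}) & population
    return MRIRecord(tf=tf, mri=len(regulated) / len(population),
                     regulated_count=len(regulated),
                     population_size=len(population))


def randomize_grn(grn: TemporalGRN, seed, mode: str = "uniform") -> TemporalGRN:
    """Rewire connectivity, preserving nodes, trajectories and edge count.

    ``uniform`` (default): each edge keeps its sign and source set but its
    endpoints are redrawn — the TF end uniformly among seed-eligible nodes,
    the target end uniformly among all nodes. ``degree_preserving``: endpoint
    pairs are shuffled by repeated two-edge swaps, preserving every node's
    in- and out-degree. Self-loops and exact duplicate (tf, target, sign)
    triples are redrawn a bounded number of times, then accepted with a
    warning.
    """
    if grn.graph.number_of_nodes() < 2 or grn.n_edges() < 1:
        raise ValueError("randomization needs >= 2 nodes and >= 1 edge")
    rng = np.random.default_rng(seed)
    nodes = sorted(grn.graph.nodes)
    sources_pool = sorted(grn.seed_eligible()) or nodes
    edges = sorted(grn.edges(), key=lambda e: (e[0], e[1], e[2]))

    out = TemporalGRN()
    for n in nodes:
        out.add_node(grn.trajectory(n))
    out.tfs = set(grn.tfs)

    if mode == "uniform":
        taken: set[tuple[str, str, int]] = set()
        for _u, _v, sign, srcs in edges:
            for attempt in range(_REWIRE_RETRIES):
                u = sources_pool[rng.integers(len(sources_pool))]
                v = nodes[rng.integers(len(nodes))]
                if u != v and (u, v, sign) not in taken:
                    break
            else:
                log.warning("rewiring retry limit hit; accepting edge "
                            "%s->%s as drawn", u, v)
            taken.add((u, v, sign))
            out.add_edge(u, v, sign, srcs)
    elif mode == "degree_preserving":
        pairs = [[u, v] for u, v, _s, _ in edges]
        signs = [s for _u, _v, s, _ in edges]
        triples = {(u, v, s) for (u, v), s in zip(pairs, signs)}
        n = len(pairs)
        for _ in range(10 * n):
            i, j = int(rng.integers(n)), int(rng.integers(n))
            if i == j:
                continue
            (a, b), (c, d) = pairs[i], pairs[j]
            new_i, new_j = (a, d, signs[i]), (c, b, signs[j])
            if a == d or c == b or new_i == new_j:
                continue
            if new_i in triples or new_j in triples:
                continue
            triples -= {(a, b, signs[i]), (c, d, signs[j])}
            triples |= {new_i, new_j}
            pairs[i], pairs[j] = [a, d], [c, b]
        for (u, v), (_a, _b, sign, srcs) in zip(pairs, edges):
            out.add_edge(u, v, sign, srcs)
    else:
        raise ValueError(f"unknown randomization mode {mode!r}")
    return out


def _parametric_p(observed: float, null: np.ndarray) -> float:
    mean, sd = float(null.mean()), float(null.std(ddof=1)) if len(null) > 1 else 0.0
    if sd == 0 or math.isnan(sd):
        return 1.0 if observed <= mean else float(np.finfo(float).tiny)
    p = float(stats.norm.sf(observed, loc=mean, scale=sd))
    return max(p, float(np.finfo(float).tiny))


def mri_null(grn: TemporalGRN, tf: str, population: set[str],
             n_random: int = 100, seed=0, temporal_rule: str = "non_strict",
             null_mode: str = "uniform") -> MRIRecord:
    """Score a TF and fill its randomization-null summary.

    p_empirical uses the add-one estimator (1 + #{null >= observed}) /
    (n_random + 1), so it can never be smaller than 1/(n_random + 1).
    Replicates in which the TF loses seed-eligibility (no out-edge after
    rewiring, when no explicit TF list constrains eligibility) are resampled.
    """
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    obs = mri_score(grn, tf, population, temporal_rule=temporal_rule)
    rng = np.random.default_rng(seed)
    null_vals = []
    attempts = 0
    while len(null_vals) < n_random:
        attempts += 1
        if attempts > 20 * n_random:
            raise RuntimeError(
                f"could not draw {n_random} null networks in which "
                f"{tf} remains seed-eligible")
        sub_seed = int(rng.integers(2 ** 31))
        rand = randomize_grn(grn, sub_seed, mode=null_mode)
        if tf not in rand.seed_eligible():
            continue
        null_vals.append(
            mri_score(rand, tf, population, temporal_rule=temporal_rule).mri)
    null = np.array(null_vals)
    p_emp = (1 + int((null >= obs.mri).sum())) / (n_random + 1)
    return MRIRecord(
        tf=tf, mri=obs.mri, regulated_count=obs.regulated_count,
        population_size=obs.population_size,
        null_mean=float(null.mean()),
        null_sd=float(null.std(ddof=1)) if n_random > 1 else 0.0,
        p_empirical=p_emp,
        p_parametric=_parametric_p(obs.mri, null))


def rank_tfs(grn: TemporalGRN, population: set[str], n_random: int = 100,
             seed=0, temporal_rule: str = "non_strict",
             null_mode: str = "uniform",
             min_mri: Optional[float] = None,
             max_p: Optional[float] = None) -> list[MRIRecord]:
    """Score every seed-eligible TF and rank by MRI.

    Sort order: MRI descending, then regulated count descending, then TF
    name ascending. A Benjamini-Hochberg FDR over the empirical p-values is
    attached before any filtering. ``min_mri`` / ``max_p`` filter the
    returned table (p filter applies to the empirical p-value).
    """
    tfs = sorted(grn.seed_eligible())
    if not tfs:
        raise ValueError("network has no seed-eligible TF")
    rng = np.random.default_rng(seed)
    records = [
        mri_null(grn, tf, population, n_random=n_random,
                 seed=int(rng.integers(2 ** 31)),
                 temporal_rule=temporal_rule, null_mode=null_mode)
        for tf in tfs
    ]
    fdrs = stats.false_discovery_control(
        [r.p_empirical for r in records], method="bh")
    for r, q in zip(records, fdrs):
        r.fdr = float(q)
    records.sort(key=lambda r: (-r.mri, -r.regulated_count, r.tf))
    if min_mri is not None:
        records = [r for r in records if r.mri >= min_mri]
    if max_p is not None:
        records = [r for r in records if r.p_empirical <= max_p]
    return records
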