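"""Integration of prior edges with discretized trajectories into a GRN.

Rule (i) of the propagation logic is applied at construction time: any prior
edge touching an unresponsive gene is discarded, because signal propagation
terminates at unresponsive nodes. Genes present in the priors but absent
from the transcriptome are treated as unresponsive and counted separately.
The retained network is always a subgraph of the prior graph; every discard
is accounted for so that retained + discarded = deduplicated priors.
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional

from .grn import PriorEdge, StateTrajectory, TemporalGRN

log = logging.getLogger(__name__)

DISCARD_REASONS = ("gene_absent", "unresponsive_tf", "unresponsive_target")


def reconstruct(priors: Iterable[PriorEdge],
                trajectories: dict[str, StateTrajectory],
                tf_list: Optional[set[str]] = None) -> TemporalGRN:
    """Build the transition-specific temporal GRN.

    Parameters
    ----------
    priors
        Prior edges (deduplicated tuples; parallel signs allowed).
    trajectories
        Discretized state trajectories for every measured gene.
    tf_list
        Optional restriction of seed-eligible nodes. When omitted, any node
        with out-edges may seed propagation.

    Returns the network with discard accounting in ``grn.meta["discarded"]``
    (counts per reason) and ``grn.meta["retained_edges"]``.

    Raises
    ------
    ValueError
        If no edge survives filtering — usually a sign the discretization
        thresholds are too strict for this dataset.
    """
    priors = list(dict.fromkeys(priors))  # defensive dedup, order-stable
    responsive = {g for g, t in trajectories.items() if t.responsive}

    discarded = {reason: 0 for reason in DISCARD_REASONS}
    retained: list[PriorEdge] = []
    for e in priors:
        if e.tf not in trajectories or e.target not in trajectories:
            discarded["gene_absent"] += 1
        elif e.tf not in responsive:
            discarded["unresponsive_tf"] += 1
        elif e.target not in responsive:
            discarded["unresponsive_target"] += 1
        else:
            retained.append(e)

    if not retained:
        raise ValueError(
            "no prior edge connects two responsive genes; review the "
            "discretization thresholds and identifier matching")

    grn = TemporalGRN()
    for e in retained:
        for gene in (e.tf, e.target):
            if gene not in grn.graph:
                grn.add_node(trajectories[gene])
        grn.add_edge(e.tf, e.target, e.sign, [e.source])

    if tf_list is not None:
        grn.tfs = {t.strip().upper() for t in tf_list} & set(grn.graph.nodes)

    grn.meta["discarded"] = discarded
    grn.meta["retained_edges"] = len(retained)
    grn.meta["input_edges"] = len(priors)
    log.info("reconstructed GRN: %d nodes, %d merged edges "
             "(retained %d / %d prior rows; discarded %s)",
             grn.graph.number_of_nodes(), grn.n_edges(), len(retained),
             len(priors), discarded)
    return grn
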