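"""Ternary discretization of temporal expression.

Each gene's trajectory is reduced to one of three states per timepoint:
+1 (induced), -1 (repressed), 0 (unchanged), by thresholding the log2
fold-change against the reference. The first timepoint is the reference and
is always state 0. A gene is *responsive* if any later state is non-zero;
unresponsive genes terminate signal propagation and are excluded from the
reconstructed network.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .grn import StateTrajectory
from .io import ExpressionMatrix

log = logging.getLogger(__name__)

#: Default call thresholds: 2-fold change on the log2 scale.
DEFAULT_UP = 1.0
DEFAULT_DOWN = -1.0
DEFAULT_PSEUDOCOUNT = 1.0


def to_log2fc(matrix: ExpressionMatrix, pseudocount: float = DEFAULT_PSEUDOCOUNT,
              reference: str = "baseline") -> ExpressionMatrix:
    """Convert raw expression to log2 fold-changes.

    ``reference="baseline"`` compares every timepoint to the first column;
    ``"previous"`` compares to the preceding column. A pseudocount guards
    against zeros: log2((x + c) / (ref + c)).
    """
    if matrix.mode == "log2fc":
        return matrix
    vals = matrix.values.to_numpy(dtype=float) + pseudocount
    if (vals <= 0).any():
        raise ValueError("expression values must be > -pseudocount")
    if reference == "baseline":
        ref = vals[:, [0]]
    elif reference == "previous":
        ref = np.column_stack([vals[:, [0]], vals[:, :-1]])
    else:
        raise ValueError(f"unknown reference mode {reference!r}")
    import pandas as pd
    lfc = pd.DataFrame(np.log2(vals / ref), index=matrix.values.index,
                       columns=matrix.values.columns)
    return ExpressionMatrix(values=lfc, mode="log2fc")


def discretize(matrix: ExpressionMatrix,
               up_threshold: float = DEFAULT_UP,
               down_threshold: float = DEFAULT_DOWN,
               pseudocount: float = DEFAULT_PSEUDOCOUNT,
               reference: str = "baseline") -> dict[str, StateTrajectory]:
    """Threshold log2 fold-changes into per-gene state trajectories.

    state(g, t) = +1 if log2fc >= up_threshold, -1 if <= down_threshold,
    else 0; the reference timepoint is always 0. Returns a dict keyed by
    gene, preserving matrix row order.
    """
    if not (up_threshold > 0 > down_threshold):
        raise ValueError(
            f"thresholds must satisfy up > 0 > down, got "
            f"up={up_threshold}, down={down_threshold}")
    matrix = to_log2fc(matrix, pseudocount=pseudocount, reference=reference)
    lfc = matrix.values.to_numpy(dtype=float)
    states = np.zeros(lfc.shape, dtype=int)
    states[lfc >= up_threshold] = 1
    states[lfc <= down_threshold] = -1
    states[:, 0] = 0  # reference defines the baseline
    out = {
        gene: StateTrajectory(gene, tuple(int(s) for s in row))
        for gene, row in zip(matrix.genes, states)
    }
    n_resp = sum(t.responsive for t in out.values())
    log.info("discretized %d genes (up>=%g, down<=%g): %d responsive",
             len(out), up_threshold, down_threshold, n_resp)
    return out


def responsive_genes(trajectories: dict[str, StateTrajectory]) -> set[str]:
    """Genes with at least one non-zero state."""
    return {g for g, t in trajectories.items() if t.responsive}
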