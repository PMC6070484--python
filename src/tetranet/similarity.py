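"""Comparison of master-regulator GRNs across cell-fate transitions.

Networks inferred for different transitions are compared by the Tanimoto
(Jaccard) index over their edge sets — (tf, target, sign) triples — or node
sets, clustered hierarchically on 1 - similarity, and aggregated into a
consensus TF ranking across transitions that share a destination cell type.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .grn import MRIRecord, TemporalGRN


def _features(grn: TemporalGRN, on: str) -> set:
    if on == "edges":
        return grn.edge_triples()
    if on == "nodes":
        return set(grn.nodes)
    raise ValueError(f"unknown feature kind {on!r}")


def tanimoto(grn_a: TemporalGRN, grn_b: TemporalGRN, on: str = "edges") -> float:
    """Intersection-over-union similarity of two networks' feature sets."""
    fa, fb = _features(grn_a, on), _features(grn_b, on)
    union = fa | fb
    if not union:
        raise ValueError(f"both networks are empty on {on!r}")
    return len(fa & fb) / len(union)


def cosine_similarity(grn_a: TemporalGRN, grn_b: TemporalGRN,
                      on: str = "edges") -> float:
    """Normalized dot product of binary feature-indicator vectors.

    Offered as an alternative to the Tanimoto index; for binary vectors this
    is |A inter B| / sqrt(|A| |B|).
    """
    fa, fb = _features(grn_a, on), _features(grn_b, on)
    if not fa or not fb:
        raise ValueError(f"a network is empty on {on!r}")
    return len(fa & fb) / float(np.sqrt(len(fa) * len(fb)))


@dataclass
class SimilarityMatrix:
    labels: list[str]
    values: np.ndarray  # symmetric, unit diagonal, entries in [0, 1]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise ValueError("similarity matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0):
            raise ValueError("similarity of a network with itself must be 1")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("similarities must lie in [0, 1]")
        self.values = v


def similarity_matrix(grns: dict[str, TemporalGRN], on: str = "edges",
                      metric: str = "tanimoto") -> SimilarityMatrix:
    """All-pairs similarity between named networks."""
    func = {"tanimoto": tanimoto, "cosine": cosine_similarity}[metric]
    labels = list(grns)
    n = len(labels)
    vals = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            vals[i, j] = vals[j, i] = func(grns[labels[i]], grns[labels[j]], on)
    return SimilarityMatrix(labels=labels, values=vals)


@dataclass
class Dendrogram:
    labels: list[str]
    linkage: np.ndarray  # scipy linkage matrix on distance = 1 - similarity
    newick: str

    @property
    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in hierarchy.leaves_list(self.linkage)]


def cluster_grns(matrix: SimilarityMatrix, linkage: str = "average") -> Dendrogram:
    """Agglomerative clustering of networks on distance = 1 - similarity.

    Average linkage (UPGMA) is the default and only mode; the result is
    deterministic given the matrix. Merge heights are cophenetic distances,
    exported as branch lengths in the Newick string.
    """
    if linkage != "average":
        raise ValueError(f"unsupported linkage {linkage!r}")
    if len(matrix.labels) < 2:
        raise ValueError("clustering needs at least 2 networks")
    dist = 1.0 - matrix.values
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    Z = hierarchy.linkage(condensed, method="average")
    return Dendrogram(labels=list(matrix.labels), linkage=Z,
                      newick=_to_newick(Z, matrix.labels))


def _to_newick(Z: np.ndarray, labels: Sequence[str]) -> str:
    tree = hierarchy.to_tree(Z)

    def rec(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return f"({rec(tree.left, tree.dist)},{rec(tree.right, tree.dist)});"


@dataclass
class ConsensusRecord:
    tf: str
    mean_mri: float
    n_transitions: int  # transitions in which the TF appears
    mean_rank: float    # mean 1-based rank where present (nan if nowhere)


def consensus_rank(records: dict[str, list[MRIRecord]],
                   target_label: Optional[str] = None) -> list[ConsensusRecord]:
    """Aggregate per-transition MRI tables into a consensus TF ranking.

    Transition labels follow the ``source->target`` convention; when
    ``target_label`` is given, only transitions whose destination matches it
    are aggregated. A TF absent from a transition contributes MRI 0 to its
    mean — a regulator that cannot drive a transition has zero
    master-regulator capacity for it. Sort: mean MRI descending, then number
    of supporting transitions, then name.
    """
    def dest(label: str) -> str:
        return label.split("->", 1)[1] if "->" in label else label

    selected = {k: v for k, v in records.items()
                if target_label is None or dest(k) == target_label}
    if not selected:
        raise ValueError(f"no transition targets {target_label!r}")
    n_total = len(selected)
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    ranks: dict[str, list[int]] = {}
    for recs in selected.values():
        ordered = sorted(recs, key=lambda r: (-r.mri, -r.regulated_count, r.tf))
        for pos, r in enumerate(ordered, start=1):
            sums[r.tf] = sums.get(r.tf, 0.0) + r.mri
            counts[r.tf] = counts.get(r.tf, 0) + 1
            ranks.setdefault(r.tf, []).append(pos)
    out = [
        ConsensusRecord(tf=tf, mean_mri=sums[tf] / n_total,
                        n_transitions=counts[tf],
                        mean_rank=float(np.mean(ranks[tf])))
        for tf in sums
    ]
    out.sort(key=lambda r: (-r.mean_mri, -r.n_transitions, r.tf))
    return out
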