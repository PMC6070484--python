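"""Core domain types for temporal gene-regulatory networks.

A temporal GRN is a signed, directed multigraph over genes. Each node carries
a ternary state trajectory (-1/0/+1 per timepoint) derived from a time-series
transcriptome; each edge carries a regulation sign (activation, repression, or
unsigned binding evidence) and the set of source databases that reported it.
Parallel edges between the same TF and target are allowed when their signs
differ (e.g., an activation call from one database and an unsigned binding
call from another).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import networkx as nx

#: Sentinel sign for edges with binding evidence but no known direction
#: (e.g., ChIP-seq-derived priors). Distinct from +1 (activation) and
#: -1 (repression).
UNSIGNED: int = 0

_SIGN_LABELS = {1: "activates", -1: "represses", UNSIGNED: "unsigned"}
_LABEL_SIGNS = {v: k for k, v in _SIGN_LABELS.items()}


def sign_label(sign: int) -> str:
    """Human-readable interaction label for a sign value."""
    try:
        return _SIGN_LABELS[sign]
    except KeyError:
        raise ValueError(f"invalid edge sign {sign!r}; expected +1, -1 or 0")


def label_sign(label: str) -> int:
    try:
        return _LABEL_SIGNS[label]
    except KeyError:
        raise ValueError(f"unknown interaction label {label!r}")


@dataclass(frozen=True)
class PriorEdge:
    """One TF -> target relationship reported by one source database."""

    tf: str
    target: str
    sign: int  # +1, -1 or UNSIGNED
    source: str

    def __post_init__(self) -> None:
        if not self.tf or not self.target:
            raise ValueError("tf and target must be non-empty")
        if self.sign not in (1, -1, UNSIGNED):
            raise ValueError(f"invalid sign {self.sign!r}")


@dataclass(frozen=True)
class StateTrajectory:
    """Per-gene discretized transcriptional state over ordered timepoints.

    ``states[0]`` is always 0: the first timepoint is the reference that
    defines the baseline against which change is called.
    """

    gene: str
    states: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.states) < 2:
            raise ValueError(f"{self.gene}: need at least 2 timepoints")
        if self.states[0] != 0:
            raise ValueError(f"{self.gene}: reference state must be 0")
        if any(s not in (-1, 0, 1) for s in self.states):
            raise ValueError(f"{self.gene}: states must be in {{-1,0,+1}}")

    @property
    def first_change(self) -> Optional[int]:
        """Index of the earliest non-zero state, or None if unresponsive."""
        for i, s in enumerate(self.states):
            if s != 0:
                return i
        return None

    @property
    def first_state(self) -> int:
        """State at the first change (0 for unresponsive genes)."""
        fc = self.first_change
        return 0 if fc is None else self.states[fc]

    @property
    def terminal_state(self) -> int:
        return self.states[-1]

    @property
    def responsive(self) -> bool:
        return self.first_change is not None


class TemporalGRN:
    """Signed, directed, source-annotated multigraph bound to trajectories.

    Every node is responsive (unresponsive genes are filtered out at
    construction) and appears in at least one edge. Parallel edges between
    the same pair differ in sign; the multigraph edge key *is* the sign.
    ``tfs`` is the seed-eligible set: propagation may only start from these.
    """

    def __init__(self) -> None:
        self.graph = nx.MultiDiGraph()
        self.tfs: set[str] = set()
        self.meta: dict = {}  # provenance/accounting; not part of equality

    # -- construction ----------------------------------------------------
    def add_node(self, trajectory: StateTrajectory) -> None:
        self.graph.add_node(trajectory.gene, trajectory=trajectory)

    def add_edge(self, tf: str, target: str, sign: int,
                 sources: Iterable[str]) -> None:
        """Add or merge an edge; source tags accumulate on the (tf, target,
        sign) triple."""
        if tf not in self.graph or target not in self.graph:
            raise KeyError("edge endpoints must be added as nodes first")
        srcs = frozenset(sources)
        if self.graph.has_edge(tf, target, key=sign):
            srcs = self.graph[tf][target][sign]["sources"] | srcs
        self.graph.add_edge(tf, target, key=sign, sources=srcs)

    # -- queries ---------------------------------------------------------
    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def trajectory(self, gene: str) -> StateTrajectory:
        return self.graph.nodes[gene]["trajectory"]

    def edges(self) -> Iterator[tuple[str, str, int, frozenset]]:
        """Yield (tf, target, sign, sources) for every edge."""
        for u, v, sign, data in self.graph.edges(keys=True, data=True):
            yield u, v, sign, data["sources"]

    def edge_triples(self) -> set[tuple[str, str, int]]:
        return {(u, v, s) for u, v, s, _ in self.edges()}

    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def seed_eligible(self) -> set[str]:
        """Nodes allowed as propagation seeds: the declared TF set when one
        was supplied, otherwise any node with at least one out-edge."""
        if self.tfs:
            return self.tfs & set(self.graph.nodes)
        return {n for n in self.graph.nodes if self.graph.out_degree(n) > 0}

    # -- equality (used by round-trip IO tests) --------------------------
    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TemporalGRN):
            return NotImplemented
        if set(self.graph.nodes) != set(other.graph.nodes):
            return False
        for n in self.graph.nodes:
            if self.trajectory(n) != other.trajectory(n):
                return False
        mine = {(u, v, s): srcs for u, v, s, srcs in self.edges()}
        theirs = {(u, v, s): srcs for u, v, s, srcs in other.edges()}
        return mine == theirs and self.tfs == other.tfs

    def __repr__(self) -> str:
        return (f"TemporalGRN({self.graph.number_of_nodes()} nodes, "
                f"{self.n_edges()} edges, {len(self.seed_eligible())} TFs)")


@dataclass
class PropagationResult:
    """Outcome of simulating regulatory signal flow from one seed TF.

    ``regulated`` maps each coherently reached node to its activation time
    (the timepoint index of its own first state change). ``excluded_edges``
    records, for every edge considered but not traversed, why it failed:
    ``incoherent_sign`` (rule ii), ``temporal_order`` (rule iii) or
    ``unreachable_downstream`` (its TF was never reached). Self-loops are
    reported separately: they are retained in the network display but a node
    cannot temporally precede itself.
    """

    seed: str
    regulated: dict[str, int]
    retained_edges: set[tuple[str, str, int]]
    excluded_edges: dict[tuple[str, str, int], str]
    self_loops: set[tuple[str, str, int]] = field(default_factory=set)


@dataclass
class MRIRecord:
    """Master Regulator Index of one TF, optionally with its null summary.

    ``mri`` is the fraction of the target population coherently regulated by
    the TF (the TF itself never counts toward its own numerator).
    """

    tf: str
    mri: float
    regulated_count: int
    population_size: int
    null_mean: Optional[float] = None
    null_sd: Optional[float] = None
    p_empirical: Optional[float] = None
    p_parametric: Optional[float] = None
    fdr: Optional[float] = None
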