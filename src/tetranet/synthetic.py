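"""Ground-truth synthetic fixtures: a planted master-regulator cascade.

The generator emulates the two inputs the pipeline consumes — a multi-source
signed prior edge table and a temporal transcriptome — with a known answer
built in. One designated TF roots a layered regulatory cascade whose
coherent, temporally ordered paths reach a controlled fraction (``coverage``)
of the terminal-state population; decoy TFs drive the remaining terminal
genes so the network is not trivially dominated by the planted regulator,
and optional decoy edges violate the coherence or temporal rules by
construction. Log2 fold-change values are drawn so that discretization at
the default 2-fold thresholds reproduces the designed states exactly;
state-flip noise then perturbs them at a configurable rate.

What this emulates: the statistical skeleton real inputs assume — responsive
TF cascades, terminal-state marker genes, redundant evidence across source
databases, and irrelevant cross-system edges. What it does not: expression
count distributions, replicate variance, or correlated noise; the pipeline
only ever sees the data through ternary discretization, so those aspects are
out of scope by design.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .discretize import DEFAULT_DOWN, DEFAULT_UP
from .grn import UNSIGNED, PriorEdge
from .io import ExpressionMatrix

log = logging.getLogger(__name__)

_BASE_TAGS = ["cellnet", "cage", "qcchipseq"]
_UNSIGNED_TAG = "qcchipseq"  # binding-based evidence carries no direction


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic cascade dataset.

    Defaults describe a 200-gene network observed over six timepoints, a
    planted regulator whose cascade covers half of the terminal population,
    three partially redundant source databases and fifty rule-violating
    decoy edges.
    """

    n_tfs: int = 20
    n_targets: int = 180
    n_timepoints: int = 6
    planted_tf: str = "MR1"
    coverage: float = 0.5
    noise: float = 0.0
    decoy_edges: int = 50
    n_sources: int = 3
    unsigned_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.coverage <= 1.0:
            raise ValueError("coverage must be in [0, 1]")
        if not 0.0 <= self.noise < 0.5:
            raise ValueError("noise must be in [0, 0.5)")
        if self.n_timepoints < 3:
            raise ValueError("need at least 3 timepoints")
        if self.n_tfs < 3:
            raise ValueError("need at least 3 TFs (planted + 2 decoys)")
        if self.n_targets < 1:
            raise ValueError("need at least 1 target gene")
        if self.n_sources < 1:
            raise ValueError("need at least 1 source tag")
        if not 0.0 <= self.unsigned_fraction <= 1.0:
            raise ValueError("unsigned_fraction must be in [0, 1]")
        self.planted_tf = self.planted_tf.strip().upper()
        if not self.planted_tf:
            raise ValueError("planted_tf must be non-empty")


@dataclass
class SyntheticDataset:
    spec: SyntheticSpec
    priors: list[PriorEdge]
    expression: ExpressionMatrix
    tf_list: list[str]
    truth: dict = field(repr=False)

    def write(self, out_dir) -> dict[str, Path]:
        """Write priors.tsv, expression.tsv, tfs.txt and truth.json.

        Output is byte-stable: the same spec (seed included) always produces
        identical files.
        """
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "priors": out / "priors.tsv",
            "expression": out / "expression.tsv",
            "tfs": out / "tfs.txt",
            "truth": out / "truth.json",
        }
        with open(paths["priors"], "w") as fh:
            fh.write("# tf\ttarget\tsign\tsource\n")
            for e in self.priors:
                tok = {1: "+", -1: "-", UNSIGNED: "NA"}[e.sign]
                fh.write(f"{e.tf}\t{e.target}\t{tok}\t{e.source}\n")
        with open(paths["expression"], "w") as fh:
            fh.write("gene\t" + "\t".join(self.expression.timepoints) + "\n")
            for gene, row in self.expression.values.iterrows():
                vals = "\t".join(f"{v:.4f}" for v in row)
                fh.write(f"{gene}\t{vals}\n")
        paths["tfs"].write_text("\n".join(self.tf_list) + "\n")
        paths["truth"].write_text(
            json.dumps(self.truth, indent=1, sort_keys=True) + "\n")
        return paths


def generate(spec: SyntheticSpec) -> SyntheticDataset:
    """Build the planted-cascade dataset for ``spec``.

    Raises ``ValueError`` when the requested coverage cannot be realised
    with the given gene counts (e.g., rank-one recovery of the planted TF
    would not be guaranteed because a decoy would tie it).
    """
    rng = np.random.default_rng(spec.seed)
    T = spec.n_timepoints
    k = math.ceil(spec.coverage * spec.n_targets)

    tf_names = [spec.planted_tf] + [f"TF{i:03d}" for i in range(2, spec.n_tfs + 1)]
    tg_names = [f"TG{i:03d}" for i in range(1, spec.n_targets + 1)]

    # Split the non-planted TFs into cascade intermediates and decoy roots.
    others = tf_names[1:]
    n_int = len(others) // 2 if T >= 4 else 0
    intermediates = others[:n_int]
    decoys = others[n_int:]
    if len(decoys) < 2:
        raise ValueError("too few TFs to place 2 decoy regulators")

    cascade_targets = tg_names[:k]
    free_targets = tg_names[k:]
    if k > 0 and free_targets and math.ceil(len(free_targets) / len(decoys)) >= k:
        raise ValueError(
            f"coverage {spec.coverage} unreachable with {spec.n_targets} "
            f"targets and {spec.n_tfs} TFs: a decoy regulator would match "
            f"the planted cascade")

    states: dict[str, int] = {}      # designed first/persistent state
    fc: dict[str, int] = {}          # designed first-change index
    terminal: dict[str, bool] = {}   # persists to the last timepoint?

    def add_gene(name, first_change, is_terminal):
        states[name] = int(rng.choice([-1, 1]))
        fc[name] = first_change
        terminal[name] = is_terminal

    add_gene(spec.planted_tf, 1, False)
    for tf in intermediates:
        add_gene(tf, 2, False)
    for tf in decoys:
        add_gene(tf, 1, False)

    # Cascade targets hang off the planted TF and the intermediates,
    # round-robin, with a first change no earlier than their parent's.
    # Feed-forward motifs (planted -> intermediate -> target plus a direct
    # planted -> target edge) mirror the hub-like wiring of real master
    # regulators and give each target redundant coherent paths, so noise on
    # a single intermediate degrades recovery gracefully instead of
    # severing a whole subtree.
    true_edges: list[tuple[str, str]] = []
    parents = [spec.planted_tf] + intermediates
    for tf in intermediates:
        true_edges.append((spec.planted_tf, tf))
    for i, tg in enumerate(cascade_targets):
        parent = parents[i % len(parents)]
        add_gene(tg, int(rng.integers(fc[parent], T)), True)
        true_edges.append((parent, tg))
        if parent != spec.planted_tf:
            true_edges.append((spec.planted_tf, tg))
    for i, tg in enumerate(free_targets):
        decoy = decoys[i % len(decoys)]
        add_gene(tg, 1, True)
        true_edges.append((decoy, tg))

    # Coherent sign for every true edge; split across source databases with
    # redundancy. Signed sources (expression- and promoter-derived) carry
    # the regulatory direction; the binding-only database corroborates a
    # fraction of edges with an additional unsigned record. Binding-only
    # evidence passes the coherence rule unconditionally, so its rate also
    # controls how permissive edge-randomized null networks are.
    tags = (_BASE_TAGS + [f"src{i}" for i in range(4, spec.n_sources + 1)])[
        :spec.n_sources]
    signed_tags = [t for t in tags if t != _UNSIGNED_TAG] or tags
    has_unsigned = _UNSIGNED_TAG in tags
    priors: list[PriorEdge] = []
    for u, v in true_edges:
        sign = states[u] * states[v]
        n_tags = 1 + int(rng.random() < 0.35)
        chosen = rng.choice(signed_tags, size=min(n_tags, len(signed_tags)),
                            replace=False)
        for tag in sorted(chosen):
            priors.append(PriorEdge(u, v, sign, str(tag)))
        if has_unsigned and rng.random() < spec.unsigned_fraction:
            priors.append(PriorEdge(u, v, UNSIGNED, _UNSIGNED_TAG))

    # Decoy edges violate rule (ii) (wrong sign) or rule (iii) (target
    # changes before its putative regulator); never unsigned, so none can
    # slip through coherence checking.
    existing = {(e.tf, e.target) for e in priors}
    cascade_nodes = [spec.planted_tf] + intermediates + cascade_targets
    decoy_pairs: list[tuple[str, str]] = []
    n_added = 0
    attempts = 0
    while n_added < spec.decoy_edges and attempts < 50 * max(spec.decoy_edges, 1):
        attempts += 1
        if rng.random() < 0.5 or not intermediates:
            u = cascade_nodes[int(rng.integers(len(cascade_nodes)))]
            pool = free_targets or tg_names
            v = pool[int(rng.integers(len(pool)))]
            if u == v or (u, v) in existing:
                continue
            sign = -states[u] * states[v]  # incoherent by construction
            if fc[v] < fc[u]:
                sign = states[u] * states[v]  # already a temporal violation
        else:
            u = intermediates[int(rng.integers(len(intermediates)))]
            pool = [g for g in (free_targets or tg_names) if fc[g] < fc[u]]
            if not pool:
                continue
            v = pool[int(rng.integers(len(pool)))]
            if (u, v) in existing:
                continue
            sign = states[u] * states[v]  # coherent sign, wrong time order
        tag = signed_tags[int(rng.integers(len(signed_tags)))]
        priors.append(PriorEdge(u, v, sign, tag))
        existing.add((u, v))
        decoy_pairs.append((u, v))
        n_added += 1
    if n_added < spec.decoy_edges:
        log.warning("placed only %d of %d requested decoy edges",
                    n_added, spec.decoy_edges)

    # Designed ternary state matrix, then optional state-flip noise.
    genes = tf_names + tg_names
    design = np.zeros((len(genes), T), dtype=int)
    for gi, g in enumerate(genes):
        stop = T if terminal[g] else T - 1
        design[gi, fc[g]:stop] = states[g]
    noisy = design.copy()
    if spec.noise > 0:
        flip = rng.random(design.shape) < spec.noise
        flip[:, 0] = False
        offsets = rng.integers(1, 3, size=design.shape)
        # map each flipped state to one of the other two values in {-1,0,1}
        noisy = np.where(flip, ((design + 1 + offsets) % 3) - 1, design)

    # Log2 fold-changes that discretize back to the (noisy) states at the
    # default 2-fold thresholds, with unambiguous margins.
    margin = np.abs(rng.normal(0.5, 0.2, size=design.shape))
    lfc = np.where(noisy != 0, noisy * (DEFAULT_UP + margin),
                   np.clip(rng.normal(0.0, 0.25, size=design.shape),
                           DEFAULT_DOWN * 0.8, DEFAULT_UP * 0.8))
    lfc[:, 0] = 0.0

    expr = ExpressionMatrix(
        values=pd.DataFrame(np.round(lfc, 4), index=genes,
                            columns=[f"t{i}" for i in range(T)]),
        mode="log2fc")

    regulated_tfs = list(intermediates)
    truth = {
        "planted_tf": spec.planted_tf,
        "true_regulated_targets": sorted(cascade_targets),
        "true_regulated_tfs": sorted(regulated_tfs),
        "terminal_population": sorted(tg_names),
        "true_mri": (k / spec.n_targets) if spec.n_targets else 0.0,
        "coverage": spec.coverage,
        "spec": asdict(spec),
        "n_decoy_edges_placed": n_added,
        "decoy_edge_list": sorted(f"{u}->{v}" for u, v in decoy_pairs),
    }

    return SyntheticDataset(spec=spec, priors=priors, expression=expr,
                            tf_list=tf_names, truth=truth)
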