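"""Readers and writers for prior edge tables, expression matrices and networks.

File conventions
----------------
* Prior edges: tab-separated, 2-4 columns — tf, target, [sign], [source].
  Sign tokens ``+ - 1 -1 +1`` map to +/-1; ``NA``, ``.`` or a missing column
  mean unsigned. A 4th column overrides the caller-supplied source tag.
* Expression: tab-separated, header row = ordered timepoint labels, first
  column = gene identifiers. Values are either raw expression or precomputed
  log2 fold-changes versus the first timepoint (declared by ``mode``).
* Networks: SIF (Cytoscape-style, write-only), GraphML and JSON
  (round-trippable with full node/edge attributes).

Comment lines starting with ``#`` are ignored in TSV inputs. Gene identifiers
are upper-cased and whitespace-trimmed on load so that symbols match between
transcriptomes and prior tables regardless of capitalisation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import networkx as nx
import numpy as np
import pandas as pd

from .grn import UNSIGNED, PriorEdge, StateTrajectory, TemporalGRN, label_sign, sign_label

log = logging.getLogger(__name__)

_SIGN_TOKENS = {
    "+": 1, "1": 1, "+1": 1,
    "-": -1, "-1": -1,
    "NA": UNSIGNED, ".": UNSIGNED, "": UNSIGNED,
}


@dataclass
class ExpressionMatrix:
    """Genes x ordered-timepoints real matrix.

    ``mode`` declares the value scale: ``"log2fc"`` (fold-changes versus the
    first timepoint) or ``"expression"`` (raw values; conversion to log2fc
    happens at discretization). The header order is the temporal order.
    """

    values: pd.DataFrame  # index = genes, columns = timepoint labels
    mode: str = "log2fc"
    dropped_rows: int = field(default=0, compare=False)

    def __post_init__(self) -> None:
        if self.mode not in ("expression", "log2fc"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.values.shape[1] < 2:
            raise ValueError("need at least 2 timepoints")
        dup = self.values.index[self.values.index.duplicated()]
        if len(dup):
            raise ValueError(f"duplicated gene identifier: {dup[0]}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def timepoints(self) -> list[str]:
        return list(self.values.columns)


def _normalize_gene(name: str) -> str:
    return name.strip().upper()


def read_prior_edges(path, source_tag: str,
                     synonyms: Optional[dict[str, str]] = None) -> list[PriorEdge]:
    """Load a TF->target prior table, normalising and deduplicating rows.

    Parameters
    ----------
    path
        Tab-separated file with columns tf, target, [sign], [source].
    source_tag
        Database tag applied to rows lacking a 4th column.
    synonyms
        Optional identifier map applied (after upper-casing) to both tf and
        target, for reconciling symbol conventions across databases.

    Duplicate (tf, target, sign, source) tuples are collapsed; the number of
    collapsed duplicates is logged.
    """
    syn = {k.upper(): v.upper() for k, v in (synonyms or {}).items()}
    seen: dict[PriorEdge, None] = {}
    duplicates = 0
    n_rows = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if not 2 <= len(fields) <= 4:
                raise ValueError(
                    f"{path}:{lineno}: expected 2-4 tab-separated columns, "
                    f"got {len(fields)}")
            tf = _normalize_gene(fields[0])
            target = _normalize_gene(fields[1])
            if not tf or not target:
                raise ValueError(f"{path}:{lineno}: empty gene identifier")
            tf = syn.get(tf, tf)
            target = syn.get(target, target)
            sign_tok = fields[2].strip() if len(fields) >= 3 else ""
            if sign_tok not in _SIGN_TOKENS:
                raise ValueError(
                    f"{path}:{lineno}: unrecognised sign token {sign_tok!r}")
            sign = _SIGN_TOKENS[sign_tok]
            source = fields[3].strip() if len(fields) == 4 and fields[3].strip() \
                else source_tag
            edge = PriorEdge(tf, target, sign, source)
            n_rows += 1
            if edge in seen:
                duplicates += 1
            else:
                seen[edge] = None
    if n_rows == 0:
        raise ValueError(f"{path}: no edges found (empty file)")
    if duplicates:
        log.info("%s: collapsed %d duplicate prior rows", path, duplicates)
    edges = list(seen)
    log.info("%s: loaded %d unique prior edges (source tag %r)",
             path, len(edges), source_tag)
    return edges


def read_expression(path, mode: str = "log2fc") -> ExpressionMatrix:
    """Load a gene x timepoint TSV into an :class:`ExpressionMatrix`.

    Rows containing missing values are dropped with a logged count;
    non-numeric cells are a hard error naming the offending coordinate.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need at least 2 timepoint columns, "
                         f"got {df.shape[1]}")
    df.index = [_normalize_gene(str(g)) for g in df.index]
    dup = pd.Index(df.index)[pd.Index(df.index).duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicated gene identifier {dup[0]!r}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.any().any():
        gene = bad.any(axis=1).idxmax()
        col = bad.loc[gene].idxmax()
        raise ValueError(
            f"{path}: non-numeric value {df.loc[gene, col]!r} at "
            f"gene {gene!r}, timepoint {col!r}")
    complete = numeric.dropna()
    dropped = len(numeric) - len(complete)
    if dropped:
        log.info("%s: dropped %d rows with missing values", path, dropped)
    return ExpressionMatrix(values=complete.astype(float), mode=mode,
                            dropped_rows=dropped)


# ---------------------------------------------------------------------------
# Network serialization
# ---------------------------------------------------------------------------

def write_network(grn: TemporalGRN, path, format: str = "graphml") -> None:
    """Serialize a temporal GRN.

    ``sif`` writes Cytoscape-compatible ``tf<TAB>interaction<TAB>target``
    lines (lossy: no trajectories). ``graphml`` and ``json`` carry node
    trajectories, edge signs and source sets, and round-trip exactly through
    :func:`read_network`.
    """
    path = Path(path)
    if format == "sif":
        _write_sif(grn, path)
    elif format == "graphml":
        nx.write_graphml(_to_flat_graph(grn), path)
    elif format == "json":
        path.write_text(json.dumps(_to_dict(grn), indent=1, sort_keys=True)
                        + "\n")
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network(path, format: Optional[str] = None) -> TemporalGRN:
    """Inverse of :func:`write_network` for graphml/json."""
    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").lower()
    if format == "graphml":
        return _from_flat_graph(nx.read_graphml(path, force_multigraph=True))
    if format == "json":
        return _from_dict(json.loads(path.read_text()))
    raise ValueError(f"cannot read network format {format!r}")


def _write_sif(grn: TemporalGRN, path: Path) -> None:
    lines = []
    for u, v, sign, _ in sorted(grn.edges(), key=lambda e: (e[0], e[1], e[2])):
        lines.append(f"{u}\t{sign_label(sign)}\t{v}")
    # isolated nodes (none normally, but keep the file valid if present)
    connected = {u for u, v, *_ in grn.edges()} | {v for _, v, *_ in grn.edges()}
    for n in sorted(set(grn.nodes) - connected):
        lines.append(n)
    path.write_text("\n".join(lines) + ("\n" if lines else ""))


def _to_dict(grn: TemporalGRN) -> dict:
    return {
        "nodes": {
            n: {"states": list(grn.trajectory(n).states),
                "is_tf": n in grn.tfs}
            for n in sorted(grn.nodes)
        },
        "edges": [
            {"tf": u, "target": v, "sign": sign,
             "sources": sorted(srcs)}
            for u, v, sign, srcs in sorted(grn.edges(),
                                           key=lambda e: (e[0], e[1], e[2]))
        ],
    }


def _from_dict(data: dict) -> TemporalGRN:
    grn = TemporalGRN()
    for gene, attrs in data["nodes"].items():
        grn.add_node(StateTrajectory(gene, tuple(attrs["states"])))
        if attrs.get("is_tf"):
            grn.tfs.add(gene)
    for e in data["edges"]:
        grn.add_edge(e["tf"], e["target"], int(e["sign"]), e["sources"])
    return grn


def _to_flat_graph(grn: TemporalGRN) -> nx.MultiDiGraph:
    """GraphML only allows scalar attributes; flatten tuples/sets to strings."""
    g = nx.MultiDiGraph()
    for n in grn.nodes:
        t = grn.trajectory(n)
        g.add_node(n, states=",".join(str(s) for s in t.states),
                   is_tf=n in grn.tfs)
    for u, v, sign, srcs in grn.edges():
        g.add_edge(u, v, key=str(sign), sign=int(sign),
                   interaction=sign_label(sign),
                   sources="|".join(sorted(srcs)))
    return g


def _from_flat_graph(g: nx.MultiDiGraph) -> TemporalGRN:
    grn = TemporalGRN()
    for n, attrs in g.nodes(data=True):
        states = tuple(int(s) for s in attrs["states"].split(","))
        grn.add_node(StateTrajectory(n, states))
        if attrs.get("is_tf"):
            grn.tfs.add(n)
    for u, v, _k, attrs in g.edges(keys=True, data=True):
        sign = int(attrs["sign"]) if "sign" in attrs \
            else label_sign(attrs["interaction"])
        sources = [s for s in attrs.get("sources", "").split("|") if s]
        grn.add_edge(u, v, sign, sources)
    return grn


def write_mri_table(records, path, provenance: Optional[dict] = None) -> None:
    """Write a ranked MRI table as TSV with optional '#' provenance header."""
    cols = ["tf", "mri", "regulated_count", "population_size",
            "null_mean", "null_sd", "p_empirical", "p_parametric", "fdr"]
    rows = [{c: getattr(r, c) for c in cols} for r in records]
    df = pd.DataFrame(rows, columns=cols)
    with open(path, "w") as fh:
        for key, val in (provenance or {}).items():
            fh.write(f"# {key}: {val}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def write_similarity_matrix(labels, values, path,
                            provenance: Optional[dict] = None) -> None:
    df = pd.DataFrame(np.asarray(values), index=labels, columns=labels)
    with open(path, "w") as fh:
        for key, val in (provenance or {}).items():
            fh.write(f"# {key}: {val}\n")
        df.to_csv(fh, sep="\t", float_format="%.6g")
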