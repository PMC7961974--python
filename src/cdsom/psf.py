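"""Pathway signal flow (PSF) over signed, acyclic pathway topologies.

Each node carries a positive expression-derived value (fold change versus
the cohort mean; unmapped nodes default to 1). Processing nodes in
topological order, a source's signal is its own value; any other node's
signal is its value times the sum of incoming edge contributions — the
parent signal for an activating edge, its reciprocal for an inhibiting
edge. Group-level pathway activity uses group-mean centralized log2
expression exponentiated back to fold-change scale, which guarantees
positivity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import networkx as nx
import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix


@dataclass
class PathwayGraph:
    graph: nx.DiGraph  # edges carry sign in {+1, -1}
    sources: list  # in-degree 0
    sinks: list  # out-degree 0

    @property
    def nodes(self) -> list:
        return list(self.graph.nodes)


@dataclass
class PSFResult:
    node_signals: dict  # node -> positive signal
    sink_signals: dict
    label: str = ""


def build_pathway(edges) -> PathwayGraph:
    """Build a pathway graph from (source, target, sign) triples."""
    g = nx.DiGraph()
    for u, v, sign in edges:
        if sign not in (1, -1):
            raise ValueError(f"edge sign must be +1 or -1, got {sign!r}")
        g.add_edge(u, v, sign=int(sign))
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError("pathway topology must be acyclic")
    sources = [n for n in g.nodes if g.in_degree(n) == 0]
    sinks = [n for n in g.nodes if g.out_degree(n) == 0]
    return PathwayGraph(graph=g, sources=sources, sinks=sinks)


def read_pathway_tsv(path) -> PathwayGraph:
    """Read an edge-list TSV with rows ``source<TAB>target<TAB>+1|-1``."""
    edges = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 tab-separated fields")
            u, v, tok = fields
            if tok not in ("+1", "-1", "1"):
                raise ValueError(f"{path}:{lineno}: unknown sign token {tok!r}")
            edges.append((u, v, 1 if tok in ("+1", "1") else -1))
    return build_pathway(edges)


def pathway_signal_flow(
    g: PathwayGraph, node_values: Mapping[str, float], label: str = ""
) -> PSFResult:
    """Propagate node values through the pathway in topological order."""
    values = {}
    for n in g.nodes:
        v = float(node_values.get(n, 1.0))
        if not np.isfinite(v) or v <= 0:
            raise ValueError(f"node value for {n!r} must be positive, got {v}")
        values[n] = v
    signal: dict = {}
    for n in nx.topological_sort(g.graph):
        if g.graph.in_degree(n) == 0:
            signal[n] = values[n]
            continue
        incoming = 0.0
        for parent, _, data in g.graph.in_edges(n, data=True):
            contrib = signal[parent] if data["sign"] == 1 else 1.0 / signal[parent]
            incoming += contrib
        signal[n] = values[n] * incoming
    return PSFResult(
        node_signals=signal,
        sink_signals={n: signal[n] for n in g.sinks},
        label=label,
    )


def group_psf(
    g: PathwayGraph,
    m: ExpressionMatrix,
    grouping: pd.Series,
) -> dict:
    """Per-group PSF from group-mean fold changes (2^mean centralized log2)."""
    if m.stage != "centralized":
        raise ValueError("group_psf expects a centralized matrix")
    grouping = pd.Series(grouping)
    results = {}
    for grp in pd.unique(grouping):
        members = [s for s in m.sample_ids if grouping.get(s) == grp]
        mean_de = m.data[members].mean(axis=1)
        fc = np.power(2.0, mean_de)
        node_values = {gene: float(v) for gene, v in fc.items() if gene in g.graph}
        results[grp] = pathway_signal_flow(g, node_values, label=str(grp))
    return results
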