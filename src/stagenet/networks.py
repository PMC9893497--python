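"""DEG filtering by effect size and interaction confidence; graph building.

A called DEG survives the network filter when its fold change is large
(|logFC| strictly above 1.5 by default) *and* it has at least one
sufficiently confident interaction (confidence strictly above 0.75) whose
other endpoint also passes the fold-change cut. Stage-specific
functional-interaction (FI) graphs are the induced subgraphs of the
interaction table on the filtered genes; the protein-protein interaction
(PPI) graph is built the same way but with a non-strict score threshold.
"""

from __future__ import annotations

from typing import Iterable

import networkx as nx

from .datatypes import InteractionNetwork
from .deg import DEGSet

__all__ = [
    "filter_degs",
    "build_stage_network",
    "build_ppi_graph",
    "filter_report_row",
]


def filter_degs(
    degset: DEGSet,
    interactions: Iterable[tuple[str, str, float]],
    lfc_cut: float = 1.5,
    conf_cut: float = 0.75,
) -> frozenset[str]:
    """Genes passing both the fold-change and the edge-confidence filter.

    Both inequalities are strict; the confident edge must connect two genes
    that both pass the fold-change cut.
    """
    strong = {g for g in degset.genes if abs(degset.logfc_map.get(g, 0.0)) > lfc_cut}
    connected: set[str] = set()
    for a, b, conf in interactions:
        if conf > conf_cut and a in strong and b in strong:
            connected.add(a)
            connected.add(b)
    return frozenset(connected)


def _induced(
    genes: frozenset[str] | set[str],
    interactions: Iterable[tuple[str, str, float]],
    cut: float,
    strict: bool,
    kind: str,
) -> InteractionNetwork:
    g = nx.Graph()
    g.add_nodes_from(genes)
    for a, b, conf in interactions:
        if a == b or a not in genes or b not in genes:
            continue
        if (conf > cut) if strict else (conf >= cut):
            g.add_edge(a, b, confidence=float(conf))
    return InteractionNetwork(graph=g, kind=kind)


def build_stage_network(
    genes: frozenset[str] | set[str],
    interactions: Iterable[tuple[str, str, float]],
    conf_cut: float = 0.75,
) -> InteractionNetwork:
    """Stage FI graph: induced subgraph keeping edges with confidence > cut.

    Isolated genes stay in the node set; an empty edge set is legal.
    """
    if not genes:
        raise ValueError("gene set is empty")
    return _induced(genes, interactions, conf_cut, strict=True, kind="FI")


def build_ppi_graph(
    genes: frozenset[str] | set[str],
    interactions: Iterable[tuple[str, str, float]],
    score_cut: float = 0.75,
) -> InteractionNetwork:
    """PPI graph at a score criterion (non-strict >=)."""
    if not genes:
        raise ValueError("gene set is empty")
    return _induced(genes, interactions, score_cut, strict=False, kind="PPI")


def filter_report_row(stage, degset: DEGSet, filtered: frozenset[str]) -> dict:
    """Before/after counts for the per-stage filter report."""
    return {
        "stage": stage.value,
        "all_degs": len(degset.genes),
        "filtered_degs": len(filtered),
    }
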