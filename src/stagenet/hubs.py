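"""Hub-gene identification on the PPI graph.

Hubs are ranked by degree (incident edge count); betweenness centrality —
for node v, the sum over unordered node pairs (s, t) of the fraction of
shortest s-t paths passing through v, endpoints excluded, unnormalized —
is reported and used only to break degree ties.
"""

from __future__ import annotations

import networkx as nx
import pandas as pd

from .datatypes import InteractionNetwork

__all__ = ["centralities", "top_hubs", "hub_subnetwork"]


def centralities(network: InteractionNetwork) -> pd.DataFrame:
    """Per-node degree and unnormalized betweenness (unweighted geodesics)."""
    g = network.graph
    btw = nx.betweenness_centrality(g, normalized=False, weight=None)
    rows = [
        {"gene": node, "degree": g.degree(node), "betweenness": btw[node]}
        for node in g.nodes
    ]
    return pd.DataFrame(rows, columns=["gene", "degree", "betweenness"])


def top_hubs(network: InteractionNetwork, k: int = 10) -> pd.DataFrame:
    """Top-``k`` genes by degree, descending.

    Ties break by betweenness descending, then lexicographic gene id; the
    returned table carries a 1-based ``rank`` column.
    """
    cent = centralities(network)
    if k > len(cent):
        raise ValueError(f"k={k} exceeds node count {len(cent)}")
    cent = cent.sort_values(
        by=["degree", "betweenness", "gene"],
        ascending=[False, False, True],
        kind="stable",
    ).head(k)
    cent = cent.reset_index(drop=True)
    cent["rank"] = cent.index + 1
    return cent


def hub_subnetwork(network: InteractionNetwork, hubs: pd.DataFrame) -> InteractionNetwork:
    """Induced subgraph on the hub genes.

    Each node keeps its degree in the *full* graph as the ``full_degree``
    attribute (the usual colour-mapping key, highest degree most intense).
    """
    genes = list(hubs["gene"])
    sub = network.graph.subgraph(genes).copy()
    for gene in genes:
        sub.nodes[gene]["full_degree"] = network.graph.degree(gene)
    return InteractionNetwork(graph=sub, kind=network.kind)
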