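"""Cluster-interaction and functional-evolution networks.

Two layers sit on top of the per-stage module partitions:

* **intra-stage**: each retained module becomes a vertex; the edge weight
  between two modules counts the stage-graph edges crossing between them
  (within-module edge counts are kept as node attributes, not self-edges);
* **inter-stage**: modules of adjacent stages (I-II, II-III, III-IV) are
  linked with weight = number of shared genes.

Combining the four intra-stage graphs with the three adjacent-stage
overlap graphs yields the functional evolutionary network, whose connected
components trace how gene modules persist and rewire across tumour
progression; a component touching all four stages is the informative one.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .datatypes import InteractionNetwork, Stage, TUMOUR_STAGES
from .mcl import ModulePartition

__all__ = [
    "EvolutionNetwork",
    "stage_node_id",
    "cluster_interaction_network",
    "adjacent_overlap_network",
    "combine_evolution_network",
    "largest_connected_component",
]


def stage_node_id(stage: Stage, module_id: int) -> str:
    """Stage-qualified cluster id, e.g. ``S2:c7``."""
    return f"S{TUMOUR_STAGES.index(stage) + 1}:c{module_id}"


@dataclass
class EvolutionNetwork:
    """Multi-stage cluster graph.

    Nodes are stage-qualified cluster ids with attributes ``stage``,
    ``module_id``, ``members`` and ``internal_edges``; edges carry an
    integer ``weight`` and an ``etype`` of ``intra`` or ``inter``.
    """

    graph: nx.Graph

    def stages_present(self) -> set[Stage]:
        return {d["stage"] for _, d in self.graph.nodes(data=True)}

    @property
    def all_stages_present(self) -> bool:
        return self.stages_present() == set(TUMOUR_STAGES)

    def node_table(self) -> list[dict]:
        rows = []
        for node, d in sorted(self.graph.nodes(data=True)):
            rows.append(
                {
                    "node": node,
                    "stage": d["stage"].value,
                    "size": len(d["members"]),
                    "internal_edges": d["internal_edges"],
                }
            )
        return rows


def cluster_interaction_network(
    stage_graph: InteractionNetwork, modules: ModulePartition
) -> nx.Graph:
    """Intra-stage module graph: crossing-edge counts between retained modules.

    Node ids are the module's index in the partition; ``internal_edges``
    (edges with both endpoints inside the module) is stored per node.
    Module pairs with no crossing edge get no edge.
    """
    g = stage_graph.graph
    retained = [
        (i, mod) for i, (mod, r) in enumerate(zip(modules.modules, modules.retained)) if r
    ]
    for i, mod in retained:
        missing = mod - set(g.nodes)
        if missing:
            raise ValueError(
                f"module {i} gene {sorted(missing)[0]!r} absent from stage graph"
            )
    member_of: dict[str, int] = {}
    for i, mod in retained:
        for gene in mod:
            member_of[gene] = i

    out = nx.Graph()
    for i, mod in retained:
        out.add_node(i, members=frozenset(mod), internal_edges=0)
    for u, v in g.edges:
        mu, mv = member_of.get(u), member_of.get(v)
        if mu is None or mv is None:
            continue
        if mu == mv:
            out.nodes[mu]["internal_edges"] += 1
        else:
            if out.has_edge(mu, mv):
                out[mu][mv]["weight"] += 1
            else:
                out.add_edge(mu, mv, weight=1)
    return out


def adjacent_overlap_network(
    modules_a: ModulePartition,
    stage_a: Stage,
    modules_b: ModulePartition,
    stage_b: Stage,
    min_overlap: int = 1,
) -> list[tuple[int, int, int]]:
    """Shared-gene counts between retained modules of two *adjacent* stages."""
    ia, ib = TUMOUR_STAGES.index(stage_a), TUMOUR_STAGES.index(stage_b)
    if ib - ia != 1:
        raise ValueError(
            f"stages {stage_a.value} and {stage_b.value} are not adjacent"
        )
    edges = []
    for i, (mod_a, ra) in enumerate(zip(modules_a.modules, modules_a.retained)):
        if not ra:
            continue
        for j, (mod_b, rb) in enumerate(zip(modules_b.modules, modules_b.retained)):
            if not rb:
                continue
            overlap = len(mod_a & mod_b)
            if overlap >= min_overlap:
                edges.append((i, j, overlap))
    return edges


def combine_evolution_network(
    intra: dict[Stage, nx.Graph],
    inter: dict[tuple[Stage, Stage], list[tuple[int, int, int]]],
) -> EvolutionNetwork:
    """Union of the four intra-stage graphs and three inter-stage overlap maps.

    Node ids become stage-qualified; the result is independent of the
    order the seven inputs are supplied in.
    """
    g = nx.Graph()
    for stage in sorted(intra, key=TUMOUR_STAGES.index):
        sg = intra[stage]
        for mid, d in sg.nodes(data=True):
            node = stage_node_id(stage, mid)
            if node in g:
                raise ValueError(f"conflicting definition for cluster {node}")
            g.add_node(
                node,
                stage=stage,
                module_id=mid,
                members=d["members"],
                internal_edges=d.get("internal_edges", 0),
            )
        for u, v, d in sg.edges(data=True):
            g.add_edge(
                stage_node_id(stage, u),
                stage_node_id(stage, v),
                weight=int(d["weight"]),
                etype="intra",
            )
    for (stage_a, stage_b), edges in sorted(
        inter.items(), key=lambda kv: TUMOUR_STAGES.index(kv[0][0])
    ):
        if TUMOUR_STAGES.index(stage_b) - TUMOUR_STAGES.index(stage_a) != 1:
            raise ValueError("inter-stage edges must join adjacent stages")
        for i, j, w in edges:
            a, b = stage_node_id(stage_a, i), stage_node_id(stage_b, j)
            if a not in g or b not in g:
                raise ValueError(f"overlap edge references unknown cluster {a} or {b}")
            g.add_edge(a, b, weight=int(w), etype="inter")
    return EvolutionNetwork(graph=g)


def largest_connected_component(net: EvolutionNetwork) -> EvolutionNetwork:
    """Subnetwork induced by the largest component (ties: smallest node id)."""
    if net.graph.number_of_nodes() == 0:
        return net
    components = sorted(
        nx.connected_components(net.graph), key=lambda c: (-len(c), min(c))
    )
    return EvolutionNetwork(graph=net.graph.subgraph(components[0]).copy())
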