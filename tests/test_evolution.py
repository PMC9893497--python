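"""Cluster-interaction graphs, adjacent-stage overlaps, combined network."""

import networkx as nx
import numpy as np
import pytest

from stagenet.datatypes import InteractionNetwork, Stage, TUMOUR_STAGES
from stagenet.evolution import (
    adjacent_overlap_network,
    cluster_interaction_network,
    combine_evolution_network,
    largest_connected_component,
    stage_node_id,
)
from stagenet.mcl import ModulePartition


def partition(*modules, graph=None):
    mods = [frozenset(m) for m in modules]
    return ModulePartition(modules=mods, retained=[True] * len(mods), graph=graph)


def net_from(edges, nodes=()):
    return InteractionNetwork.from_edges([(a, b, 0.9) for a, b in edges], nodes=nodes)


class TestClusterInteraction:
    def test_crossing_edges_counted(self):
        net = net_from([("a", "c"), ("b", "d")])
        g = cluster_interaction_network(net, partition({"a", "b"}, {"c", "d"}))
        assert g[0][1]["weight"] == 2

    def test_no_crossing_edges_no_edge(self):
        net = net_from([("a", "b"), ("c", "d")])
        g = cluster_interaction_network(net, partition({"a", "b"}, {"c", "d"}))
        assert g.number_of_edges() == 0
        assert g.nodes[0]["internal_edges"] == 1

    def test_weight_symmetric(self):
        net = net_from([("a", "c"), ("a", "d"), ("b", "c")])
        p12 = cluster_interaction_network(net, partition({"a", "b"}, {"c", "d"}))
        p21 = cluster_interaction_network(net, partition({"c", "d"}, {"a", "b"}))
        assert p12[0][1]["weight"] == p21[0][1]["weight"] == 3

    def test_missing_gene_is_error(self):
        net = net_from([("a", "b")])
        with pytest.raises(ValueError, match="ghost"):
            cluster_interaction_network(net, partition({"a", "ghost"}))

    def test_weight_conservation_on_random_instances(self):
        """Crossing-edge counts plus within-module counts account for every
        graph edge, for 20 random planted instances."""
        rng = np.random.default_rng(53)
        for _ in range(20):
            n = int(rng.integers(12, 30))
            nodes = [f"v{i:02d}" for i in range(n)]
            edges = [
                (a, b)
                for i, a in enumerate(nodes)
                for b in nodes[i + 1 :]
                if rng.random() < 0.3
            ]
            net = net_from(edges, nodes=nodes)
            k = int(rng.integers(2, 5))
            assign = rng.integers(0, k, n)
            modules = [
                {nodes[i] for i in range(n) if assign[i] == m} for m in range(k)
            ]
            modules = [m for m in modules if m]
            g = cluster_interaction_network(net, partition(*modules))
            crossing = sum(d["weight"] for _, _, d in g.edges(data=True))
            internal = sum(d["internal_edges"] for _, d in g.nodes(data=True))
            assert crossing + internal == len(edges)


class TestAdjacentOverlap:
    def test_shared_gene_count(self):
        edges = adjacent_overlap_network(
            partition({"a", "b", "c"}), Stage.I, partition({"b", "c", "d"}), Stage.II
        )
        assert edges == [(0, 0, 2)]

    def test_disjoint_modules_no_edge(self):
        assert (
            adjacent_overlap_network(
                partition({"a"}), Stage.II, partition({"b"}), Stage.III
            )
            == []
        )

    def test_non_adjacent_stages_rejected(self):
        with pytest.raises(ValueError, match="not adjacent"):
            adjacent_overlap_network(
                partition({"a"}), Stage.I, partition({"a"}), Stage.III
            )

    def test_identical_partitions_are_diagonal(self):
        mods = [set("abcdef"), set("ghij"), set("klm")]
        pa, pb = partition(*mods), partition(*mods)
        edges = adjacent_overlap_network(pa, Stage.III, pb, Stage.IV)
        expected = {
            (i, j, len(a & b))
            for i, a in enumerate(pa.modules)
            for j, b in enumerate(pb.modules)
            if a & b
        }
        assert set(edges) == expected
        assert all(i == j for i, j, _ in edges)
        for i, j, w in edges:
            assert w == len(pa.modules[i])

    def test_weight_bounded_by_smaller_module(self):
        rng = np.random.default_rng(59)
        genes = [f"g{i}" for i in range(40)]
        pa_order = list(rng.permutation(genes))
        pb_order = list(rng.permutation(genes))
        mods_a = [set(pa_order[i * 10 : (i + 1) * 10]) for i in range(3)]
        mods_b = [set(pb_order[i * 7 : (i + 1) * 7]) for i in range(3)]
        for i, j, w in adjacent_overlap_network(
            partition(*mods_a), Stage.I, partition(*mods_b), Stage.II
        ):
            assert w <= min(len(mods_a[i]), len(mods_b[j]))


def toy_seven_networks():
    """Four intra graphs + three inter maps tracking one persistent module."""
    intra = {}
    for stage in TUMOUR_STAGES:
        g = nx.Graph()
        g.add_node(0, members=frozenset({"a", "b", "c", "d", "e"}), internal_edges=4)
        g.add_node(1, members=frozenset({f"x{stage.value}", f"y{stage.value}"}),
                   internal_edges=1)
        g.add_edge(0, 1, weight=2)
        intra[stage] = g
    inter = {
        (a, b): [(0, 0, 5)]
        for a, b in zip(TUMOUR_STAGES, TUMOUR_STAGES[1:])
    }
    return intra, inter


class TestCombine:
    def test_node_conservation(self):
        intra, inter = toy_seven_networks()
        net = combine_evolution_network(intra, inter)
        assert net.graph.number_of_nodes() == 8  # 2 retained modules x 4 stages
        assert net.all_stages_present

    def test_empty_inter_gives_disjoint_union(self):
        intra, _ = toy_seven_networks()
        net = combine_evolution_network(intra, {})
        assert nx.number_connected_components(net.graph) == 4
        assert net.graph.number_of_edges() == 4  # one intra edge per stage

    def test_order_independence(self):
        intra, inter = toy_seven_networks()
        a = combine_evolution_network(intra, inter)
        intra_r = dict(reversed(list(intra.items())))
        inter_r = dict(reversed(list(inter.items())))
        b = combine_evolution_network(intra_r, inter_r)
        assert nx.utils.graphs_equal(a.graph, b.graph)

    def test_persistent_module_spans_component(self):
        intra, inter = toy_seven_networks()
        net = combine_evolution_network(intra, inter)
        comp = nx.node_connected_component(
            net.graph, stage_node_id(Stage.I, 0)
        )
        for stage in TUMOUR_STAGES:
            assert stage_node_id(stage, 0) in comp

    def test_conflicting_cluster_id_rejected(self):
        intra, inter = toy_seven_networks()
        with pytest.raises(ValueError, match="unknown cluster"):
            combine_evolution_network(intra, {(Stage.I, Stage.II): [(9, 9, 1)]})


class TestLargestComponent:
    def test_identity_when_connected(self):
        intra, inter = toy_seven_networks()
        net = combine_evolution_network(intra, inter)
        if nx.is_connected(net.graph):
            sub = largest_connected_component(net)
            assert set(sub.graph.nodes) == set(net.graph.nodes)

    def test_picks_bigger_component(self):
        intra, _ = toy_seven_networks()
        net = combine_evolution_network(
            intra, {(Stage.I, Stage.II): [(0, 0, 3)], (Stage.II, Stage.III): [(0, 0, 3)]}
        )
        sub = largest_connected_component(net)
        # stages I-III chained via module 0: 3 module-0 nodes + their intra partners
        assert sub.graph.number_of_nodes() == 6
        assert not sub.all_stages_present

    def test_stage_coverage_flag_by_scan(self):
        intra, inter = toy_seven_networks()
        net = combine_evolution_network(intra, inter)
        sub = largest_connected_component(net)
        stages = {d["stage"] for _, d in sub.graph.nodes(data=True)}
        assert sub.all_stages_present == (stages == set(TUMOUR_STAGES))
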