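"""Markov Cluster Algorithm (MCL) on weighted graphs, with module selection.

MCL simulates flow on the graph: the column-stochastic transition matrix is
alternately *expanded* (matrix power, spreading flow along walks) and
*inflated* (entrywise power plus column renormalization, strengthening
strong currents), with small entries pruned, until a fixed point. The
attractor structure of the limit matrix yields a hard clustering.

Module selection keeps clusters that have at least ``min_size`` genes *and*
induce a connected subgraph of the source network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .datatypes import InteractionNetwork

logger = logging.getLogger(__name__)

__all__ = ["ModulePartition", "mcl_cluster", "select_modules"]


@dataclass
class ModulePartition:
    """Disjoint gene clusters in deterministic order.

    Modules are sorted by decreasing size, ties by lexicographically
    smallest member. ``retained`` marks modules passing selection; it is
    all-True until :func:`select_modules` runs.
    """

    modules: list[frozenset[str]]
    retained: list[bool]
    graph: nx.Graph | None = None
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for mod in self.modules:
            if seen & mod:
                raise ValueError("modules are not disjoint")
            seen |= mod

    def __len__(self) -> int:
        return len(self.modules)

    @property
    def node_set(self) -> frozenset[str]:
        out: set[str] = set()
        for m in self.modules:
            out |= m
        return frozenset(out)

    def retained_modules(self) -> list[frozenset[str]]:
        return [m for m, r in zip(self.modules, self.retained) if r]

    def labels(self) -> dict[str, int]:
        """gene -> module index (position in the sorted module list)."""
        return {g: i for i, mod in enumerate(self.modules) for g in mod}


def _order_modules(modules: list[set[str]]) -> list[frozenset[str]]:
    return [
        frozenset(m)
        for m in sorted(modules, key=lambda m: (-len(m), min(m)))
    ]


def mcl_cluster(
    network: InteractionNetwork,
    inflation: float = 2.0,
    expansion: int = 2,
    prune_threshold: float = 1e-5,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> ModulePartition:
    """Cluster a weighted graph with MCL.

    Edge confidences are the flow capacities; every node gets a self-loop
    weighted by its maximum incident edge weight (1 for isolated nodes),
    the usual regularization that prevents parity oscillation. If the
    iteration has not converged after ``max_iter`` rounds the current
    partition is returned with a logged warning.
    """
    nodes = sorted(network.graph.nodes, key=str)
    n = len(nodes)
    if n == 0:
        raise ValueError("graph is empty")
    index = {v: i for i, v in enumerate(nodes)}

    a = np.zeros((n, n))
    for u, v, d in network.graph.edges(data=True):
        w = float(d.get("confidence", 1.0))
        a[index[u], index[v]] = w
        a[index[v], index[u]] = w
    loop = a.max(axis=0)
    loop[loop == 0] = 1.0
    np.fill_diagonal(a, loop)

    m = a / a.sum(axis=0, keepdims=True)
    deviations: list[float] = []
    converged = False
    for iteration in range(max_iter):
        prev = m
        m = np.linalg.matrix_power(m, expansion)
        m = np.power(m, inflation)
        m[m < prune_threshold] = 0.0
        colsum = m.sum(axis=0, keepdims=True)
        # pruning can only empty a column if the threshold is pathological
        colsum[colsum == 0] = 1.0
        m = m / colsum
        deviations.append(float(np.max(np.abs(m.sum(axis=0) - 1.0))))
        if np.max(np.abs(m - prev)) < tol:
            converged = True
            break
    if not converged:
        logger.warning("MCL did not converge within %d iterations", max_iter)

    # attractors: nodes retaining flow onto themselves in the limit matrix
    attractors = np.flatnonzero(m.diagonal() > prune_threshold)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[ry] = rx

    for i in attractors:
        for j in np.flatnonzero(m[i] > 0):
            union(i, j)
    groups: dict[int, set[str]] = {}
    for v in range(n):
        groups.setdefault(find(v), set()).add(nodes[v])

    modules = _order_modules(list(groups.values()))
    return ModulePartition(
        modules=modules,
        retained=[True] * len(modules),
        graph=network.graph,
        diagnostics={
            "iterations": len(deviations),
            "converged": converged,
            "column_sum_deviations": deviations,
        },
    )


def select_modules(
    partition: ModulePartition,
    min_size: int = 5,
    graph: nx.Graph | None = None,
) -> ModulePartition:
    """Flag modules with >= ``min_size`` genes whose induced subgraph is connected."""
    g = graph if graph is not None else partition.graph
    if g is None:
        raise ValueError("module selection needs the source graph")
    retained = []
    for mod in partition.modules:
        ok = len(mod) >= min_size and nx.is_connected(g.subgraph(mod))
        retained.append(ok)
    return ModulePartition(
        modules=list(partition.modules),
        retained=retained,
        graph=g,
        diagnostics=dict(partition.diagnostics),
    )
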