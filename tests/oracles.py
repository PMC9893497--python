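"""Independent brute-force oracles and fixtures shared by several tests.

Everything here deliberately avoids the code paths it is used to check:
explicit sorting instead of rank trimming, path enumeration instead of
Brandes' algorithm, binomial-coefficient sums instead of distribution
functions.
"""

import itertools
from math import comb

import networkx as nx
import numpy as np
import pandas as pd

from stagenet.datatypes import CountMatrix, InteractionNetwork


def brute_force_tmm(obs, ref, lib_obs, lib_ref):
    """Pairwise TMM factor by explicit sort-and-trim of M/A values."""
    ms, as_, ws = [], [], []
    for yo, yr in zip(obs, ref):
        if yo > 0 and yr > 0:
            po, pr = yo / lib_obs, yr / lib_ref
            ms.append(np.log2(po / pr))
            as_.append(0.5 * (np.log2(po) + np.log2(pr)))
            ws.append(
                1.0
                / ((lib_obs - yo) / (lib_obs * yo) + (lib_ref - yr) / (lib_ref * yr))
            )
    n = len(ms)
    by_m = sorted(range(n), key=lambda i: ms[i])
    by_a = sorted(range(n), key=lambda i: as_[i])
    keep_m = set(by_m[int(np.floor(n * 0.3)) : n - int(np.floor(n * 0.3))])
    keep_a = set(by_a[int(np.floor(n * 0.05)) : n - int(np.floor(n * 0.05))])
    keep = keep_m & keep_a
    num = sum(ms[i] * ws[i] for i in keep)
    den = sum(ws[i] for i in keep)
    return 2.0 ** (num / den)


def asymmetric_tmm_fixture() -> CountMatrix:
    """100 genes, 90 equal-proportion, 10 8-fold up in sample B."""
    rng = np.random.default_rng(17)
    base = rng.integers(50, 500, 100)
    b = base.copy()
    b[:10] = base[:10] * 8
    return CountMatrix(
        pd.DataFrame({"A": base, "B": b}, index=[f"g{i:03d}" for i in range(100)])
    )


def planted_bridge_graph(seed=101):
    """Two 8-node communities (p_in = 0.9) joined by one bridge edge."""
    rng = np.random.default_rng(seed)
    left = [f"L{i}" for i in range(8)]
    right = [f"R{i}" for i in range(8)]
    edges = []
    for side in (left, right):
        for i, a in enumerate(side):
            for b in side[i + 1 :]:
                if rng.random() < 0.9:
                    edges.append((a, b, float(rng.uniform(0.8, 1.0))))
    edges.append((left[0], right[0], 0.9))
    net = InteractionNetwork.from_edges(edges, nodes=left + right)
    assert nx.is_connected(net.graph)
    labels = {**{v: 0 for v in left}, **{v: 1 for v in right}}
    return net, labels


def brute_force_betweenness(graph: nx.Graph) -> dict:
    """Unnormalized betweenness by BFS distances + DFS geodesic enumeration."""
    nodes = list(graph.nodes)
    adj = {v: set(graph.neighbors(v)) for v in nodes}

    def bfs_dist(src):
        dist = {src: 0}
        frontier = [src]
        while frontier:
            nxt = []
            for u in frontier:
                for w in adj[u]:
                    if w not in dist:
                        dist[w] = dist[u] + 1
                        nxt.append(w)
            frontier = nxt
        return dist

    btw = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        dist = bfs_dist(s)
        if t not in dist:
            continue
        paths = []

        def extend(path):
            u = path[-1]
            if u == t:
                paths.append(path)
                return
            for w in adj[u]:
                if w in dist and dist[w] == dist[u] + 1:
                    extend(path + [w])

        extend([s])
        geodesics = [p for p in paths if len(p) - 1 == dist[t]]
        for p in geodesics:
            for v in p[1:-1]:
                btw[v] += 1.0 / len(geodesics)
    return btw


def hypergeom_enumeration(k, n, K, N):
    """P(X >= k) by direct summation of binomial coefficients."""
    total = comb(N, n)
    return sum(comb(K, j) * comb(N - K, n - j) for j in range(k, min(n, K) + 1)) / total
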