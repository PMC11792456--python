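"""Brute-force reference implementations used to cross-check graph metrics.

Deliberately naive (explicit loops, Floyd-Warshall, direct formula sums) and
independent of networkx, so they can serve as oracles for the production
topology and node-role code on small graphs.
"""

from __future__ import annotations

import itertools

import numpy as np


def adjacency(nodes, edges):
    index = {v: i for i, v in enumerate(nodes)}
    a = np.zeros((len(nodes), len(nodes)), dtype=int)
    for u, v in edges:
        a[index[u], index[v]] = a[index[v], index[u]] = 1
    return a, index


def brute_density(nodes, edges):
    n = len(nodes)
    return 2 * len(edges) / (n * (n - 1)) if n > 1 else 0.0


def brute_average_degree(nodes, edges):
    return 2 * len(edges) / len(nodes)


def brute_clustering(nodes, edges):
    """Mean local clustering; nodes of degree < 2 contribute 0."""
    a, _ = adjacency(nodes, edges)
    total = 0.0
    for i in range(len(nodes)):
        nbrs = np.where(a[i])[0]
        k = len(nbrs)
        if k < 2:
            continue
        links = sum(a[u, v] for u, v in itertools.combinations(nbrs, 2))
        total += 2 * links / (k * (k - 1))
    return total / len(nodes)


def brute_shortest_paths(nodes, edges):
    """All-pairs shortest path lengths by Floyd-Warshall."""
    a, _ = adjacency(nodes, edges)
    n = len(nodes)
    d = np.where(a == 1, 1.0, np.inf)
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        d = np.minimum(d, d[:, k][:, None] + d[k, :][None, :])
    return d


def brute_diameter_apl(nodes, edges):
    """Diameter and mean shortest path over the largest connected component."""
    d = brute_shortest_paths(nodes, edges)
    n = len(nodes)
    # connected components from finite distances
    seen, comps = set(), []
    for i in range(n):
        if i in seen:
            continue
        comp = {j for j in range(n) if np.isfinite(d[i, j])}
        comps.append(sorted(comp))
        seen |= comp
    lcc = max(comps, key=len)
    sub = d[np.ix_(lcc, lcc)]
    off = sub[~np.eye(len(lcc), dtype=bool)]
    return float(off.max()), float(off.mean())


def brute_modularity(nodes, edges, partition):
    """Newman Q = sum_ij [A_ij - k_i k_j / 2m] delta(c_i, c_j) / 2m."""
    a, index = adjacency(nodes, edges)
    k = a.sum(axis=1)
    m2 = a.sum()  # 2m
    q = 0.0
    for u in nodes:
        for v in nodes:
            if partition[u] == partition[v]:
                i, j = index[u], index[v]
                q += a[i, j] - k[i] * k[j] / m2
    return q / m2


def brute_zi_pi(nodes, edges, partition):
    """Within-module degree z-score and among-module connectivity by loops."""
    a, index = adjacency(nodes, edges)
    out = {}
    within = {}
    for v in nodes:
        within[v] = sum(
            a[index[v], index[u]]
            for u in nodes
            if u != v and partition[u] == partition[v]
        )
    for v in nodes:
        module_members = [u for u in nodes if partition[u] == partition[v]]
        vals = np.array([within[u] for u in module_members], dtype=float)
        sd = vals.std(ddof=0)
        zi = (within[v] - vals.mean()) / sd if sd > 0 else 0.0
        k = a[index[v]].sum()
        if k == 0:
            pi = 0.0
        else:
            counts = {}
            for u in nodes:
                if a[index[v], index[u]]:
                    counts[partition[u]] = counts.get(partition[u], 0) + 1
            pi = 1.0 - sum((c / k) ** 2 for c in counts.values())
        out[v] = (float(zi), float(pi))
    return out


def random_graph(rng, max_nodes=50):
    """A random signed graph plus a random (contiguous-block) partition."""
    n = int(rng.integers(5, max_nodes + 1))
    p = rng.uniform(0.08, 0.35)
    nodes = [f"n{i}" for i in range(n)]
    edges = [
        (nodes[i], nodes[j])
        for i in range(n)
        for j in range(i + 1, n)
        if rng.random() < p
    ]
    n_mod = int(rng.integers(1, 5))
    partition = {v: int(rng.integers(0, n_mod)) for v in nodes}
    return nodes, edges, partition
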