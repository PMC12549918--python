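"""Numba-compiled graph kernels for small dense binary graphs.

All kernels operate on square ``uint8`` adjacency matrices (0/1, zero
diagonal, symmetric). They are deliberately loop-based: the graphs in a
cognitive connectome have a few dozen nodes, and the permutation engine
evaluates metrics on tens of thousands of binarized graphs, so per-call
overhead matters more than asymptotics.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "bfs_distances",
    "nodal_global_efficiency",
    "transitivity",
    "nodal_local_efficiency",
    "nodal_participation",
    "characteristic_path_length",
    "global_binary_profile",
]


@njit(cache=True)
def bfs_distances(adj):
    """All-pairs unweighted shortest-path lengths; -1 marks unreachable."""
    n = adj.shape[0]
    dist = np.full((n, n), -1, dtype=np.int32)
    queue = np.empty(n, dtype=np.int64)
    for s in range(n):
        dist[s, s] = 0
        head = 0
        tail = 0
        queue[tail] = s
        tail += 1
        while head < tail:
            u = queue[head]
            head += 1
            du = dist[s, u]
            for v in range(n):
                if adj[u, v] != 0 and dist[s, v] < 0:
                    dist[s, v] = du + 1
                    queue[tail] = v
                    tail += 1
    return dist


@njit(cache=True)
def nodal_global_efficiency(adj):
    """Per-node mean inverse distance to all other nodes (unreachable -> 0)."""
    n = adj.shape[0]
    out = np.zeros(n)
    if n < 2:
        return out
    dist = bfs_distances(adj)
    for i in range(n):
        acc = 0.0
        for j in range(n):
            if j != i and dist[i, j] > 0:
                acc += 1.0 / dist[i, j]
        out[i] = acc / (n - 1)
    return out


@njit(cache=True)
def transitivity(adj):
    """3 * triangles / number of length-2 paths; 0 on a path-free graph."""
    n = adj.shape[0]
    paths2 = 0.0
    for i in range(n):
        deg = 0
        for j in range(n):
            if adj[i, j] != 0:
                deg += 1
        paths2 += deg * (deg - 1)
    if paths2 == 0.0:
        return 0.0
    tri = 0
    for i in range(n):
        for j in range(i + 1, n):
            if adj[i, j] != 0:
                for k in range(j + 1, n):
                    if adj[i, k] != 0 and adj[j, k] != 0:
                        tri += 1
    # 3*tri / (paths2/2)
    return 6.0 * tri / paths2


@njit(cache=True)
def nodal_local_efficiency(adj):
    """Per-node global efficiency of the neighbour-induced subgraph.

    Nodes with fewer than two neighbours score 0.
    """
    n = adj.shape[0]
    out = np.zeros(n)
    nbrs = np.empty(n, dtype=np.int64)
    for i in range(n):
        k = 0
        for j in range(n):
            if adj[i, j] != 0:
                nbrs[k] = j
                k += 1
        if k < 2:
            continue
        sub = np.empty((k, k), dtype=np.uint8)
        for a in range(k):
            for b in range(k):
                sub[a, b] = adj[nbrs[a], nbrs[b]]
        dist = bfs_distances(sub)
        acc = 0.0
        for a in range(k):
            for b in range(k):
                if a != b and dist[a, b] > 0:
                    acc += 1.0 / dist[a, b]
        out[i] = acc / (k * (k - 1))
    return out


@njit(cache=True)
def nodal_participation(adj, modules, n_modules):
    """Participation coefficient 1 - sum_s (k_is/k_i)^2; isolated nodes -> 0."""
    n = adj.shape[0]
    out = np.zeros(n)
    counts = np.empty(n_modules, dtype=np.float64)
    for i in range(n):
        for m in range(n_modules):
            counts[m] = 0.0
        k = 0
        for j in range(n):
            if adj[i, j] != 0:
                k += 1
                counts[modules[j]] += 1.0
        if k == 0:
            continue
        acc = 0.0
        for m in range(n_modules):
            frac = counts[m] / k
            acc += frac * frac
        out[i] = 1.0 - acc
    return out


@njit(cache=True)
def characteristic_path_length(adj):
    """Mean shortest-path length over reachable ordered pairs (inf if none)."""
    n = adj.shape[0]
    dist = bfs_distances(adj)
    total = 0.0
    count = 0
    for i in range(n):
        for j in range(n):
            if j != i and dist[i, j] > 0:
                total += dist[i, j]
                count += 1
    if count == 0:
        return np.inf
    return total / count


@njit(cache=True)
def adjacency_from_order(order, rows, cols, k, n):
    """Adjacency keeping the first ``k`` candidate edges of a ranked order."""
    adj = np.zeros((n, n), dtype=np.uint8)
    for e in range(k):
        idx = order[e]
        i = rows[idx]
        j = cols[idx]
        adj[i, j] = 1
        adj[j, i] = 1
    return adj


@njit(cache=True)
def global_binary_profile(order, rows, cols, edge_counts, n):
    """Global efficiency, transitivity and local efficiency per density.

    ``order`` ranks the n*(n-1)/2 candidate edges (strongest first);
    ``edge_counts`` gives the number of retained edges at each density.
    Returns an (n_density, 3) array with columns
    (global_efficiency, transitivity, local_efficiency).
    """
    nd = edge_counts.shape[0]
    out = np.empty((nd, 3))
    for d in range(nd):
        adj = adjacency_from_order(order, rows, cols, edge_counts[d], n)
        geff = nodal_global_efficiency(adj)
        leff = nodal_local_efficiency(adj)
        out[d, 0] = geff.mean()
        out[d, 1] = transitivity(adj)
        out[d, 2] = leff.mean()
    return out
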