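"""Shared fixtures and independent brute-force graph oracles.

The oracles here are deliberately naive (itertools enumeration,
Floyd-Warshall, direct formula evaluation) and share no code with the
package's metric implementations.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from cogconn import CognitiveDataset, CohortConfig, GroupSpec, generate_cohort
from cogconn.connectome import BinaryGraph
from cogconn.preprocessing import preprocess


# ---------------------------------------------------------------------------
# brute-force oracles


def bf_floyd_warshall(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    dist = np.where(adj > 0, 1.0, np.inf)
    np.fill_diagonal(dist, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if dist[i, k] + dist[k, j] < dist[i, j]:
                    dist[i, j] = dist[i, k] + dist[k, j]
    return dist


def bf_global_efficiency(adj: np.ndarray) -> float:
    n = adj.shape[0]
    if n < 2:
        return 0.0
    dist = bf_floyd_warshall(adj)
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(dist[i, j]):
                total += 1.0 / dist[i, j]
    return total / (n * (n - 1))


def bf_nodal_global_efficiency(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    dist = bf_floyd_warshall(adj)
    out = np.zeros(n)
    for i in range(n):
        acc = 0.0
        for j in range(n):
            if i != j and np.isfinite(dist[i, j]):
                acc += 1.0 / dist[i, j]
        out[i] = acc / (n - 1)
    return out


def bf_transitivity(adj: np.ndarray) -> float:
    n = adj.shape[0]
    triangles = 0
    for i, j, k in itertools.combinations(range(n), 3):
        if adj[i, j] and adj[j, k] and adj[i, k]:
            triangles += 1
    deg = adj.sum(axis=0, dtype=int)
    paths = sum(d * (d - 1) / 2 for d in deg)
    if paths == 0:
        return 0.0
    return 3.0 * triangles / paths


def bf_local_efficiency(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j]]
        if len(nbrs) < 2:
            continue
        sub = adj[np.ix_(nbrs, nbrs)]
        out[i] = bf_global_efficiency(sub)
    return out


def bf_participation(adj: np.ndarray, modules: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    out = np.zeros(n)
    for i in range(n):
        k = adj[i].sum()
        if k == 0:
            continue
        acc = 0.0
        for s in np.unique(modules):
            k_is = sum(adj[i, j] for j in range(n) if modules[j] == s)
            acc += (k_is / k) ** 2
        out[i] = 1.0 - acc
    return out


def bf_characteristic_path_length(adj: np.ndarray) -> float:
    dist = bf_floyd_warshall(adj)
    n = adj.shape[0]
    vals = [dist[i, j] for i in range(n) for j in range(n)
            if i != j and np.isfinite(dist[i, j]) and dist[i, j] > 0]
    return float(np.mean(vals)) if vals else np.inf


def random_binary_graph(rng: np.random.Generator, n: int, p: float = 0.4) -> BinaryGraph:
    adj = np.triu((rng.random((n, n)) < p).astype(np.uint8), k=1)
    adj = adj + adj.T
    return BinaryGraph(adjacency=adj, node_labels=tuple(f"n{i}" for i in range(n)))


# ---------------------------------------------------------------------------
# cohort fixtures


def make_two_group_clean(
    n_a: int = 100,
    n_b: int = 100,
    topo_a: str = "smallworld",
    topo_b: str = "smallworld",
    seed: int = 0,
    **cfg_kwargs,
) -> tuple[CognitiveDataset, CognitiveDataset]:
    """Two preprocessed single-group datasets, ready to compare."""
    cfg = CohortConfig(
        groups=[GroupSpec("a", n_a, topo_a), GroupSpec("b", n_b, topo_b)],
        mean_shifts={},
        seed=seed,
        **cfg_kwargs,
    )
    data = generate_cohort(cfg)
    clean, _ = preprocess(data, reference_group="a")
    return (
        clean.with_table(clean.group_table("a")),
        clean.with_table(clean.group_table("b")),
    )


@pytest.fixture(scope="session")
def two_identical_groups():
    """Two groups drawn from one generative process (null scenario)."""
    return make_two_group_clean(seed=42)


@pytest.fixture(scope="session")
def demo_cohort():
    """Default four-group demo cohort, raw."""
    return generate_cohort(CohortConfig(seed=7))
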