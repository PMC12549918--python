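"""Weighted Spearman connectomes and density-threshold binarization.

Nodes are cognitive measures; edges are pairwise Spearman correlations
across the participants of one group. Binary graphs keep the strongest
(signed) correlations up to a target density — the fraction of the
n(n-1)/2 possible edges retained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._kernels import adjacency_from_order
from .datasets import CognitiveDataset


class ConnectomeError(ValueError):
    """Raised on invalid connectome construction or binarization."""


@dataclass(frozen=True)
class DensityGrid:
    """Evenly spaced grid of network densities.

    Defaults to the 10%-30% range in 1% steps commonly used for
    fixed-density thresholding of association matrices.
    """

    d_min: float = 0.10
    d_max: float = 0.30
    step: float = 0.01

    def __post_init__(self) -> None:
        if not (0 < self.d_min < self.d_max <= 1):
            raise ValueError("require 0 < d_min < d_max <= 1")
        if self.step <= 0:
            raise ValueError("step must be positive")

    @property
    def densities(self) -> np.ndarray:
        n = int(round((self.d_max - self.d_min) / self.step)) + 1
        return np.round(self.d_min + self.step * np.arange(n), 10)

    @property
    def median_density(self) -> float:
        return float(np.median(self.densities))

    def __contains__(self, density: float) -> bool:
        return bool(np.any(np.isclose(self.densities, density)))


@dataclass
class WeightedConnectome:
    """Symmetric signed correlation matrix with zero diagonal."""

    matrix: np.ndarray
    node_labels: tuple[str, ...]
    group: str = ""
    n_participants: int = 0

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ConnectomeError("matrix must be square")
        if m.shape[0] != len(self.node_labels):
            raise ConnectomeError("node_labels length mismatch")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ConnectomeError("matrix must be symmetric")
        if np.nanmax(np.abs(m)) > 1 + 1e-9:
            raise ConnectomeError("correlations must lie in [-1, 1]")
        np.fill_diagonal(m, 0.0)
        self.matrix = m
        self.node_labels = tuple(self.node_labels)

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(self.n_nodes, k=1)
        return self.matrix[iu]

    def subset(self, labels: Sequence[str]) -> "WeightedConnectome":
        idx = [self.node_labels.index(l) for l in labels]
        return WeightedConnectome(
            matrix=self.matrix[np.ix_(idx, idx)],
            node_labels=tuple(labels),
            group=self.group,
            n_participants=self.n_participants,
        )

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            self.matrix, index=self.node_labels, columns=self.node_labels
        ).to_csv(path)

    def to_edge_list(self, path: str | Path) -> None:
        iu = np.triu_indices(self.n_nodes, k=1)
        rows = [
            (self.node_labels[i], self.node_labels[j], self.matrix[i, j])
            for i, j in zip(*iu)
        ]
        pd.DataFrame(rows, columns=["node_a", "node_b", "weight"]).to_csv(
            path, sep="\t", index=False
        )


@dataclass
class BinaryGraph:
    """Undirected unweighted graph as a 0/1 adjacency matrix."""

    adjacency: np.ndarray
    node_labels: tuple[str, ...]
    density: float | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ConnectomeError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ConnectomeError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ConnectomeError("self-loops are not allowed")
        if not np.isin(a, (0, 1)).all():
            raise ConnectomeError("adjacency entries must be 0/1")
        self.adjacency = a.astype(np.uint8)
        self.node_labels = tuple(self.node_labels)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=0).astype(int)

    def to_networkx(self):
        import networkx as nx

        g = nx.from_numpy_array(self.adjacency)
        return nx.relabel_nodes(g, dict(enumerate(self.node_labels)))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            self.adjacency, index=self.node_labels, columns=self.node_labels
        ).to_csv(path)


@dataclass
class BinaryGraphEnsemble:
    """Binarized graphs of one connectome over a density grid."""

    graphs: list[BinaryGraph]
    grid: DensityGrid
    group: str = ""

    def __getitem__(self, i: int) -> BinaryGraph:
        return self.graphs[i]

    def __len__(self) -> int:
        return len(self.graphs)

    def at_density(self, density: float) -> BinaryGraph:
        for g in self.graphs:
            if g.density is not None and np.isclose(g.density, density):
                return g
        raise KeyError(f"density {density} not in ensemble")


# ---------------------------------------------------------------------------
# construction


def spearman_matrix(scores: np.ndarray) -> np.ndarray:
    """Pairwise Spearman matrix (average-rank ties), zero diagonal."""
    ranks = stats.rankdata(scores, axis=0)
    with np.errstate(invalid="raise"):
        corr = np.corrcoef(ranks, rowvar=False)
    corr = np.clip(corr, -1.0, 1.0)
    np.fill_diagonal(corr, 0.0)
    return corr


def build_connectome(data: CognitiveDataset, group: str) -> WeightedConnectome:
    """Spearman connectome of one group from residualized complete-case data."""
    scores = data.scores(group)
    if scores.shape[0] < 3:
        raise ConnectomeError(
            f"group {group!r} has {scores.shape[0]} rows; need >= 3"
        )
    if np.isnan(scores).any():
        raise ConnectomeError("missing values present; complete cases required")
    spans = np.ptp(scores, axis=0)
    flat = [m for m, s in zip(data.measures, spans) if s == 0]
    if flat:
        raise ConnectomeError(
            f"zero-variance measure(s) within group {group!r}: {flat}"
        )
    return WeightedConnectome(
        matrix=spearman_matrix(scores),
        node_labels=tuple(data.measures),
        group=group,
        n_participants=scores.shape[0],
    )


def edge_count(density: float, n_nodes: int) -> int:
    """Round-half-up count of edges retained at a density."""
    m = n_nodes * (n_nodes - 1) // 2
    return int(np.floor(density * m + 0.5))


def ranked_edge_order(condensed: np.ndarray) -> np.ndarray:
    """Candidate-edge ranking: signed weight descending, lexicographic ties.

    The condensed upper-triangle vector is already in lexicographic
    node-pair order, so a stable sort on the negated weights breaks ties
    that way.
    """
    return np.argsort(-condensed, kind="stable")


def binarize(w: WeightedConnectome, density: float) -> BinaryGraph:
    """Keep the strongest (signed) correlations up to the target density."""
    if not (0 < density <= 1):
        raise ConnectomeError(f"density must be in (0, 1], got {density}")
    n = w.n_nodes
    k = edge_count(density, n)
    if k == 0:
        raise ConnectomeError(f"density {density} yields zero edges for n={n}")
    rows, cols = np.triu_indices(n, k=1)
    order = ranked_edge_order(w.condensed())
    adj = adjacency_from_order(order, rows, cols, k, n)
    return BinaryGraph(adjacency=adj, node_labels=w.node_labels, density=density)


def binarize_grid(w: WeightedConnectome, grid: DensityGrid) -> BinaryGraphEnsemble:
    graphs = [binarize(w, float(d)) for d in grid.densities]
    return BinaryGraphEnsemble(graphs=graphs, grid=grid, group=w.group)


def detect_fragmenting_nodes(
    w: WeightedConnectome, grid: DensityGrid
) -> list[str]:
    """Nodes isolated at the top of the density range.

    Measures that barely correlate with the rest of the battery remain
    unconnected even at d_max; they are reported so the caller can drop
    them and rebuild an unfragmented connectome.
    """
    g = binarize(w, grid.d_max)
    deg = g.degrees()
    return [lab for lab, d in zip(w.node_labels, deg) if d == 0]


def select_density_range(
    w_ref: WeightedConnectome,
    exclude_labels: Sequence[str] = (),
    grid_candidates: DensityGrid = DensityGrid(0.05, 0.50, 0.01),
    step: float = 0.01,
    n_random: int = 100,
    seed: int = 0,
) -> DensityGrid:
    """Choose a density range on the reference-group connectome.

    The lower bound is the smallest candidate density at which no node is
    isolated; the upper bound is the largest density (at or above the
    lower bound) at which the graph is small-world (sigma > 1). Both are
    determined on the connectome restricted to the non-excluded nodes
    (dominant instrument blocks such as MoCA sub-scores can inflate the
    density at which other nodes connect). The chosen range is then
    checked on the full node set; fragmentation there raises warnings,
    not errors.
    """
    from .metrics import small_worldness

    keep = [l for l in w_ref.node_labels if l not in set(exclude_labels)]
    if not keep:
        raise ConnectomeError("exclusion list removes every node")
    sub = w_ref.subset(keep)

    densities = grid_candidates.densities
    lower = None
    for d in densities:
        g = binarize(sub, float(d))
        if (g.degrees() > 0).all():
            lower = float(d)
            break
    if lower is None:
        raise ConnectomeError(
            "no candidate density connects every node of the reference "
            f"connectome (max candidate {densities[-1]})"
        )
    upper = None
    rng = np.random.default_rng(seed)
    for d in densities[::-1]:
        if d < lower:
            break
        g = binarize(sub, float(d))
        sigma = small_worldness(g, n_random=n_random, seed=int(rng.integers(2**31)))
        if sigma > 1:
            upper = float(d)
            break
    if upper is None or upper <= lower:
        raise ConnectomeError(
            "no density above the connectivity bound retains a small-world "
            f"topology (lower bound {lower}); inspect the reference connectome"
        )
    grid = DensityGrid(lower, upper, step)
    for d in grid.densities:
        if d <= grid.d_min:
            continue
        g = binarize(w_ref, float(d))
        if (g.degrees() == 0).any():
            isolated = [
                lab for lab, k in zip(w_ref.node_labels, g.degrees()) if k == 0
            ]
            warnings.warn(
                f"full connectome has isolated node(s) {isolated} at density "
                f"{d:.2f} inside the selected range",
                stacklevel=2,
            )
    return grid
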