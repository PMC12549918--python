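"""Graph measures for cognitive connectomes.

Global measures: average strength (weighted), global efficiency
(integration), transitivity and local efficiency (segregation), plus a
small-world index against a degree-preserving rewiring null. Nodal
measures: strength (weighted), participation, global efficiency and
local efficiency.

Strength is computed on the signed weighted matrix (negative
correlations subtract); all other measures are computed on binarized
graphs. Definitions follow the standard complex-network conventions
for binary undirected graphs: transitivity (not mean clustering) and
characteristic path length over reachable pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import _kernels
from .connectome import (
    BinaryGraph,
    BinaryGraphEnsemble,
    DensityGrid,
    WeightedConnectome,
    binarize,
)


class MetricError(ValueError):
    pass


# ---------------------------------------------------------------------------
# weighted measures


def nodal_strength(w: WeightedConnectome, absolute: bool = False) -> pd.Series:
    """Signed sum of each node's correlation weights.

    With ``absolute=True`` negative weights contribute their magnitude
    instead of subtracting.
    """
    m = np.abs(w.matrix) if absolute else w.matrix
    return pd.Series(m.sum(axis=0), index=list(w.node_labels), name="strength")


def average_strength(w: WeightedConnectome, absolute: bool = False) -> float:
    """Mean nodal strength — the magnitude of correlations in the graph."""
    return float(nodal_strength(w, absolute=absolute).mean())


# ---------------------------------------------------------------------------
# binary measures


def shortest_path_lengths(g: BinaryGraph) -> pd.DataFrame:
    """Breadth-first pairwise distances; unreachable pairs are infinite."""
    dist = _kernels.bfs_distances(g.adjacency).astype(float)
    dist[dist < 0] = np.inf
    labels = list(g.node_labels)
    return pd.DataFrame(dist, index=labels, columns=labels)


def global_efficiency(g: BinaryGraph, node: str | None = None) -> float:
    """Mean inverse shortest-path length (unreachable pairs contribute 0)."""
    eff = _kernels.nodal_global_efficiency(g.adjacency)
    if node is None:
        return float(eff.mean())
    return float(eff[g.node_labels.index(node)])


def nodal_global_efficiency(g: BinaryGraph) -> pd.Series:
    eff = _kernels.nodal_global_efficiency(g.adjacency)
    return pd.Series(eff, index=list(g.node_labels), name="global_efficiency")


def transitivity(g: BinaryGraph) -> float:
    """3 x triangles over length-2 paths; 0 when no such paths exist."""
    return float(_kernels.transitivity(g.adjacency))


def local_efficiency(g: BinaryGraph, node: str | None = None) -> float:
    """Efficiency of a node's neighbour subgraph (mean over nodes if global)."""
    eff = _kernels.nodal_local_efficiency(g.adjacency)
    if node is None:
        return float(eff.mean())
    return float(eff[g.node_labels.index(node)])


def nodal_local_efficiency(g: BinaryGraph) -> pd.Series:
    eff = _kernels.nodal_local_efficiency(g.adjacency)
    return pd.Series(eff, index=list(g.node_labels), name="local_efficiency")


def participation(g: BinaryGraph, communities: Mapping[str, str]) -> pd.Series:
    """Participation coefficient per node given a node -> module mapping."""
    missing = [l for l in g.node_labels if l not in communities]
    if missing:
        raise MetricError(f"nodes without module assignment: {missing}")
    module_names = sorted({communities[l] for l in g.node_labels})
    lut = {m: i for i, m in enumerate(module_names)}
    modules = np.array([lut[communities[l]] for l in g.node_labels], dtype=np.int64)
    part = _kernels.nodal_participation(g.adjacency, modules, len(module_names))
    return pd.Series(part, index=list(g.node_labels), name="participation")


def characteristic_path_length(g: BinaryGraph) -> float:
    """Mean shortest-path length over reachable ordered pairs."""
    return float(_kernels.characteristic_path_length(g.adjacency))


# ---------------------------------------------------------------------------
# small-world index


def maslov_sneppen_rewire(
    g: BinaryGraph, rng: np.random.Generator, swaps_per_edge: int = 10
) -> BinaryGraph:
    """Degree-preserving randomization by attempted double-edge swaps."""
    adj = g.adjacency.copy()
    rows, cols = np.nonzero(np.triu(adj, k=1))
    edges = np.stack([rows, cols], axis=1).astype(np.int64)
    m = len(edges)
    if m < 2:
        raise MetricError("graph has fewer than 2 edges; cannot rewire")
    attempts = swaps_per_edge * m
    picks = rng.integers(0, m, size=(attempts, 2))
    flips = rng.random(attempts) < 0.5
    for t in range(attempts):
        e1, e2 = picks[t]
        if e1 == e2:
            continue
        a, b = edges[e1]
        c, d = edges[e2]
        if flips[t]:
            c, d = d, c
        if a == c or a == d or b == c or b == d:
            continue
        if adj[a, d] or adj[c, b]:
            continue
        adj[a, b] = adj[b, a] = 0
        adj[c, d] = adj[d, c] = 0
        adj[a, d] = adj[d, a] = 1
        adj[c, b] = adj[b, c] = 1
        edges[e1] = (a, d) if a < d else (d, a)
        edges[e2] = (c, b) if c < b else (b, c)
    return BinaryGraph(adjacency=adj, node_labels=g.node_labels)


def small_worldness(g: BinaryGraph, n_random: int = 100, seed: int = 0) -> float:
    """Small-world index sigma = (C/C_rand) / (L/L_rand).

    C is transitivity, L the characteristic path length over reachable
    pairs; the null statistics are means over ``n_random`` degree-
    preserving rewirings (10 attempted double-edge swaps per edge each).
    sigma > 1 indicates non-random, small-world topology.
    """
    if g.n_edges < 2:
        raise MetricError("graph has fewer than 2 edges; small-worldness undefined")
    if n_random < 1:
        raise MetricError("n_random must be >= 1")
    c_obs = transitivity(g)
    l_obs = characteristic_path_length(g)
    rng = np.random.default_rng(seed)
    c_rand = np.empty(n_random)
    l_rand = np.empty(n_random)
    for i in range(n_random):
        r = maslov_sneppen_rewire(g, rng)
        c_rand[i] = transitivity(r)
        l_rand[i] = characteristic_path_length(r)
    c_bar = c_rand.mean()
    l_bar = l_rand.mean()
    if c_bar == 0 or not np.isfinite(l_bar) or l_bar == 0 or not np.isfinite(l_obs):
        return np.nan
    return float((c_obs / c_bar) / (l_obs / l_bar))


# ---------------------------------------------------------------------------
# measure profiles


@dataclass
class GlobalMeasureProfile:
    """Global measures of one group: weighted strength plus per-density curves."""

    group: str
    average_strength: float
    densities: np.ndarray
    global_efficiency: np.ndarray
    transitivity: np.ndarray
    local_efficiency: np.ndarray
    small_worldness: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "group": self.group,
                "measure": "average_strength",
                "density": np.nan,
                "node_or_global": "global",
                "value": self.average_strength,
            }
        ]
        curves = {
            "global_efficiency": self.global_efficiency,
            "transitivity": self.transitivity,
            "local_efficiency": self.local_efficiency,
        }
        if self.small_worldness is not None:
            curves["small_worldness"] = self.small_worldness
        for name, vals in curves.items():
            for d, v in zip(self.densities, vals):
                rows.append(
                    {
                        "group": self.group,
                        "measure": name,
                        "density": float(d),
                        "node_or_global": "global",
                        "value": float(v),
                    }
                )
        return pd.DataFrame(rows)


@dataclass
class NodalMeasureProfile:
    """Nodal measures of one group at a chosen density."""

    group: str
    density: float
    strength: pd.Series
    participation: pd.Series
    global_efficiency: pd.Series
    local_efficiency: pd.Series

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, series in (
            ("strength", self.strength),
            ("participation", self.participation),
            ("global_efficiency", self.global_efficiency),
            ("local_efficiency", self.local_efficiency),
        ):
            density = np.nan if name == "strength" else self.density
            for node, v in series.items():
                rows.append(
                    {
                        "group": self.group,
                        "measure": name,
                        "density": density,
                        "node_or_global": node,
                        "value": float(v),
                    }
                )
        return pd.DataFrame(rows)


def global_measures(
    w: WeightedConnectome,
    grid: DensityGrid,
    with_small_world: bool = False,
    n_random: int = 100,
    seed: int = 0,
) -> GlobalMeasureProfile:
    """Compute the global measure profile of one connectome over a grid."""
    densities = grid.densities
    geff = np.empty(len(densities))
    trans = np.empty(len(densities))
    leff = np.empty(len(densities))
    sigma = np.empty(len(densities)) if with_small_world else None
    rng = np.random.default_rng(seed)
    for i, d in enumerate(densities):
        g = binarize(w, float(d))
        geff[i] = global_efficiency(g)
        trans[i] = transitivity(g)
        leff[i] = local_efficiency(g)
        if with_small_world:
            sigma[i] = small_worldness(g, n_random=n_random, seed=int(rng.integers(2**31)))
    return GlobalMeasureProfile(
        group=w.group,
        average_strength=average_strength(w),
        densities=densities,
        global_efficiency=geff,
        transitivity=trans,
        local_efficiency=leff,
        small_worldness=sigma,
    )


def nodal_measures(
    w: WeightedConnectome,
    density: float,
    communities: Mapping[str, str],
) -> NodalMeasureProfile:
    """Compute the nodal measure profile of one connectome at one density."""
    g = binarize(w, density)
    return NodalMeasureProfile(
        group=w.group,
        density=density,
        strength=nodal_strength(w),
        participation=participation(g, communities),
        global_efficiency=nodal_global_efficiency(g),
        local_efficiency=nodal_local_efficiency(g),
    )
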