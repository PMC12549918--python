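"""Permutation-based group comparison of connectome measures.

Two groups are compared by pooling their (residualized) participants
and repeatedly re-splitting them into pseudo-groups of the original
sizes; connectomes and measures are rebuilt on every split. Global
binary measures are tested across the whole density sweep and declared
significant only when the observed difference falls outside the null
envelope at a minimum number of consecutive densities; weighted average
strength is tested once. Nodal measures are tested at the median
density with Benjamini-Hochberg FDR across nodes within each measure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from ._kernels import (
    adjacency_from_order,
    global_binary_profile,
    nodal_global_efficiency,
    nodal_local_efficiency,
    nodal_participation,
)
from .connectome import DensityGrid, edge_count, ranked_edge_order, spearman_matrix
from .datasets import CognitiveDataset

GLOBAL_BINARY_MEASURES = ("global_efficiency", "transitivity", "local_efficiency")
NODAL_MEASURES = ("strength", "participation", "global_efficiency", "local_efficiency")


class ComparisonError(ValueError):
    pass


@dataclass(frozen=True)
class PermutationSpec:
    """Settings of the permutation comparison."""

    n_perm: int = 1000
    seed: int = 0
    alpha: float = 0.05
    min_consecutive: int = 5
    nodal_density: float = 0.20
    envelope: str = "percentile"  # or "sd" for +/- z * SD of null differences

    def __post_init__(self) -> None:
        if self.n_perm < 100:
            raise ComparisonError("n_perm must be >= 100")
        if not (0 < self.alpha < 0.5):
            raise ComparisonError("alpha must lie in (0, 0.5)")
        if self.min_consecutive < 1:
            raise ComparisonError("min_consecutive must be >= 1")
        if self.envelope not in ("percentile", "sd"):
            raise ComparisonError("envelope must be 'percentile' or 'sd'")


def consecutive_run(flags: Sequence[bool], k: int) -> bool:
    """True iff the sequence contains a run of >= k consecutive True."""
    if k < 1:
        raise ComparisonError("k must be >= 1")
    run = 0
    for f in flags:
        run = run + 1 if f else 0
        if run >= k:
            return True
    return False


def fdr_bh(pvalues: Sequence[float], alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (reject decisions, adjusted p-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return reject, p_adj


def permutation_p(observed: np.ndarray, nulls: np.ndarray) -> np.ndarray:
    """Two-tailed add-one permutation p-value per statistic."""
    n_perm = nulls.shape[0]
    exceed = (np.abs(nulls) >= np.abs(observed)[None, :]).sum(axis=0)
    return (1.0 + exceed) / (n_perm + 1.0)


# ---------------------------------------------------------------------------
# permutation engine


def _scores_matrix(data: CognitiveDataset, group: str | None = None) -> np.ndarray:
    X = data.scores(group)
    if np.isnan(X).any():
        raise ComparisonError("comparison requires complete-case data")
    return X


def _engine(
    XA: np.ndarray,
    XB: np.ndarray,
    stat_fn: Callable[[np.ndarray], np.ndarray],
    spec: PermutationSpec,
) -> tuple[np.ndarray, np.ndarray]:
    """Observed statistic difference and its permutation null samples."""
    nA, nB = XA.shape[0], XB.shape[0]
    if min(nA, nB) < 3:
        raise ComparisonError("each (pseudo-)group needs >= 3 participants")
    observed = np.asarray(stat_fn(XA) - stat_fn(XB), dtype=float)
    pooled = np.vstack([XA, XB])
    rng = np.random.default_rng(spec.seed)
    nulls = np.empty((spec.n_perm, observed.size))
    for p in range(spec.n_perm):
        perm = rng.permutation(nA + nB)
        nulls[p] = stat_fn(pooled[perm[:nA]]) - stat_fn(pooled[perm[nA:]])
    return observed, nulls


def permutation_null(
    dataA: CognitiveDataset,
    dataB: CognitiveDataset,
    statistic: Callable[[np.ndarray], np.ndarray],
    spec: PermutationSpec,
) -> tuple[np.ndarray, np.ndarray]:
    """Generic permutation null for a statistic of one group's score matrix.

    Returns ``(observed_difference, null_differences)`` where the null
    array has one row per permutation. The statistic receives the score
    matrix (participants x measures) of a pseudo-group and must return a
    scalar or vector; connectome-based statistics therefore rebuild the
    connectome on every split.
    """
    if dataA.measures != dataB.measures:
        raise ComparisonError("the two datasets must share the same measures")
    return _engine(
        _scores_matrix(dataA), _scores_matrix(dataB), _as_vector(statistic), spec
    )


def _as_vector(stat_fn):
    def wrapped(X):
        return np.atleast_1d(np.asarray(stat_fn(X), dtype=float))

    return wrapped


def _envelope(
    nulls: np.ndarray, spec: PermutationSpec
) -> tuple[np.ndarray, np.ndarray]:
    if spec.envelope == "percentile":
        lo = np.percentile(nulls, 100 * spec.alpha / 2, axis=0)
        hi = np.percentile(nulls, 100 * (1 - spec.alpha / 2), axis=0)
    else:
        from scipy import stats as _st

        z = _st.norm.ppf(1 - spec.alpha / 2)
        mu = nulls.mean(axis=0)
        sd = nulls.std(axis=0, ddof=1)
        lo, hi = mu - z * sd, mu + z * sd
    return lo, hi


# ---------------------------------------------------------------------------
# global comparison


@dataclass
class GlobalComparisonResult:
    """Global-measure comparison of two groups over the density sweep."""

    group_a: str
    group_b: str
    densities: np.ndarray
    observed: dict[str, np.ndarray]  # per binary measure, per density
    null_lo: dict[str, np.ndarray]
    null_hi: dict[str, np.ndarray]
    flags: dict[str, np.ndarray]  # outside-envelope per density
    significant: dict[str, bool]  # consecutive-density rule
    strength_observed: float
    strength_p: float
    strength_significant: bool
    spec: PermutationSpec = field(default_factory=PermutationSpec)
    n_a: int = 0
    n_b: int = 0

    def direction(self, measure: str) -> int:
        """Sign of the observed difference (A minus B) for a measure.

        Uses the flagged densities when any exist, the whole sweep
        otherwise; ``average_strength`` uses its single observed value.
        """
        if measure == "average_strength":
            return int(np.sign(self.strength_observed))
        obs = self.observed[measure]
        mask = self.flags[measure]
        vals = obs[mask] if mask.any() else obs
        return int(np.sign(vals.mean()))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "group_pair": f"{self.group_a}_vs_{self.group_b}",
                "measure": "average_strength",
                "density": np.nan,
                "observed_diff": self.strength_observed,
                "null_lo": np.nan,
                "null_hi": np.nan,
                "p": self.strength_p,
                "significant": self.strength_significant,
            }
        ]
        for m in GLOBAL_BINARY_MEASURES:
            for i, d in enumerate(self.densities):
                rows.append(
                    {
                        "group_pair": f"{self.group_a}_vs_{self.group_b}",
                        "measure": m,
                        "density": float(d),
                        "observed_diff": float(self.observed[m][i]),
                        "null_lo": float(self.null_lo[m][i]),
                        "null_hi": float(self.null_hi[m][i]),
                        "p": np.nan,
                        "significant": bool(self.significant[m]),
                    }
                )
        return pd.DataFrame(rows)

    def summary(self) -> dict:
        out = {
            "group_pair": f"{self.group_a}_vs_{self.group_b}",
            "average_strength": {
                "observed": self.strength_observed,
                "p": self.strength_p,
                "significant": self.strength_significant,
            },
        }
        for m in GLOBAL_BINARY_MEASURES:
            out[m] = {
                "significant": bool(self.significant[m]),
                "direction": self.direction(m),
                "n_flagged_densities": int(self.flags[m].sum()),
            }
        return out


def _global_stat_builder(n_nodes: int, grid: DensityGrid):
    rows, cols = np.triu_indices(n_nodes, k=1)
    edge_counts = np.array(
        [edge_count(float(d), n_nodes) for d in grid.densities], dtype=np.int64
    )
    if np.any(edge_counts == 0):
        raise ComparisonError("density grid yields zero edges at some density")
    iu = (rows, cols)

    def stat(X: np.ndarray) -> np.ndarray:
        corr = spearman_matrix(X)
        cond = corr[iu]
        order = ranked_edge_order(cond)
        prof = global_binary_profile(order, rows, cols, edge_counts, n_nodes)
        strength = corr.sum(axis=0).mean()
        # layout: [strength, geff..., trans..., leff...]
        return np.concatenate([[strength], prof[:, 0], prof[:, 1], prof[:, 2]])

    return stat


def compare_global(
    dataA: CognitiveDataset,
    dataB: CognitiveDataset,
    grid: DensityGrid | None = None,
    spec: PermutationSpec | None = None,
) -> GlobalComparisonResult:
    """Permutation comparison of global measures over the density sweep.

    A binary measure is significant when the observed difference lies
    outside the null envelope at >= ``spec.min_consecutive`` consecutive
    densities; average strength is tested once on the weighted matrices
    with a two-tailed add-one permutation p-value.
    """
    grid = grid or DensityGrid()
    spec = spec or PermutationSpec()
    if dataA.measures != dataB.measures:
        raise ComparisonError("the two datasets must share the same measures")
    n_nodes = len(dataA.measures)
    stat = _global_stat_builder(n_nodes, grid)
    observed, nulls = _engine(_scores_matrix(dataA), _scores_matrix(dataB), stat, spec)
    lo, hi = _envelope(nulls, spec)
    nd = len(grid.densities)
    obs_d: dict[str, np.ndarray] = {}
    lo_d: dict[str, np.ndarray] = {}
    hi_d: dict[str, np.ndarray] = {}
    flags: dict[str, np.ndarray] = {}
    signif: dict[str, bool] = {}
    for k, m in enumerate(GLOBAL_BINARY_MEASURES):
        sl = slice(1 + k * nd, 1 + (k + 1) * nd)
        obs_d[m] = observed[sl]
        lo_d[m] = lo[sl]
        hi_d[m] = hi[sl]
        flags[m] = (obs_d[m] < lo_d[m]) | (obs_d[m] > hi_d[m])
        signif[m] = consecutive_run(flags[m], spec.min_consecutive)
    strength_p = float(permutation_p(observed[:1], nulls[:, :1])[0])
    groupA = dataA.groups[0] if dataA.groups else "A"
    groupB = dataB.groups[0] if dataB.groups else "B"
    return GlobalComparisonResult(
        group_a=groupA,
        group_b=groupB,
        densities=grid.densities,
        observed=obs_d,
        null_lo=lo_d,
        null_hi=hi_d,
        flags=flags,
        significant=signif,
        strength_observed=float(observed[0]),
        strength_p=strength_p,
        strength_significant=strength_p <= spec.alpha,
        spec=spec,
        n_a=dataA.n_participants,
        n_b=dataB.n_participants,
    )


# ---------------------------------------------------------------------------
# nodal comparison


@dataclass
class NodalComparisonResult:
    """Nodal-measure comparison at the median density, FDR across nodes."""

    group_a: str
    group_b: str
    density: float
    adjacent_densities: tuple[float, ...]
    table: pd.DataFrame  # node, measure, observed_diff, p, p_adj,
    # fdr_significant, consistent_adjacent

    def discoveries(self, measure: str | None = None) -> pd.DataFrame:
        t = self.table[self.table["fdr_significant"]]
        if measure is not None:
            t = t[t["measure"] == measure]
        return t

    def to_frame(self) -> pd.DataFrame:
        out = self.table.copy()
        out.insert(0, "group_pair", f"{self.group_a}_vs_{self.group_b}")
        return out


def _nodal_stat_builder(
    n_nodes: int,
    grid: DensityGrid,
    densities: Sequence[float],
    modules: np.ndarray,
    n_modules: int,
):
    rows, cols = np.triu_indices(n_nodes, k=1)
    edge_counts = [edge_count(float(d), n_nodes) for d in densities]
    iu = (rows, cols)

    def stat(X: np.ndarray) -> np.ndarray:
        corr = spearman_matrix(X)
        order = ranked_edge_order(corr[iu])
        parts = [corr.sum(axis=0)]  # nodal strength, weighted
        for k in edge_counts:
            adj = adjacency_from_order(order, rows, cols, k, n_nodes)
            parts.append(nodal_participation(adj, modules, n_modules))
            parts.append(nodal_global_efficiency(adj))
            parts.append(nodal_local_efficiency(adj))
        return np.concatenate(parts)

    return stat


def compare_nodal(
    dataA: CognitiveDataset,
    dataB: CognitiveDataset,
    grid: DensityGrid | None = None,
    spec: PermutationSpec | None = None,
    communities: Mapping[str, str] | None = None,
) -> NodalComparisonResult:
    """Permutation comparison of nodal measures at the median density.

    Tests nodal strength (weighted), participation, nodal global
    efficiency and nodal local efficiency with two-tailed add-one
    permutation p-values, FDR-adjusted across nodes within each
    measure. Decisions are recomputed at the two adjacent grid
    densities; ``consistent_adjacent`` records whether the median-
    density decision agrees with both neighbours (strength, being
    density-free, is always consistent).
    """
    grid = grid or DensityGrid()
    spec = spec or PermutationSpec()
    if dataA.measures != dataB.measures:
        raise ComparisonError("the two datasets must share the same measures")
    if spec.nodal_density not in grid:
        raise ComparisonError(
            f"nodal density {spec.nodal_density} not in the density grid"
        )
    nodes = dataA.measures
    n_nodes = len(nodes)
    if communities is None:
        communities = {m: dataA.measure_meta[m].domain for m in nodes}
    module_names = sorted(set(communities[m] for m in nodes))
    lut = {m: i for i, m in enumerate(module_names)}
    modules = np.array([lut[communities[m]] for m in nodes], dtype=np.int64)

    dens = grid.densities
    idx = int(np.argmin(np.abs(dens - spec.nodal_density)))
    adjacent = [float(dens[i]) for i in (idx - 1, idx + 1) if 0 <= i < len(dens)]
    all_densities = [float(dens[idx])] + adjacent

    stat = _nodal_stat_builder(n_nodes, grid, all_densities, modules, len(module_names))
    observed, nulls = _engine(_scores_matrix(dataA), _scores_matrix(dataB), stat, spec)
    pvals = permutation_p(observed, nulls)

    binary_measures = ("participation", "global_efficiency", "local_efficiency")

    def block(di: int, mi: int) -> slice:
        start = n_nodes + (di * 3 + mi) * n_nodes
        return slice(start, start + n_nodes)

    # decisions per density per measure
    decisions: dict[tuple[float, str], np.ndarray] = {}
    adj_p: dict[str, np.ndarray] = {}
    for di, d in enumerate(all_densities):
        for mi, m in enumerate(binary_measures):
            rej, padj = fdr_bh(pvals[block(di, mi)], spec.alpha)
            decisions[(d, m)] = rej
            if di == 0:
                adj_p[m] = padj
    strength_rej, strength_padj = fdr_bh(pvals[:n_nodes], spec.alpha)

    rows_out = []
    for j, node in enumerate(nodes):
        rows_out.append(
            {
                "node": node,
                "measure": "strength",
                "observed_diff": float(observed[j]),
                "p": float(pvals[j]),
                "p_adj": float(strength_padj[j]),
                "fdr_significant": bool(strength_rej[j]),
                "consistent_adjacent": True,
            }
        )
    for mi, m in enumerate(binary_measures):
        med = decisions[(all_densities[0], m)]
        sl = block(0, mi)
        for j, node in enumerate(nodes):
            consistent = all(
                decisions[(d, m)][j] == med[j] for d in adjacent
            )
            rows_out.append(
                {
                    "node": node,
                    "measure": m,
                    "observed_diff": float(observed[sl][j]),
                    "p": float(pvals[sl][j]),
                    "p_adj": float(adj_p[m][j]),
                    "fdr_significant": bool(med[j]),
                    "consistent_adjacent": bool(consistent),
                }
            )
    groupA = dataA.groups[0] if dataA.groups else "A"
    groupB = dataB.groups[0] if dataB.groups else "B"
    return NodalComparisonResult(
        group_a=groupA,
        group_b=groupB,
        density=all_densities[0],
        adjacent_densities=tuple(adjacent),
        table=pd.DataFrame(rows_out),
    )


# ---------------------------------------------------------------------------
# plotting (difference-vs-density curves with null envelopes)


def plot_global_differences(result: GlobalComparisonResult, path: str | Path) -> None:
    """Write difference-vs-density curves with the null envelope shaded."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(12, 3.2), sharex=True)
    for ax, m in zip(axes, GLOBAL_BINARY_MEASURES):
        ax.fill_between(
            result.densities,
            result.null_lo[m],
            result.null_hi[m],
            color="0.85",
            label="null 95% envelope",
        )
        ax.plot(result.densities, result.observed[m], "ro-", ms=3, lw=0.8)
        ax.axhline(0, color="k", lw=0.5)
        tag = "significant" if result.significant[m] else "n.s."
        ax.set_title(f"{m} ({tag})", fontsize=9)
        ax.set_xlabel("density")
    axes[0].set_ylabel(f"{result.group_a} − {result.group_b}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
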