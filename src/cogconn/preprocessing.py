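"""Preprocessing of raw cognitive cohorts into analysis-ready scores.

The standard chain is: orient all measures so higher = better, drop
measures with excessive missingness (and restrict to complete cases),
transform skewed measures monotonically, residualize covariates (age,
sex, education), z-score against a reference group, and optionally
average z-scores into domain composites. All steps are deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .datasets import COVARIATES, CognitiveDataset, MeasureMeta


class PreprocessError(ValueError):
    pass


@dataclass
class PreprocessReport:
    """Machine-readable record of preprocessing decisions."""

    excluded_measures: dict[str, str] = field(default_factory=dict)
    transforms_applied: dict[str, str] = field(default_factory=dict)
    regression_models: dict[str, str] = field(default_factory=dict)
    inverted_measures: list[str] = field(default_factory=list)
    n_rows_dropped: int = 0

    def merge(self, other: "PreprocessReport") -> "PreprocessReport":
        return PreprocessReport(
            excluded_measures={**self.excluded_measures, **other.excluded_measures},
            transforms_applied={**self.transforms_applied, **other.transforms_applied},
            regression_models={**self.regression_models, **other.regression_models},
            inverted_measures=self.inverted_measures + other.inverted_measures,
            n_rows_dropped=self.n_rows_dropped + other.n_rows_dropped,
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, sort_keys=True))


def orient_measures(
    data: CognitiveDataset,
) -> tuple[CognitiveDataset, PreprocessReport]:
    """Negate higher-is-worse measures so higher always means better.

    The orientation flag is flipped on the returned metadata, so a
    second application is a no-op.
    """
    out = data.copy()
    report = PreprocessReport()
    updates: dict[str, MeasureMeta] = {}
    for m in out.measures:
        meta = out.measure_meta[m]
        if meta.orientation == "higher_worse":
            out.table[m] = -out.table[m]
            updates[m] = MeasureMeta(
                domain=meta.domain,
                orientation="higher_better",
                scale_type=meta.scale_type,
                instrument=meta.instrument,
            )
            report.inverted_measures.append(m)
    return out.with_meta(updates), report


def filter_missing(
    data: CognitiveDataset, max_frac: float = 0.15
) -> tuple[CognitiveDataset, PreprocessReport]:
    """Drop measures missing in strictly more than ``max_frac`` of rows.

    After dropping, rows are restricted to complete cases across the
    retained measures, so downstream correlations use one common sample.
    """
    if not (0 < max_frac < 1):
        raise PreprocessError("max_frac must lie in (0, 1)")
    report = PreprocessReport()
    n = data.n_participants
    drop = []
    for m in data.measures:
        frac = data.table[m].isna().sum() / n
        if frac > max_frac:
            drop.append(m)
            report.excluded_measures[m] = (
                f"missingness {frac:.3f} > {max_frac:.2f}"
            )
    out = data.drop_measures(drop) if drop else data.copy()
    if not out.measures:
        raise PreprocessError("missingness filter excluded every measure")
    complete = out.table.dropna(subset=out.measures)
    report.n_rows_dropped = len(out.table) - len(complete)
    return out.with_table(complete), report


def _sample_skewness(x: np.ndarray) -> float:
    return float(stats.skew(x, bias=True))


def transform_skew(
    data: CognitiveDataset, skew_threshold: float = 1.0
) -> tuple[CognitiveDataset, PreprocessReport]:
    """Monotone log transform of measures with |skewness| above threshold.

    Right-skewed measures get ``log1p(x - min(x))``; left-skewed ones
    the reflected ``-log1p(max(x) - x)``. Both are strictly monotone, so
    Spearman correlations with other measures are unchanged wherever no
    ties are created. Constant measures are flagged, not transformed.
    """
    out = data.copy()
    report = PreprocessReport()
    for m in out.measures:
        x = out.table[m].to_numpy(dtype=float)
        obs = x[~np.isnan(x)]
        if obs.size == 0 or np.all(obs == obs[0]):
            report.transforms_applied[m] = "none:degenerate_constant"
            continue
        skew = _sample_skewness(obs)
        if abs(skew) <= skew_threshold:
            continue
        if skew > 0:
            out.table[m] = np.log1p(x - np.nanmin(x))
            report.transforms_applied[m] = "log1p_shifted"
        else:
            out.table[m] = -np.log1p(np.nanmax(x) - x)
            report.transforms_applied[m] = "reflected_log1p"
    return out, report


def _is_binary_like(x: np.ndarray) -> bool:
    return np.unique(x[~np.isnan(x)]).size <= 2


def residualize(
    data: CognitiveDataset,
    covariates: Sequence[str] = COVARIATES,
) -> tuple[CognitiveDataset, PreprocessReport]:
    """Remove covariate effects from every measure.

    Continuous measures are replaced by residuals of an ordinary linear
    model on the covariates, fitted on the pooled sample across all
    groups (group mean differences — the quantity under study — are
    retained in the residuals). Measures with at most two observed
    values are treated as binary and replaced by observed minus the
    fitted probability of a logistic model.
    """
    out = data.copy()
    report = PreprocessReport()
    cov = out.table[list(covariates)].to_numpy(dtype=float)
    if np.isnan(cov).any():
        raise PreprocessError("covariates contain missing values")
    flat = [c for c, s in zip(covariates, cov.std(axis=0)) if s == 0]
    if flat:
        raise PreprocessError(f"zero-variance covariate(s): {flat}")
    design = sm.add_constant(cov, has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise PreprocessError(f"singular design over covariates {list(covariates)}")
    if len(out.table) < 10:
        raise PreprocessError("need at least 10 rows to fit covariate models")
    for m in out.measures:
        y = out.table[m].to_numpy(dtype=float)
        mask = ~np.isnan(y)
        if _is_binary_like(y) and out.measure_meta[m].scale_type == "discrete_bounded":
            vals = np.unique(y[mask])
            y01 = (y == vals[-1]).astype(float)
            model = sm.Logit(y01[mask], design[mask]).fit(disp=0)
            resid = np.full_like(y, np.nan)
            resid[mask] = y01[mask] - model.predict(design[mask])
            report.regression_models[m] = "logistic"
        else:
            model = sm.OLS(y[mask], design[mask]).fit()
            resid = np.full_like(y, np.nan)
            resid[mask] = model.resid
            report.regression_models[m] = "linear"
        out.table[m] = resid
    return out, report


def zscore_reference(
    data: CognitiveDataset, reference_group: str
) -> CognitiveDataset:
    """Standardize every measure by the reference group's mean and SD."""
    out = data.copy()
    ref = out.group_table(reference_group)
    if len(ref) < 2:
        raise PreprocessError(
            f"reference group {reference_group!r} needs >= 2 rows"
        )
    for m in out.measures:
        mu = ref[m].mean()
        sd = ref[m].std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise PreprocessError(
                f"reference SD is zero or undefined for measure {m!r}"
            )
        out.table[m] = (out.table[m] - mu) / sd
    return out


def domain_composites(
    data: CognitiveDataset, domain_map: dict[str, str] | None = None
) -> pd.DataFrame:
    """Per-participant mean z-score of each domain's member measures."""
    if domain_map is None:
        domain_map = {m: data.measure_meta[m].domain for m in data.measures}
    domains: dict[str, list[str]] = {}
    for m, d in domain_map.items():
        domains.setdefault(d, []).append(m)
    for d, members in domains.items():
        if not members:
            raise PreprocessError(f"domain {d!r} has no member measures")
    comp = pd.DataFrame(index=data.table.index)
    for d, members in domains.items():
        comp[d] = data.table[members].mean(axis=1)
    return comp


def preprocess(
    data: CognitiveDataset,
    reference_group: str,
    max_missing_frac: float = 0.15,
    skew_threshold: float = 1.0,
    covariates: Sequence[str] = COVARIATES,
) -> tuple[CognitiveDataset, PreprocessReport]:
    """Full deterministic preprocessing chain."""
    out, rep = orient_measures(data)
    out, r = filter_missing(out, max_missing_frac)
    rep = rep.merge(r)
    out, r = transform_skew(out, skew_threshold)
    rep = rep.merge(r)
    out, r = residualize(out, covariates)
    rep = rep.merge(r)
    out = zscore_reference(out, reference_group)
    return out, rep
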