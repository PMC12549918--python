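"""Robustness checks: leave-k-out replication and size-matched subsampling.

A finding (a globally significant measure with its direction, or a
nodal FDR discovery) "replicates" in a resampled analysis when the same
significance flag and the same sign of the group difference recur.
Sampling is without replacement, drawn independently per group, and
fully determined by the PermutationSpec seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .comparison import (
    GLOBAL_BINARY_MEASURES,
    ComparisonError,
    GlobalComparisonResult,
    PermutationSpec,
    compare_global,
)
from .connectome import DensityGrid
from .datasets import CognitiveDataset


class StabilityError(ValueError):
    pass


def _drop_rows(data: CognitiveDataset, k: int, rng: np.random.Generator) -> CognitiveDataset:
    n = data.n_participants
    if k == 0:
        return data
    drop = rng.choice(n, size=k, replace=False)
    keep = np.setdiff1d(np.arange(n), drop)
    return data.with_table(data.table.iloc[keep])


def _findings(result: GlobalComparisonResult) -> dict[str, tuple[bool, int]]:
    out = {
        m: (result.significant[m], result.direction(m))
        for m in GLOBAL_BINARY_MEASURES
    }
    out["average_strength"] = (
        result.strength_significant,
        result.direction("average_strength"),
    )
    return out


@dataclass
class StabilityReport:
    """Replication of the primary findings over resampled analyses."""

    primary: GlobalComparisonResult
    iterations: list[GlobalComparisonResult]
    seeds: list[int]
    agreement: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.agreement:
            base = _findings(self.primary)
            reps = [_findings(r) for r in self.iterations]
            for m, (sig, sign) in base.items():
                if not self.iterations:
                    self.agreement[m] = float("nan")
                    continue
                ok = 0
                for r in reps:
                    rsig, rsign = r[m]
                    if rsig == sig and (not sig or rsign == sign):
                        ok += 1
                self.agreement[m] = ok / len(reps)

    def replicated(self, measure: str) -> bool:
        """True when the primary finding recurred in every iteration."""
        return self.agreement[measure] == 1.0

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seeds": self.seeds,
            "agreement": self.agreement,
            "primary": self.primary.summary(),
            "iterations": [r.summary() for r in self.iterations],
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def leave_k_out(
    dataA: CognitiveDataset,
    dataB: CognitiveDataset,
    k: int = 5,
    iterations: int = 5,
    grid: DensityGrid | None = None,
    spec: PermutationSpec | None = None,
    primary: GlobalComparisonResult | None = None,
) -> StabilityReport:
    """Rerun the global comparison after removing k random rows per group.

    With ``k=0`` every iteration reproduces the primary analysis
    exactly. The input datasets are never mutated.
    """
    grid = grid or DensityGrid()
    spec = spec or PermutationSpec()
    if k < 0:
        raise StabilityError("k must be >= 0")
    if k > 0 and (dataA.n_participants <= k or dataB.n_participants <= k):
        raise StabilityError(
            f"group sizes ({dataA.n_participants}, {dataB.n_participants}) "
            f"must exceed k={k}"
        )
    if primary is None:
        primary = compare_global(dataA, dataB, grid, spec)
    root = np.random.SeedSequence(spec.seed)
    seeds = [int(s.generate_state(1)[0] % 2**31) for s in root.spawn(iterations)]
    results = []
    for it_seed in seeds:
        rng = np.random.default_rng(it_seed)
        subA = _drop_rows(dataA, k, rng)
        subB = _drop_rows(dataB, k, rng)
        results.append(compare_global(subA, subB, grid, spec))
    return StabilityReport(primary=primary, iterations=results, seeds=seeds)


def size_matched_subsample(
    data_large: CognitiveDataset,
    data_small: CognitiveDataset,
    grid: DensityGrid | None = None,
    spec: PermutationSpec | None = None,
) -> tuple[GlobalComparisonResult, str]:
    """Subsample the larger group to the smaller group's size and compare.

    Returns the comparison and a notice string (empty unless the groups
    were already the same size, in which case the standard comparison is
    returned unchanged).
    """
    grid = grid or DensityGrid()
    spec = spec or PermutationSpec()
    nL, nS = data_large.n_participants, data_small.n_participants
    if nL < nS:
        raise StabilityError("data_large is smaller than data_small")
    if nL == nS:
        return (
            compare_global(data_large, data_small, grid, spec),
            "groups already size-matched; standard comparison returned",
        )
    rng = np.random.default_rng(spec.seed)
    keep = np.sort(rng.choice(nL, size=nS, replace=False))
    sub = data_large.with_table(data_large.table.iloc[keep])
    return compare_global(sub, data_small, grid, spec), ""
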