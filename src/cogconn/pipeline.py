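"""End-to-end orchestration: simulate-or-load through stability reports.

``run_pipeline`` composes the full analysis — preprocessing, per-group
connectomes, density handling, fragmenting-node exclusion, global and
nodal permutation comparisons, and stability checks — and writes every
artefact plus a manifest with content hashes. One global seed fans out
deterministically to per-stage child seeds, so identical config + seed
produces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .comparison import (
    PermutationSpec,
    compare_global,
    compare_nodal,
    plot_global_differences,
)
from .connectome import (
    DensityGrid,
    build_connectome,
    detect_fragmenting_nodes,
    select_density_range,
)
from .datasets import (
    COVARIATES,
    GROUP_COL,
    CognitiveDataset,
    load_cohort,
    load_measure_meta,
)
from .metrics import global_measures, nodal_measures
from .preprocessing import preprocess
from .stability import leave_k_out, size_matched_subsample
from .synthetic import CohortConfig, GroupSpec, generate_cohort

log = logging.getLogger("cogconn")


class PipelineError(RuntimeError):
    pass


def _stage_seed(global_seed: int, stage: int) -> int:
    ss = np.random.SeedSequence(global_seed, spawn_key=(stage,))
    return int(ss.generate_state(1)[0] % 2**31)


@dataclass
class PipelineConfig:
    """Full configuration of one pipeline run."""

    # input: either a cohort CSV + metadata sidecar, or a simulation config
    cohort_csv: str | None = None
    measure_meta: str | None = None
    simulate: CohortConfig | None = None

    reference_group: str = "hc"
    comparisons: list[tuple[str, str]] = field(
        default_factory=lambda: [("mci_lb", "hc"), ("mci_lb", "mci_ad"), ("mci_lb", "dlb")]
    )

    density: str | tuple[float, float] = (0.10, 0.30)  # or "auto"
    density_step: float = 0.01
    density_exclude: list[str] = field(default_factory=list)

    n_perm: int = 1000
    alpha: float = 0.05
    min_consecutive: int = 5
    nodal_density: float = 0.20

    stability_k: int = 5
    stability_iterations: int = 5
    run_stability: bool = True
    run_size_matched: bool = True

    max_missing_frac: float = 0.15
    skew_threshold: float = 1.0

    output_dir: str = "cogconn_output"
    seed: int = 0
    log_level: str = "INFO"
    make_plots: bool = False

    def __post_init__(self) -> None:
        if self.simulate is None and (self.cohort_csv is None or self.measure_meta is None):
            raise PipelineError(
                "config needs either `simulate` or both `cohort_csv` and `measure_meta`"
            )

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        raw = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        sim = raw.pop("simulate", None)
        if sim is not None:
            groups = [GroupSpec(**g) for g in sim.pop("groups", [])]
            sim = CohortConfig(groups=groups, **sim) if groups else CohortConfig(**sim)
        comps = [tuple(c) for c in raw.pop("comparisons", [])]
        cfg = cls(simulate=sim, **raw)
        if comps:
            cfg.comparisons = comps
        density = cfg.density
        if isinstance(density, list):
            cfg.density = tuple(density)
        return cfg

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulate is not None:
            d["simulate"] = dataclasses.asdict(self.simulate)
        return d


@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_inputs(table_path: str | Path, meta_path: str | Path) -> ValidationReport:
    """Schema check of a cohort CSV and its metadata sidecar."""
    rep = ValidationReport()
    try:
        meta = load_measure_meta(meta_path)
    except Exception as exc:  # noqa: BLE001 - reported, not raised
        rep.errors.append(f"metadata unreadable: {exc}")
        return rep
    try:
        sep = "\t" if str(table_path).endswith((".tsv", ".txt")) else ","
        table = pd.read_csv(table_path, sep=sep)
    except Exception as exc:  # noqa: BLE001
        rep.errors.append(f"cohort table unreadable: {exc}")
        return rep
    if GROUP_COL not in table.columns:
        rep.errors.append(f"cohort table lacks a {GROUP_COL!r} column")
    for cov in COVARIATES:
        if cov not in table.columns:
            rep.errors.append(f"cohort table lacks covariate column {cov!r}")
    for m in meta:
        if m not in table.columns:
            rep.errors.append(f"measure {m!r} declared in metadata but absent from table")
    known = {GROUP_COL, *COVARIATES, "participant_id", *meta}
    for c in table.columns:
        if c not in known:
            rep.warnings.append(f"unknown extra column {c!r} (ignored)")
    if GROUP_COL in table.columns:
        if table[GROUP_COL].isna().any():
            rep.errors.append("empty group labels present")
        elif table[GROUP_COL].nunique() < 2:
            rep.warnings.append("fewer than two groups; comparisons impossible")
    return rep


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the run manifest (also written).

    Stages: load/simulate -> preprocess -> connectomes (with
    fragmenting-node exclusion) -> density grid -> metric tables ->
    pairwise comparisons -> stability. Every output lands in
    ``config.output_dir``.
    """
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = {
        "simulate": _stage_seed(config.seed, 0),
        "density_selection": _stage_seed(config.seed, 1),
        "comparison": _stage_seed(config.seed, 2),
        "stability": _stage_seed(config.seed, 3),
        "metrics": _stage_seed(config.seed, 4),
    }

    # -- stage 1: input ----------------------------------------------------
    if config.simulate is not None:
        sim = dataclasses.replace(config.simulate, seed=seeds["simulate"])
        log.info("simulating cohort (seed %d)", sim.seed)
        data = generate_cohort(sim)
        data.to_csv(outdir / "cohort_raw.csv")
        data.meta_to_yaml(outdir / "measure_meta.yaml")
    else:
        for p in (config.cohort_csv, config.measure_meta):
            if not Path(p).exists():
                raise PipelineError(f"input stage: file not found: {p}")
        report = validate_inputs(config.cohort_csv, config.measure_meta)
        for w in report.warnings:
            log.warning("input validation: %s", w)
        if not report.ok:
            raise PipelineError(
                "input stage: schema errors: " + "; ".join(report.errors)
            )
        data = load_cohort(config.cohort_csv, config.measure_meta)
    if config.reference_group not in data.groups:
        raise PipelineError(
            f"input stage: reference group {config.reference_group!r} absent "
            f"(groups: {data.groups})"
        )

    # -- stage 2: preprocessing -------------------------------------------
    log.info("preprocessing %d participants, %d measures", data.n_participants, len(data.measures))
    clean, prep_report = preprocess(
        data,
        reference_group=config.reference_group,
        max_missing_frac=config.max_missing_frac,
        skew_threshold=config.skew_threshold,
    )
    prep_report.to_json(outdir / "preprocess_report.json")
    clean.to_csv(outdir / "cohort_preprocessed.csv")

    # -- stage 3: density grid + fragmenting nodes ------------------------
    ref = build_connectome(clean, config.reference_group)
    if config.density == "auto":
        log.info("auto-selecting density range on %r", config.reference_group)
        grid = select_density_range(
            ref,
            exclude_labels=config.density_exclude,
            step=config.density_step,
            seed=seeds["density_selection"],
        )
    else:
        d_min, d_max = config.density
        grid = DensityGrid(d_min, d_max, config.density_step)
    log.info("density grid: %.2f-%.2f step %.2f", grid.d_min, grid.d_max, grid.step)

    fragmenting = detect_fragmenting_nodes(ref, grid)
    if fragmenting:
        log.info("excluding fragmenting node(s): %s", fragmenting)
        clean = clean.drop_measures(fragmenting)
    (outdir / "fragmenting_nodes.json").write_text(json.dumps(fragmenting))

    # -- stage 4: per-group connectomes and metric tables ------------------
    connectomes = {g: build_connectome(clean, g) for g in clean.groups}
    for g, w in connectomes.items():
        w.to_csv(outdir / f"connectome_{g}.csv")
    communities = {m: clean.measure_meta[m].domain for m in clean.measures}
    metric_frames = []
    rng = np.random.default_rng(seeds["metrics"])
    for g, w in connectomes.items():
        prof = global_measures(
            w, grid, with_small_world=True, n_random=50, seed=int(rng.integers(2**31))
        )
        metric_frames.append(prof.to_frame())
        nod = nodal_measures(w, config.nodal_density, communities)
        metric_frames.append(nod.to_frame())
    pd.concat(metric_frames, ignore_index=True).to_csv(
        outdir / "metric_tables.csv", index=False
    )

    # -- stage 5: comparisons ---------------------------------------------
    summaries = {}
    by_group = {g: clean.with_table(clean.group_table(g)) for g in clean.groups}
    for i, (a, b) in enumerate(config.comparisons):
        for g in (a, b):
            if g not in by_group:
                raise PipelineError(f"comparison stage: group {g!r} not in data")
        spec = PermutationSpec(
            n_perm=config.n_perm,
            seed=_stage_seed(seeds["comparison"], i),
            alpha=config.alpha,
            min_consecutive=config.min_consecutive,
            nodal_density=config.nodal_density,
        )
        log.info("comparing %s vs %s (%d permutations)", a, b, spec.n_perm)
        gres = compare_global(by_group[a], by_group[b], grid, spec)
        nres = compare_nodal(by_group[a], by_group[b], grid, spec, communities)
        tag = f"{a}_vs_{b}"
        gres.to_frame().to_csv(outdir / f"comparison_{tag}_global.csv", index=False)
        nres.to_frame().to_csv(outdir / f"comparison_{tag}_nodal.csv", index=False)
        summaries[tag] = gres.summary()
        if config.make_plots:
            plot_global_differences(gres, outdir / f"comparison_{tag}_global.png")

        # -- stage 6: stability -------------------------------------------
        if config.run_stability:
            sspec = dataclasses.replace(spec, seed=_stage_seed(seeds["stability"], i))
            rep = leave_k_out(
                by_group[a],
                by_group[b],
                k=config.stability_k,
                iterations=config.stability_iterations,
                grid=grid,
                spec=sspec,
                primary=gres,
            )
            rep.to_json(outdir / f"stability_{tag}_leave{config.stability_k}out.json")
        if config.run_size_matched:
            nA = by_group[a].n_participants
            nB = by_group[b].n_participants
            if nA != nB:
                large, small = (a, b) if nA > nB else (b, a)
                mspec = dataclasses.replace(
                    spec, seed=_stage_seed(seeds["stability"], 100 + i)
                )
                mres, notice = size_matched_subsample(
                    by_group[large], by_group[small], grid, mspec
                )
                mres.to_frame().to_csv(
                    outdir / f"comparison_{tag}_sizematched.csv", index=False
                )
                if notice:
                    log.info("size-matched: %s", notice)

    (outdir / "comparison_summaries.json").write_text(
        json.dumps(summaries, indent=2, sort_keys=True)
    )

    # -- manifest ----------------------------------------------------------
    files = sorted(
        p for p in outdir.iterdir() if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "version": __version__,
        "config": config.echo(),
        "seeds": seeds,
        "grid": {"d_min": grid.d_min, "d_max": grid.d_max, "step": grid.step},
        "fragmenting_nodes": fragmenting,
        "hashes": {p.name: _sha256(p) for p in files},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
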