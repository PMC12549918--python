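"""Participant-by-measure tables for cognitive connectome analysis.

A :class:`CognitiveDataset` wraps a pandas table with one row per
participant, a group label, the three standard covariates (age, sex,
education) and a set of named cognitive measures, plus per-measure
metadata (cognitive domain, score orientation, scale type, instrument
family).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

GROUP_COL = "group"
COVARIATES = ("age", "sex", "education")

ORIENTATIONS = ("higher_better", "higher_worse")
SCALE_TYPES = ("continuous", "discrete_bounded")


class SchemaError(ValueError):
    """Raised when a cohort table or its metadata violate the schema."""


@dataclass(frozen=True)
class MeasureMeta:
    """Metadata for one cognitive measure."""

    domain: str
    orientation: str = "higher_better"
    scale_type: str = "continuous"
    instrument: str = ""

    def __post_init__(self) -> None:
        if self.orientation not in ORIENTATIONS:
            raise SchemaError(f"unknown orientation {self.orientation!r}")
        if self.scale_type not in SCALE_TYPES:
            raise SchemaError(f"unknown scale_type {self.scale_type!r}")


@dataclass
class CognitiveDataset:
    """Participant x measure table with group labels and covariates.

    ``table`` is indexed by participant id and holds the group column,
    covariate columns and one numeric column per measure. Every measure
    column must have an entry in ``measure_meta``.
    """

    table: pd.DataFrame
    measure_meta: dict[str, MeasureMeta] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if GROUP_COL not in self.table.columns:
            raise SchemaError(f"table lacks a {GROUP_COL!r} column")
        for cov in COVARIATES:
            if cov not in self.table.columns:
                raise SchemaError(f"table lacks covariate column {cov!r}")
        for m in self.measures:
            if m not in self.measure_meta:
                raise SchemaError(f"measure {m!r} has no metadata")
        if self.table[GROUP_COL].isna().any() or (self.table[GROUP_COL] == "").any():
            raise SchemaError("empty group labels")

    # -- accessors ---------------------------------------------------------

    @property
    def measures(self) -> list[str]:
        reserved = {GROUP_COL, *COVARIATES}
        return [c for c in self.table.columns if c not in reserved]

    @property
    def groups(self) -> list[str]:
        return list(pd.unique(self.table[GROUP_COL]))

    @property
    def n_participants(self) -> int:
        return len(self.table)

    def domain_of(self, measure: str) -> str:
        return self.measure_meta[measure].domain

    @property
    def domains(self) -> list[str]:
        seen: list[str] = []
        for m in self.measures:
            d = self.measure_meta[m].domain
            if d not in seen:
                seen.append(d)
        return seen

    def group_table(self, group: str) -> pd.DataFrame:
        sub = self.table[self.table[GROUP_COL] == group]
        if sub.empty:
            raise KeyError(f"group {group!r} not present")
        return sub

    def scores(self, group: str | None = None) -> np.ndarray:
        """Measure matrix (rows = participants, columns = measures)."""
        tab = self.table if group is None else self.group_table(group)
        return tab[self.measures].to_numpy(dtype=float)

    # -- functional updates ------------------------------------------------

    def with_table(self, table: pd.DataFrame) -> "CognitiveDataset":
        meta = {m: self.measure_meta[m] for m in table.columns if m in self.measure_meta}
        return CognitiveDataset(table=table, measure_meta=meta)

    def with_meta(self, updates: Mapping[str, MeasureMeta]) -> "CognitiveDataset":
        meta = dict(self.measure_meta)
        meta.update(updates)
        return CognitiveDataset(table=self.table.copy(), measure_meta=meta)

    def drop_measures(self, names: Iterable[str]) -> "CognitiveDataset":
        names = list(names)
        table = self.table.drop(columns=names)
        return self.with_table(table)

    def copy(self) -> "CognitiveDataset":
        return CognitiveDataset(
            table=self.table.copy(),
            measure_meta=dict(self.measure_meta),
        )

    # -- I/O ---------------------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        """Write the cohort table as CSV (missing values as empty fields)."""
        self.table.to_csv(path, index=True, index_label="participant_id")

    def meta_to_yaml(self, path: str | Path) -> None:
        payload = {
            name: {
                "domain": mm.domain,
                "orientation": mm.orientation,
                "scale_type": mm.scale_type,
                "instrument": mm.instrument,
            }
            for name, mm in self.measure_meta.items()
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def load_measure_meta(path: str | Path) -> dict[str, MeasureMeta]:
    """Read a measure-metadata sidecar (YAML or JSON keyed by measure)."""
    text = Path(path).read_text()
    raw = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise SchemaError(f"metadata file {path} must map measure -> fields")
    meta = {}
    for name, fields in raw.items():
        if "domain" not in fields:
            raise SchemaError(f"measure {name!r} lacks a domain assignment")
        meta[name] = MeasureMeta(
            domain=fields["domain"],
            orientation=fields.get("orientation", "higher_better"),
            scale_type=fields.get("scale_type", "continuous"),
            instrument=fields.get("instrument", ""),
        )
    return meta


def load_cohort(
    table_path: str | Path,
    meta_path: str | Path,
    id_column: str = "participant_id",
) -> CognitiveDataset:
    """Load a cohort CSV/TSV plus its metadata sidecar."""
    sep = "\t" if str(table_path).endswith((".tsv", ".txt")) else ","
    table = pd.read_csv(table_path, sep=sep)
    if id_column in table.columns:
        table = table.set_index(id_column)
    meta = load_measure_meta(meta_path)
    known = {GROUP_COL, *COVARIATES, *meta}
    extra = [c for c in table.columns if c not in known]
    table = table.drop(columns=extra)
    return CognitiveDataset(table=table, measure_meta=meta)
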