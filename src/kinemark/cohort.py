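"""Cohort container, CSV I/O, min-max normalization and stratification.

A cohort is a longitudinal table with one row per patient x assessment day,
holding the RMK feature values and the four clinical scale scores.  Missing
values are blank cells in CSV and NaN in memory.  All operations here are
deterministic.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

from .schema import (
    ALLOWED_DAYS,
    ID_COLUMNS,
    MR_DAYS,
    SCALE_NAMES,
    SCALE_RANGES,
    DEFAULT_SCHEMA,
    RMKSchema,
)

logger = logging.getLogger(__name__)


class SchemaError(ValueError):
    """A CSV file does not conform to the expected column schema."""


class CellParseError(ValueError):
    """A numeric cell could not be parsed; carries row/column location."""

    def __init__(self, row: int, column: str, value: str):
        self.row, self.column, self.value = row, column, value
        super().__init__(f"unparseable numeric value {value!r} at row {row}, column {column!r}")


@dataclass
class AssessmentRecord:
    """One patient x day row: RMK values, scale scores, with NaN = missing."""

    patient_id: str
    site: str
    day: int
    rmk: dict[str, float]
    fm: float = np.nan
    mp: float = np.nan
    nih: float = np.nan
    mr: float = np.nan

    def scale(self, name: str) -> float:
        return getattr(self, name.lower())


@dataclass
class Cohort:
    """Longitudinal RMK + clinical-scale table.

    ``data`` columns are ``patient_id, site, day, <35 features>, FM, MP,
    NIH, MR``.  ``norm_state`` maps feature -> (min, max) once the cohort
    has been min-max normalized; ``None`` means raw values.
    """

    schema: RMKSchema
    data: pd.DataFrame
    norm_state: dict[str, tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        missing = [c for c in self.schema.columns() if c not in self.data.columns]
        if missing:
            raise SchemaError(f"cohort table missing required columns: {missing}")
        bad_days = set(self.data["day"].unique()) - ALLOWED_DAYS
        if bad_days:
            raise ValueError(f"assessment days outside the allowed schedule: {sorted(bad_days)}")
        self.data = self.data.loc[:, list(self.schema.columns())].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def is_normalized(self) -> bool:
        return self.norm_state is not None

    @property
    def patients(self) -> list[str]:
        return list(dict.fromkeys(self.data["patient_id"]))

    def records(self) -> Iterator[AssessmentRecord]:
        feats = self.schema.features
        for _, row in self.data.iterrows():
            yield AssessmentRecord(
                patient_id=str(row["patient_id"]),
                site=str(row["site"]),
                day=int(row["day"]),
                rmk={f: float(row[f]) for f in feats},
                fm=float(row["FM"]),
                mp=float(row["MP"]),
                nih=float(row["NIH"]),
                mr=float(row["MR"]),
            )

    def rows_for(self, patient_id: str, day: int | None = None) -> pd.DataFrame:
        sel = self.data["patient_id"] == patient_id
        if day is not None:
            sel &= self.data["day"] == day
        return self.data.loc[sel]


def read_cohort(path: str | Path, schema: RMKSchema = DEFAULT_SCHEMA) -> Cohort:
    """Read a cohort CSV (blank cells = missing; no silent numeric coercion).

    A sidecar ``<path>.meta.json`` written by :func:`write_cohort` restores
    the normalization state if present.
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = list(schema.features) + list(SCALE_NAMES) + list(ID_COLUMNS)
    for col in required:
        if col not in raw.columns:
            raise SchemaError(f"required column {col!r} missing from {path}")

    numeric_cols = list(schema.features) + list(SCALE_NAMES)
    data = pd.DataFrame({"patient_id": raw["patient_id"], "site": raw["site"]})
    day = pd.to_numeric(raw["day"], errors="coerce")
    if day.isna().any():
        i = int(day.index[day.isna()][0])
        raise CellParseError(i, "day", raw["day"].iloc[i])
    data["day"] = day.astype(int)
    for col in numeric_cols:
        text = raw[col].str.strip()
        vals = pd.to_numeric(text.replace("", np.nan), errors="coerce")
        bad = vals.isna() & (text != "")
        if bad.any():
            i = int(bad.index[bad][0])
            raise CellParseError(i, col, raw[col].iloc[i])
        data[col] = vals.astype(float)

    _check_scale_ranges(data)

    norm_state = None
    meta_path = path.with_name(path.name + ".meta.json")
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        if meta.get("normalization") is not None:
            norm_state = {k: (float(v[0]), float(v[1])) for k, v in meta["normalization"].items()}
    return Cohort(schema=schema, data=data, norm_state=norm_state)


def _check_scale_ranges(data: pd.DataFrame) -> None:
    for scale, (lo, hi) in SCALE_RANGES.items():
        vals = data[scale].dropna()
        if len(vals) and ((vals < lo) | (vals > hi)).any():
            bad = vals[(vals < lo) | (vals > hi)].iloc[0]
            raise ValueError(f"{scale} score {bad} outside documented range [{lo}, {hi}]")


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write the cohort CSV plus a sidecar with the normalization state.

    Round-trips losslessly through :func:`read_cohort` (values, blanks,
    column order).
    """
    path = Path(path)
    out = cohort.data.loc[:, list(cohort.schema.columns())]
    out.to_csv(path, index=False, na_rep="")
    meta = {
        "normalization": (
            {k: [v[0], v[1]] for k, v in cohort.norm_state.items()}
            if cohort.norm_state is not None
            else None
        )
    }
    path.with_name(path.name + ".meta.json").write_text(json.dumps(meta, indent=1))


def normalize_minmax(cohort: Cohort) -> Cohort:
    """Linearly rescale every RMK feature to [0, 1].

    For feature ``r``, ``x'(r,p,t) = (x - min) / (max - min)`` with the min
    and max taken over all patients and time points.  Missing values stay
    missing.  A constant feature (max == min) is mapped to 0 everywhere and
    a warning is logged: it carries no information but should not crash a
    pipeline.  Clinical scales are left on their native ranges.
    """
    if cohort.is_normalized:
        raise ValueError("cohort is already normalized")
    data = cohort.data.copy()
    state: dict[str, tuple[float, float]] = {}
    for feat in cohort.schema.features:
        col = data[feat]
        if col.notna().sum() == 0:
            raise ValueError(f"feature {feat!r} has no observed values to normalize")
        lo, hi = float(col.min()), float(col.max())
        state[feat] = (lo, hi)
        if hi == lo:
            logger.warning("feature %r is constant (%.6g); normalized to 0", feat, lo)
            warnings.warn(f"feature {feat!r} has zero range; normalized to 0", stacklevel=2)
            data[feat] = col.where(col.isna(), 0.0)
        else:
            data[feat] = (col - lo) / (hi - lo)
    return Cohort(schema=cohort.schema, data=data, norm_state=state)


def denormalize(cohort: Cohort) -> Cohort:
    """Invert :func:`normalize_minmax` using the stored (min, max) pairs."""
    if not cohort.is_normalized:
        raise ValueError("cohort is not normalized")
    data = cohort.data.copy()
    for feat, (lo, hi) in cohort.norm_state.items():
        data[feat] = data[feat] * (hi - lo) + lo
    return Cohort(schema=cohort.schema, data=data, norm_state=None)


class EmptyTableError(ValueError):
    """Filtering left no usable training rows."""


def assemble_training_records(cohort: Cohort, target: str) -> pd.DataFrame:
    """Build the model table for one clinical scale.

    Keeps rows where all RMK features and the target score are present; the
    assessment day is never a predictor.  For the modified Rankin scale only
    day-30 and day-90 records are eligible, because the scale is only
    administered then.  Returns a DataFrame with the 35 feature columns plus
    the target column (and patient_id/day carried for grouping).
    """
    target = target.upper()
    if target not in SCALE_NAMES:
        raise ValueError(f"unknown target scale {target!r}")
    if not cohort.is_normalized:
        raise ValueError("normalize the cohort before assembling training records")
    feats = list(cohort.schema.features)
    data = cohort.data
    if target == "MR":
        data = data[data["day"].isin(MR_DAYS)]
    mask = data[feats].notna().all(axis=1) & data[target].notna()
    table = data.loc[mask, ["patient_id", "day"] + feats + [target]].reset_index(drop=True)
    if len(table) == 0:
        raise EmptyTableError(f"no complete records for target {target}")
    return table


def split_completers(cohort: Cohort) -> tuple[set[str], set[str]]:
    """Partition patients into completers and non-completers.

    A completer has day-7 and day-90 records present with no missing value
    among the RMK features and the clinical scales at both visits.  A
    scale counts as required only on days it is administered: the
    modified Rankin scale exists only at days 30/90, so it is required at
    the day-90 visit but not at day 7.  The partition is exhaustive and
    disjoint over the distinct patients.
    """
    feats = list(cohort.schema.features)
    cols_by_day = {
        day: feats + [s for s in SCALE_NAMES if s != "MR" or day in MR_DAYS]
        for day in (7, 90)
    }
    completers: set[str] = set()
    non_completers: set[str] = set()
    for pid, grp in cohort.data.groupby("patient_id", sort=False):
        ok = True
        for day in (7, 90):
            rows = grp[grp["day"] == day]
            if len(rows) == 0 or not rows.iloc[[0]][cols_by_day[day]].notna().all(axis=1).item():
                ok = False
                break
        (completers if ok else non_completers).add(str(pid))
    return completers, non_completers


def subset_by_patients(cohort: Cohort, patient_ids: set[str]) -> Cohort:
    """Restrict a cohort to the given patients, keeping normalization state."""
    data = cohort.data[cohort.data["patient_id"].isin(patient_ids)].reset_index(drop=True)
    return Cohort(schema=cohort.schema, data=data, norm_state=cohort.norm_state)


def summarize_cohort(cohort: Cohort) -> pd.DataFrame:
    """Descriptive statistics per variable, stratified by completer status.

    Returns count/min/max/mean/sd/median per variable for completers,
    non-completers, and the pooled cohort, over non-missing values.
    """
    completers, _ = split_completers(cohort)
    strata = {
        "completers": cohort.data["patient_id"].isin(completers),
        "non_completers": ~cohort.data["patient_id"].isin(completers),
        "total": pd.Series(True, index=cohort.data.index),
    }
    variables = list(cohort.schema.features) + list(SCALE_NAMES)
    rows = []
    for var in variables:
        for stratum, mask in strata.items():
            vals = cohort.data.loc[mask, var].dropna()
            if len(vals):
                rows.append(
                    dict(variable=var, stratum=stratum, count=len(vals),
                         min=vals.min(), max=vals.max(), mean=vals.mean(),
                         sd=vals.std(ddof=1) if len(vals) > 1 else np.nan,
                         median=vals.median())
                )
            else:
                rows.append(
                    dict(variable=var, stratum=stratum, count=0, min=np.nan,
                         max=np.nan, mean=np.nan, sd=np.nan, median=np.nan)
                )
    return pd.DataFrame(rows)
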