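"""Cohort CSV schema I/O and artifact (de)serialization.

Cohort files are plain CSV, one row per participant, with the columns of
:data:`twostep.cohort.COHORT_COLUMNS`; booleans are written as 0/1 and
missing optional fields are left empty.  Models and thresholds serialize to
JSON, configurations to YAML.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from .cohort import COHORT_COLUMNS, REQUIRED_COLUMNS, ReferenceSample
from .errors import SchemaError
from .risk_model import FittedRiskModel
from .thresholds import ThresholdSet

__all__ = [
    "read_cohort",
    "write_cohort",
    "save_model",
    "load_model",
    "save_thresholds",
    "load_thresholds",
    "load_reference",
    "save_reference",
]

log = logging.getLogger(__name__)

_BOOL_COLUMNS = ("apoe4", "abeta_pet_positive", "csf_positive")


def _coerce_binary(series: pd.Series, name: str, allow_missing: bool) -> pd.Series:
    vals = pd.to_numeric(series, errors="coerce")
    bad_text = vals.isna() & series.notna()
    if bad_text.any():
        example = series[bad_text].iloc[0]
        raise SchemaError(
            f"column {name!r} contains non-numeric value {example!r}; "
            "code binary fields as 0/1 (e.g. APOE e4 carrier status, not genotype text)"
        )
    ok = vals.isin([0, 1]) | vals.isna()
    if not ok.all():
        raise SchemaError(f"column {name!r} must be coded 0/1, found {vals[~ok].iloc[0]!r}")
    if vals.isna().any() and not allow_missing:
        raise SchemaError(f"column {name!r} has missing values but is required")
    return vals


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort CSV; unknown columns are preserved.

    Raises SchemaError listing any missing required columns or mis-coded
    binary fields; logs the row count and per-column missingness.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort file {path} is missing required columns: {missing}")
    for col in _BOOL_COLUMNS:
        if col in df.columns:
            coerced = _coerce_binary(df[col], col, allow_missing=(col == "csf_positive"))
            if coerced.isna().any():
                df[col] = coerced.astype(float)
            else:
                df[col] = coerced.astype(bool)
    df["id"] = df["id"].astype(str)
    n_missing = int(df[[c for c in COHORT_COLUMNS if c in df.columns]].isna().sum().sum())
    log.info("read cohort %s: n = %d rows, %d missing values", path, len(df), n_missing)
    return df


def write_cohort(cohort: pd.DataFrame, path) -> None:
    """Write a cohort CSV in the documented schema (booleans as 0/1)."""
    out = cohort.copy()
    for col in _BOOL_COLUMNS:
        if col in out.columns:
            vals = out[col].astype(float)
            out[col] = vals.astype("Int64") if vals.isna().any() else vals.astype(int)
    cols = [c for c in COHORT_COLUMNS if c in out.columns]
    cols += [c for c in out.columns if c not in cols]
    out[cols].to_csv(path, index=False, float_format="%.10g")


def save_model(model: FittedRiskModel, path) -> None:
    Path(path).write_text(json.dumps(model.to_dict(), indent=2))


def load_model(path) -> FittedRiskModel:
    return FittedRiskModel.from_dict(json.loads(Path(path).read_text()))


def save_thresholds(thresholds: ThresholdSet, path) -> None:
    Path(path).write_text(thresholds.to_json())


def load_thresholds(path) -> ThresholdSet:
    return ThresholdSet.from_json(Path(path).read_text())


def save_reference(reference: ReferenceSample, path) -> None:
    Path(path).write_text(
        yaml.safe_dump(
            {
                "n": reference.n,
                "mean_ptau": reference.mean_ptau,
                "sd_ptau": reference.sd_ptau,
                "assay_label": reference.assay_label,
            }
        )
    )


def load_reference(path) -> ReferenceSample:
    d = yaml.safe_load(Path(path).read_text())
    return ReferenceSample(
        n=int(d["n"]),
        mean_ptau=float(d["mean_ptau"]),
        sd_ptau=float(d["sd_ptau"]),
        assay_label=str(d.get("assay_label", "assay")),
    )
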