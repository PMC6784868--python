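"""Cleaning of individual survey records and stratified summarisation.

Cleaning rules applied to microdata, mirroring the common protocol used for
pooled anthropometric analyses: adults (18+) who are not pregnant; plausible
BMI (10-80 kg m^-2), height (100-250 cm) and weight (12-300 kg); and, in
surveys that recorded place of residence, exclusion of records whose
rural/urban status is unknown.  Surveys without any residence information
are summarised as a single "mixed" stratum representing the
population-weighted sum of rural and urban means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .schema import (
    INPUT_AGE_GROUPS,
    AgeGroup,
    read_observations,
    validate_observations,
    write_observations,
)

__all__ = [
    "IndividualRecord",
    "clean_individual_records",
    "assign_age_group",
    "summarize_stratified",
    "load_summary_file",
    "save_summary_file",
]

RECORD_COLUMNS = ["study_id", "age", "sex", "height", "weight", "pregnant", "stratum", "weight_sample"]

EXCLUSION_REASONS = (
    "missing",
    "pregnant",
    "age",
    "implausible height/weight",
    "implausible BMI",
    "unknown stratum",
)


@dataclass
class IndividualRecord:
    """One measured participant; convenience constructor for record tables."""

    study_id: str
    age: float
    sex: str
    height: float  # cm
    weight: float  # kg
    pregnant: bool = False
    stratum: str = "unknown"  # rural / urban / unknown
    weight_sample: float = 1.0


def records_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records.copy()
    return pd.DataFrame([r.__dict__ for r in records])


def clean_individual_records(records) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the inclusion rules; return (kept, exclusion_log).

    Bounds are inclusive: a 250 cm, 300 kg participant is kept.  Records with
    unknown residence are dropped only in studies where residence was
    recorded for at least one participant.  The log counts exclusions by
    reason; reasons are assessed in a fixed order and each record is counted
    once.
    """
    df = records_frame(records)
    if df.empty:
        return df, pd.DataFrame({"reason": EXCLUSION_REASONS, "count": 0})
    df = df.reset_index(drop=True)
    bmi = df["weight"] / (df["height"] / 100.0) ** 2

    reason = pd.Series(pd.NA, index=df.index, dtype="object")
    missing = df["height"].isna() | df["weight"].isna() | df["age"].isna()
    reason[missing] = "missing"
    m = reason.isna() & df["pregnant"].fillna(False).astype(bool)
    reason[m] = "pregnant"
    m = reason.isna() & (df["age"] < 18)
    reason[m] = "age"
    m = reason.isna() & (
        (df["height"] < 100) | (df["height"] > 250) | (df["weight"] < 12) | (df["weight"] > 300)
    )
    reason[m] = "implausible height/weight"
    m = reason.isna() & ((bmi < 10) | (bmi > 80))
    reason[m] = "implausible BMI"

    records_residence = df.groupby("study_id")["stratum"].transform(
        lambda s: s.isin(["rural", "urban"]).any()
    )
    m = reason.isna() & records_residence & ~df["stratum"].isin(["rural", "urban"])
    reason[m] = "unknown stratum"

    kept = df[reason.isna()].copy()
    kept["bmi"] = bmi[reason.isna()]
    counts = reason.dropna().value_counts()
    log = pd.DataFrame(
        {"reason": EXCLUSION_REASONS,
         "count": [int(counts.get(r, 0)) for r in EXCLUSION_REASONS]}
    )
    return kept, log


def assign_age_group(age: float) -> AgeGroup:
    """Map an adult age in years to the canonical input age group."""
    if age < 18:
        raise ValueError(f"age {age} is below 18")
    age = math.floor(age)
    for lo, hi in INPUT_AGE_GROUPS:
        if lo <= age <= hi:
            return (lo, hi)
    raise AssertionError("unreachable: canonical grid covers all ages >= 18")


def _weighted_summary(x: np.ndarray, w: np.ndarray, deff: float) -> tuple[float, float, float]:
    sw = w.sum()
    mean = float((w * x).sum() / sw)
    n_eff = float(sw**2 / (w**2).sum())
    if len(x) > 1:
        var = float((w * (x - mean) ** 2).sum() / sw) * len(x) / (len(x) - 1)
    else:
        var = np.nan
    se = math.sqrt(var / n_eff) * math.sqrt(deff) if np.isfinite(var) else np.nan
    return mean, se, n_eff


def summarize_stratified(
    kept: pd.DataFrame,
    *,
    study_meta: dict | None = None,
    design_effect: float = 1.0,
) -> pd.DataFrame:
    """Weighted summary rows per sex x age group x stratum.

    ``study_meta`` maps study_id -> dict with country/region/super_region/
    mid_year/coverage; missing entries default to blanks.  Studies whose
    records carry no residence information contribute "mixed" rows.  Cells
    with a single record get a pooled-variance SE and ``sparse_cell=True``.
    """
    if kept.empty:
        return pd.DataFrame(columns=[
            "study_id", "country", "region", "super_region", "mid_year", "sex",
            "age_lo", "age_hi", "stratum", "coverage", "mean_bmi", "se", "n_eff",
            "sparse_cell",
        ])
    df = kept.copy()
    if "bmi" not in df.columns:
        df["bmi"] = df["weight"] / (df["height"] / 100.0) ** 2
    if "weight_sample" not in df.columns:
        df["weight_sample"] = 1.0
    df["weight_sample"] = df["weight_sample"].fillna(1.0)
    df["age_lo"], df["age_hi"] = zip(*df["age"].map(assign_age_group))
    has_res = df.groupby("study_id")["stratum"].transform(
        lambda s: s.isin(["rural", "urban"]).any()
    )
    df["stratum_out"] = np.where(has_res, df["stratum"], "mixed")

    meta = study_meta or {}
    rows = []
    for (study, sex, lo, hi, stratum), cell in df.groupby(
        ["study_id", "sex", "age_lo", "age_hi", "stratum_out"], sort=True
    ):
        mean, se, n_eff = _weighted_summary(
            cell["bmi"].to_numpy(float), cell["weight_sample"].to_numpy(float), design_effect
        )
        m = meta.get(study, {})
        rows.append(
            (study, m.get("country", ""), m.get("region", ""), m.get("super_region", ""),
             m.get("mid_year", 0), sex, lo, hi, stratum, m.get("coverage", "national"),
             mean, se, n_eff, len(cell) < 2)
        )
    out = pd.DataFrame(rows, columns=[
        "study_id", "country", "region", "super_region", "mid_year", "sex",
        "age_lo", "age_hi", "stratum", "coverage", "mean_bmi", "se", "n_eff",
        "sparse_cell",
    ])
    # pooled-variance fallback for single-record cells: borrow the median
    # within-cell SD of the same study and sex, else of the whole table
    if out["se"].isna().any():
        df["_dev2"] = np.nan
        pooled_sd = (
            df.groupby(["study_id", "sex"])["bmi"].std().groupby("sex").median()
        )
        overall = df["bmi"].std()
        for i in out.index[out["se"].isna()]:
            sd = pooled_sd.get(out.loc[i, "sex"], np.nan)
            if not np.isfinite(sd):
                sd = overall if np.isfinite(overall) else 1.0
            out.loc[i, "se"] = sd * math.sqrt(design_effect)
    return out


def load_summary_file(path, *, require_mean: bool = True) -> pd.DataFrame:
    """Read and schema-validate an observation CSV."""
    return read_observations(path, require_mean=require_mean)


def save_summary_file(df: pd.DataFrame, path) -> None:
    write_observations(validate_observations(df), path)
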