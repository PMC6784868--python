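"""Shared schemas: age-group grids, country hierarchy, and the observation table.

The whole package moves survey summaries around as a pandas DataFrame with one
row per study x sex x age-group x stratum cell.  This module owns the column
contract and its validation, plus the two age grids:

* the *input* grid used when summarising surveys — single years 18 and 19,
  then 10-year groups 20-29 ... 70-79 and an open-ended 80+ group;
* the *estimation* grid on which the model produces estimates — single years
  18 and 19, then 5-year groups from 20-24 upward, with everyone aged 80 and
  over carried in the top group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "INPUT_AGE_GROUPS",
    "ESTIMATION_AGE_GROUPS",
    "STRATA",
    "COVERAGE_LEVELS",
    "OBS_COLUMNS",
    "AgeGroup",
    "Hierarchy",
    "age_group_midpoint",
    "validate_observations",
    "write_observations",
    "read_observations",
]

#: (low, high) in whole years, both inclusive; ``inf`` marks an open top group.
AgeGroup = tuple[float, float]

INPUT_AGE_GROUPS: list[AgeGroup] = [
    (18, 18),
    (19, 19),
    (20, 29),
    (30, 39),
    (40, 49),
    (50, 59),
    (60, 69),
    (70, 79),
    (80, math.inf),
]

ESTIMATION_AGE_GROUPS: list[AgeGroup] = [(18, 18), (19, 19)] + [
    (lo, lo + 4) for lo in range(20, 80, 5)
] + [(80, 84)]

STRATA = ("rural", "urban", "mixed")
COVERAGE_LEVELS = ("national", "subnational", "community")

#: Canonical observation-table columns, in serialisation order.
OBS_COLUMNS = [
    "study_id",
    "country",
    "region",
    "super_region",
    "mid_year",
    "sex",
    "age_lo",
    "age_hi",
    "stratum",
    "coverage",
    "mean_bmi",
    "se",
    "n_eff",
]


def age_group_midpoint(group: AgeGroup, top_age: float = 85.0) -> float:
    """Midpoint in years of an inclusive integer age interval.

    ``[20, 29]`` covers ages 20.0-30.0, so its midpoint is 25.0.  Open-ended
    top groups are truncated at ``top_age``.
    """
    lo, hi = group
    hi = min(hi + 1, top_age)
    return (lo + hi) / 2.0


def years_in_group(group: AgeGroup, top_age: float = 85.0) -> float:
    lo, hi = group
    return min(hi + 1, top_age) - lo


@dataclass(frozen=True)
class Hierarchy:
    """Country -> region -> super-region nesting used for shrinkage."""

    country_region: dict[str, str]
    region_super: dict[str, str]

    countries: tuple[str, ...] = field(init=False)
    regions: tuple[str, ...] = field(init=False)
    super_regions: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        missing = set(self.country_region.values()) - set(self.region_super)
        if missing:
            raise ValueError(f"regions without a super-region: {sorted(missing)}")
        object.__setattr__(self, "countries", tuple(sorted(self.country_region)))
        object.__setattr__(self, "regions", tuple(sorted(self.region_super)))
        object.__setattr__(
            self, "super_regions", tuple(sorted(set(self.region_super.values())))
        )

    def super_of_country(self, country: str) -> str:
        return self.region_super[self.country_region[country]]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (c, r, self.region_super[r]) for c, r in sorted(self.country_region.items())
        ]
        return pd.DataFrame(rows, columns=["country", "region", "super_region"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Hierarchy":
        cr = dict(zip(df["country"], df["region"]))
        rs = dict(zip(df["region"], df["super_region"]))
        return cls(country_region=cr, region_super=rs)


class ObservationValidationError(ValueError):
    """Raised when an observation table violates the schema contract."""


def validate_observations(df: pd.DataFrame, *, require_mean: bool = True) -> pd.DataFrame:
    """Check an observation table against the schema; return it unchanged.

    Raises :class:`ObservationValidationError` listing offending row indices.
    """
    problems: list[str] = []
    missing = [c for c in OBS_COLUMNS if c not in df.columns and not (
        c in ("mean_bmi", "se") and not require_mean)]
    if missing:
        raise ObservationValidationError(f"missing columns: {missing}")
    bad = df.index[~df["stratum"].isin(STRATA)]
    if len(bad):
        problems.append(f"unknown stratum labels at rows {list(bad[:10])}")
    bad = df.index[~df["coverage"].isin(COVERAGE_LEVELS)]
    if len(bad):
        problems.append(f"unknown coverage labels at rows {list(bad[:10])}")
    if require_mean:
        bad = df.index[~((df["mean_bmi"] > 10) & (df["mean_bmi"] < 80))]
        if len(bad):
            problems.append(f"mean_bmi outside (10, 80) at rows {list(bad[:10])}")
        bad = df.index[~(df["se"] > 0)]
        if len(bad):
            problems.append(f"non-positive se at rows {list(bad[:10])}")
    bad = df.index[~(df["n_eff"] >= 1)]
    if len(bad):
        problems.append(f"n_eff < 1 at rows {list(bad[:10])}")
    bad = df.index[~(df["age_hi"] >= df["age_lo"])]
    if len(bad):
        problems.append(f"age_hi < age_lo at rows {list(bad[:10])}")
    if problems:
        raise ObservationValidationError("; ".join(problems))
    return df


def write_observations(df: pd.DataFrame, path) -> None:
    cols = [c for c in OBS_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    df.to_csv(path, index=False, columns=cols)


def read_observations(path, *, require_mean: bool = True) -> pd.DataFrame:
    df = pd.read_csv(path)
    return validate_observations(df, require_mean=require_mean)


def spanned_estimation_groups(
    group: AgeGroup, grid: list[AgeGroup] | None = None
) -> list[tuple[int, float]]:
    """Indices of estimation-grid groups overlapped by an input age group.

    Returns ``(index, overlap_years)`` pairs; an open-ended input group picks
    up the open top of the grid.
    """
    grid = ESTIMATION_AGE_GROUPS if grid is None else grid
    lo, hi = group
    out = []
    for i, (glo, ghi) in enumerate(grid):
        top_in = hi + 1 if math.isfinite(hi) else math.inf
        top_g = ghi + 1
        if i == len(grid) - 1 and not math.isfinite(hi):
            top_g = math.inf
        overlap = min(top_in, top_g) - max(lo, glo)
        if overlap > 0:
            out.append((i, min(overlap, years_in_group((glo, ghi)))))
    if not out:
        raise ValueError(f"age group {group} does not overlap the estimation grid")
    return out
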