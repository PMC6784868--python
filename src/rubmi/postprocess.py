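"""From posterior draws to reported quantities.

Age-standardised means (WHO standard population weights), population-
weighted national/regional/global aggregates, 95% credible intervals
(empirical 2.5th/97.5th percentiles, linear interpolation) and posterior
direction probabilities.  Every function here is a deterministic function
of the draws — no fresh randomness enters after sampling.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from .schema import Hierarchy
from .synthetic_world import PopulationTable

__all__ = [
    "AgeStandard",
    "EstimateSummary",
    "load_who_standard",
    "age_standardize",
    "aggregate_weighted",
    "credible_interval",
    "direction_probability",
    "summarize",
    "estimates_table",
]


@dataclass(frozen=True)
class AgeStandard:
    """Normalised age weights keyed by the lower bound of each age group."""

    weights: dict[int, float]

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("age weights must be non-negative")
        total = sum(self.weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"age weights must sum to 1 (got {total!r})")

    @classmethod
    def from_shares(cls, shares: dict[int, float]) -> "AgeStandard":
        total = sum(shares.values())
        return cls({k: v / total for k, v in shares.items()})

    def vector(self, ages) -> np.ndarray:
        missing = [a for a in ages if int(a) not in self.weights]
        if missing:
            raise ValueError(f"age standard missing groups {missing}")
        w = np.array([self.weights[int(a)] for a in ages])
        return w / w.sum()


def load_who_standard() -> AgeStandard:
    """WHO world standard population weights over the adult estimation grid."""
    ref = importlib.resources.files("rubmi.data").joinpath("who_standard.csv")
    with ref.open() as fh:
        df = pd.read_csv(fh, comment="#")
    return AgeStandard.from_shares(dict(zip(df["age_lo"].astype(int), df["share"])))


def age_standardize(draws: xr.DataArray, standard: AgeStandard) -> xr.DataArray:
    """Weighted mean over the age dimension with standard-population weights."""
    w = standard.vector(draws["age"].values)
    wda = xr.DataArray(w, dims=("age",), coords={"age": draws["age"]})
    return (draws * wda).sum("age")


def aggregate_weighted(
    draws: xr.DataArray,
    pop: PopulationTable,
    level: str,
    hierarchy: Hierarchy | None = None,
    standard: AgeStandard | None = None,
) -> xr.DataArray:
    """Population-weighted aggregation of stratum draws.

    ``level='national'`` combines rural and urban by the year-specific urban
    share, keeping the country dimension; ``'regional'``/``'global'``
    additionally average countries with population weights (regional needs
    ``hierarchy``).  Aggregation runs on the age-specific draws; pass
    ``standard`` to age-standardise the result.
    """
    sex = draws.attrs.get("sex")
    share = pop.share_urban
    popn = pop.population
    if "sex" in share.dims:
        if sex is None:
            raise ValueError("draws must carry a 'sex' attr to index the population table")
        share = share.sel(sex=sex)
        popn = popn.sel(sex=sex)
    share = share.sel(country=draws["country"], year=draws["year"], age=draws["age"])
    popn = popn.sel(country=draws["country"], year=draws["year"], age=draws["age"])

    national = (
        draws.sel(stratum="urban") * share + draws.sel(stratum="rural") * (1.0 - share)
    )
    if level == "national":
        out = national
    elif level == "global":
        wpop = popn / popn.sum("country")
        out = (national * wpop).sum("country")
    elif level == "regional":
        if hierarchy is None:
            raise ValueError("regional aggregation needs the hierarchy")
        missing = [c for c in draws["country"].values if c not in hierarchy.countries]
        if missing:
            raise ValueError(f"population/hierarchy missing members: {missing}")
        region = xr.DataArray(
            [hierarchy.country_region[c] for c in draws["country"].values],
            dims=("country",), coords={"country": draws["country"]},
        )
        wsum = popn.groupby(region.rename("region")).sum()
        out = (
            (national * popn).groupby(region.rename("region")).sum()
            / wsum
        )
    else:
        raise ValueError(f"unknown aggregation level {level!r}")
    if standard is not None:
        out = age_standardize(out, standard)
    out.attrs.update(draws.attrs)
    return out


def credible_interval(values: np.ndarray, axis: int = -1) -> tuple[np.ndarray, np.ndarray]:
    """Empirical 95% credible bounds (2.5th/97.5th, linear interpolation)."""
    values = np.asarray(values)
    n = values.shape[axis]
    if n < 2:
        raise ValueError("need at least 2 draws for a credible interval")
    if n < 40:
        warnings.warn(f"only {n} draws: 2.5%/97.5% percentiles are poorly resolved")
    lo = np.percentile(values, 2.5, axis=axis)
    hi = np.percentile(values, 97.5, axis=axis)
    return lo, hi


def direction_probability(values: np.ndarray) -> float:
    """Posterior probability that the quantity shares the sign of its mean."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 draws")
    m = values.mean()
    if m == 0.0:
        warnings.warn("posterior mean exactly zero; direction undefined")
        return 0.5
    sign = np.sign(m)
    return float(np.mean(np.sign(values) == sign) + 0.5 * np.mean(values == 0.0))


@dataclass(frozen=True)
class EstimateSummary:
    """Posterior mean, 95% credible bounds and direction probability."""

    mean: float
    l95: float
    u95: float
    prob_direction: float

    def __post_init__(self) -> None:
        if not (self.l95 <= self.mean <= self.u95):
            raise ValueError("credible bounds must bracket the posterior mean")


def summarize(values: np.ndarray) -> EstimateSummary:
    values = np.asarray(values, dtype=float)
    lo, hi = credible_interval(values)
    return EstimateSummary(
        mean=float(values.mean()), l95=float(lo), u95=float(hi),
        prob_direction=direction_probability(values),
    )


def estimates_table(draws_by_stratum: xr.DataArray) -> pd.DataFrame:
    """Flatten draw arrays to a (unit, year[, stratum]) summary CSV shape."""
    dims = [d for d in draws_by_stratum.dims if d != "draw"]
    mean = draws_by_stratum.mean("draw")
    lo = draws_by_stratum.quantile(0.025, "draw", method="linear")
    hi = draws_by_stratum.quantile(0.975, "draw", method="linear")
    df = mean.to_dataframe(name="mean").reset_index()
    df["l95"] = lo.to_dataframe(name="l").reset_index()["l"]
    df["u95"] = hi.to_dataframe(name="u").reset_index()["u"]
    return df[[*dims, "mean", "l95", "u95"]]
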