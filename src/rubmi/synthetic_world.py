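"""Synthetic world generator: ground-truth BMI surfaces and survey-like data.

The generator draws a world with the statistical structure the trend model
assumes — hierarchical country intercepts and slopes, a second-order random
walk (RW2) deviation per country, a nonlinear age pattern with country-level
spline perturbations, and a country- and year-varying urban-rural BMI gap —
then samples heterogeneous survey summaries from it: national, subnational
and community sources with systematic offsets and extra study-level noise,
a fraction of surveys not stratified by place of residence, and a small
fraction reporting only BMI-category prevalences.

Every downstream module (crosswalk, trend model, postprocessing,
decomposition, validation) is tested against worlds from this module, so
parameter-recovery and coverage claims refer to data generated here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import xarray as xr
from scipy.stats import norm

from .schema import (
    ESTIMATION_AGE_GROUPS,
    INPUT_AGE_GROUPS,
    AgeGroup,
    Hierarchy,
    age_group_midpoint,
    spanned_estimation_groups,
    validate_observations,
    years_in_group,
)
from .splines import bspline_basis

__all__ = [
    "WorldConfig",
    "TruthSurface",
    "PopulationTable",
    "SyntheticWorld",
    "generate_truth",
    "generate_population_table",
    "sample_observations",
    "make_prevalence_only_subset",
    "generate_world",
]

PREVALENCE_METRICS = ("ge25", "ge30", "lt185")
_METRIC_THRESHOLDS = {"ge25": 25.0, "ge30": 30.0, "lt185": 18.5}


class WorldConfigError(ValueError):
    """A WorldConfig field violates its contract."""


@dataclass
class WorldConfig:
    """Parameters of the synthetic world.

    SDs are in kg m^-2 (per year where noted).  Defaults give a world of
    3 super-regions x 2 regions x 4 countries over 1985-2017 with roughly
    eight surveys per country, BMI levels around 22-28, urban-rural gaps of
    order 1 kg m^-2 that narrow slowly, and survey noise typical of
    population surveys with a few hundred subjects per cell.
    """

    n_super_regions: int = 3
    regions_per_super: int = 2
    countries_per_region: int = 4
    year_start: int = 1985
    year_end: int = 2017
    sexes: tuple[str, ...] = ("female", "male")
    age_groups: list[AgeGroup] = field(default_factory=lambda: list(INPUT_AGE_GROUPS))
    estimation_age_groups: list[AgeGroup] = field(
        default_factory=lambda: list(ESTIMATION_AGE_GROUPS)
    )
    # level of the rural surface
    base_mean: float = 24.0
    base_trend: float = 0.05  # kg m^-2 per year, global
    sex_offset: dict[str, float] = field(
        default_factory=lambda: {"female": 0.3, "male": -0.3}
    )
    trend_sd_hierarchy: tuple[float, float, float] = (1.2, 0.8, 0.6)
    slope_sd_hierarchy: tuple[float, float, float] = (0.015, 0.010, 0.008)
    rw2_innovation_sd: float = 0.03
    # age pattern
    age_dev_sd: float = 0.3  # country perturbation on spline coefficients
    # urban-rural gap
    urban_gap_base_mean: float = 1.2
    urban_gap_base_sd: float = 0.6
    urban_gap_trend_mean: float = -0.015  # per year; gaps narrow on average
    urban_gap_trend_sd: float = 0.012
    # survey heterogeneity
    coverage_offsets: dict[str, float] = field(
        default_factory=lambda: {"national": 0.0, "subnational": 0.2, "community": 0.35}
    )
    coverage_extra_sd: dict[str, float] = field(
        default_factory=lambda: {"national": 0.15, "subnational": 0.3, "community": 0.45}
    )
    coverage_probs: tuple[float, float, float] = (0.6, 0.25, 0.15)
    within_sd: dict[str, float] = field(
        default_factory=lambda: {"female": 4.0, "male": 3.5}
    )
    frac_unstratified: float = 0.25
    frac_prevalence_only: float = 0.02
    surveys_per_country: float = 8.0
    halve_pre2000_rate: bool = True
    obs_n_range: tuple[int, int] = (100, 600)
    seed: int = 0

    def validate(self) -> "WorldConfig":
        for name in (
            "rw2_innovation_sd",
            "urban_gap_base_sd",
            "urban_gap_trend_sd",
            "age_dev_sd",
            "surveys_per_country",
        ):
            if getattr(self, name) < 0:
                raise WorldConfigError(f"{name} must be >= 0")
        for name in ("trend_sd_hierarchy", "slope_sd_hierarchy"):
            if any(v < 0 for v in getattr(self, name)):
                raise WorldConfigError(f"{name} entries must be >= 0")
        for name in ("frac_unstratified", "frac_prevalence_only"):
            if not 0 <= getattr(self, name) <= 1:
                raise WorldConfigError(f"{name} must be in [0, 1]")
        if self.year_end < self.year_start:
            raise WorldConfigError("year_range is empty")
        prev_hi = None
        for lo, hi in self.age_groups:
            if lo < 18:
                raise WorldConfigError("age groups must start at 18 or later")
            if hi < lo:
                raise WorldConfigError(f"age group ({lo}, {hi}) is descending")
            if prev_hi is not None and lo <= prev_hi:
                raise WorldConfigError("age groups overlap or are unordered")
            prev_hi = hi
        if any(sx not in self.within_sd for sx in self.sexes):
            raise WorldConfigError("within_sd must cover every sex")
        return self

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.year_start, self.year_end + 1)

    @property
    def ref_year(self) -> float:
        return (self.year_start + self.year_end) / 2.0

    def hierarchy(self) -> Hierarchy:
        cr, rs = {}, {}
        for s in range(self.n_super_regions):
            sr = f"SR{s}"
            for r in range(self.regions_per_super):
                reg = f"{sr}R{r}"
                rs[reg] = sr
                for c in range(self.countries_per_region):
                    cr[f"{reg}C{c}"] = reg
        return Hierarchy(country_region=cr, region_super=rs)


def _rng(config: WorldConfig, *tags: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((config.seed, 977, *tags)))


# purpose codes for per-(country, purpose) stream splitting
_P_TRUTH, _P_POP, _P_SURVEY, _P_PREV = 1, 2, 3, 4


@dataclass
class TruthSurface:
    """Ground-truth mean BMI surfaces on the estimation age grid."""

    rural: xr.DataArray  # (country, year, sex, age)
    gap: xr.DataArray  # (country, year, sex); urban minus rural
    hierarchy: Hierarchy
    age_groups: list[AgeGroup]

    @property
    def urban(self) -> xr.DataArray:
        return self.rural + self.gap

    def stratum(self, name: str) -> xr.DataArray:
        if name == "rural":
            return self.rural
        if name == "urban":
            return self.urban
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for name in ("rural", "urban"):
            df = self.stratum(name).to_dataframe(name="mean_bmi").reset_index()
            df["stratum"] = name
            frames.append(df)
        out = pd.concat(frames, ignore_index=True)
        out["age_lo"] = out["age"]
        lookup = {lo: hi for lo, hi in self.age_groups}
        out["age_hi"] = out["age"].map(lookup)
        return out[["country", "year", "sex", "age_lo", "age_hi", "stratum", "mean_bmi"]]


@dataclass
class PopulationTable:
    """Population counts and urban shares on the estimation age grid."""

    population: xr.DataArray  # (country, year, sex, age)
    share_urban: xr.DataArray  # (country, year, sex, age)

    def share(self, country: str, year: int, sex: str) -> float:
        """Population-weighted urban share across ages for one cell."""
        p = self.population.sel(country=country, year=year, sex=sex).values
        s = self.share_urban.sel(country=country, year=year, sex=sex).values
        return float((p * s).sum() / p.sum())

    def to_frame(self) -> pd.DataFrame:
        ds = xr.Dataset({"population": self.population, "share_urban": self.share_urban})
        return ds.to_dataframe().reset_index()

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PopulationTable":
        ds = df.set_index(["country", "year", "sex", "age"]).to_xarray()
        return cls(population=ds["population"], share_urban=ds["share_urban"])


@dataclass
class SyntheticWorld:
    config: WorldConfig
    truth: TruthSurface
    population: PopulationTable
    observations: pd.DataFrame


def _age_curve(ages: np.ndarray) -> np.ndarray:
    """Fixed global age pattern: rise through mid-life, mild decline after."""
    x = ages - 18.0
    return 0.12 * x - 0.0013 * x**2


def _hier_draws(rng, mean, sds, n_super, n_regions, n_countries, region_of, super_of):
    """Country values as global mean plus super/region/country deviations."""
    dev_s = rng.normal(0.0, 1.0, n_super) * sds[0]
    dev_r = rng.normal(0.0, 1.0, n_regions) * sds[1]
    dev_c = rng.normal(0.0, 1.0, n_countries) * sds[2]
    return mean + dev_s[super_of[region_of]] + dev_r[region_of] + dev_c


def generate_truth(config: WorldConfig) -> TruthSurface:
    """Draw ground-truth rural surfaces and urban-rural gaps.

    Deterministic given ``config.seed``; per-country random streams are keyed
    by country index so enlarging the world leaves existing countries alone.
    """
    config.validate()
    hier = config.hierarchy()
    countries = list(hier.countries)
    regions = list(hier.regions)
    supers = list(hier.super_regions)
    region_of = np.array([regions.index(hier.country_region[c]) for c in countries])
    super_of = np.array([supers.index(hier.region_super[r]) for r in regions])

    years = config.years
    t = years - config.ref_year
    ages = np.array([age_group_midpoint(g) for g in config.estimation_age_groups])
    B = bspline_basis(ages)
    f_age = _age_curve(ages)

    n_c, n_t, n_a = len(countries), len(years), len(ages)
    rural = np.empty((n_c, n_t, len(config.sexes), n_a))
    gap = np.empty((n_c, n_t, len(config.sexes)))
    g3 = 1.0 / math.sqrt(3.0)

    for si, sex in enumerate(config.sexes):
        rng = _rng(config, _P_TRUTH, si)
        a_c = _hier_draws(
            rng,
            config.base_mean + config.sex_offset.get(sex, 0.0),
            config.trend_sd_hierarchy,
            len(supers), len(regions), n_c, region_of, super_of,
        )
        b_c = _hier_draws(
            rng, config.base_trend, config.slope_sd_hierarchy,
            len(supers), len(regions), n_c, region_of, super_of,
        )
        d0 = _hier_draws(
            rng, config.urban_gap_base_mean,
            tuple(config.urban_gap_base_sd * g3 for _ in range(3)),
            len(supers), len(regions), n_c, region_of, super_of,
        )
        d1 = _hier_draws(
            rng, config.urban_gap_trend_mean,
            tuple(config.urban_gap_trend_sd * g3 for _ in range(3)),
            len(supers), len(regions), n_c, region_of, super_of,
        )
        for ci in range(n_c):
            crng = _rng(config, _P_TRUTH, si, ci)
            innov = crng.normal(0.0, 1.0, n_t) * config.rw2_innovation_sd
            u = np.cumsum(np.cumsum(innov))
            # project out constant and linear trend: those belong to (a_c, b_c)
            Xl = np.column_stack([np.ones(n_t), t])
            u = u - Xl @ np.linalg.lstsq(Xl, u, rcond=None)[0]
            d_spl = crng.normal(0.0, 1.0, B.shape[1]) * config.age_dev_sd
            rural[ci, :, si, :] = (
                a_c[ci] + b_c[ci] * t[:, None] + u[:, None] + (f_age + B @ d_spl)[None, :]
            )
            gap[ci, :, si] = d0[ci] + d1[ci] * t

    coords = {
        "country": countries,
        "year": years,
        "sex": list(config.sexes),
        "age": [int(g[0]) for g in config.estimation_age_groups],
    }
    rural_da = xr.DataArray(rural, dims=("country", "year", "sex", "age"), coords=coords)
    gap_da = xr.DataArray(
        gap, dims=("country", "year", "sex"),
        coords={k: coords[k] for k in ("country", "year", "sex")},
    )
    if not (float(rural_da.min()) > 10 and float((rural_da + gap_da).max()) < 80):
        raise WorldConfigError("generated surfaces leave the plausible BMI range (10, 80)")
    return TruthSurface(
        rural=rural_da, gap=gap_da, hierarchy=hier,
        age_groups=list(config.estimation_age_groups),
    )


def generate_population_table(config: WorldConfig) -> PopulationTable:
    """Logistic urbanisation curves plus a static age pyramid per country."""
    config.validate()
    hier = config.hierarchy()
    countries = list(hier.countries)
    years = config.years
    ages = np.array([age_group_midpoint(g) for g in config.estimation_age_groups])
    widths = np.array([years_in_group(g) for g in config.estimation_age_groups])
    age_shape = np.exp(-0.025 * (ages - 18.0)) * widths

    n_c, n_t, n_s, n_a = len(countries), len(years), len(config.sexes), len(ages)
    pop = np.empty((n_c, n_t, n_s, n_a))
    share = np.empty((n_c, n_t, n_s, n_a))
    for ci in range(n_c):
        crng = _rng(config, _P_POP, ci)
        base = float(crng.lognormal(math.log(3e6), 0.8))
        slope = crng.uniform(0.02, 0.09)
        mid = crng.uniform(1975.0, 2035.0)
        s_t = 1.0 / (1.0 + np.exp(-slope * (years - mid)))
        pop[ci] = base * (age_shape / age_shape.sum())[None, None, :] / n_s
        share[ci] = s_t[:, None, None]
    coords = {
        "country": countries,
        "year": years,
        "sex": list(config.sexes),
        "age": [int(g[0]) for g in config.estimation_age_groups],
    }
    dims = ("country", "year", "sex", "age")
    return PopulationTable(
        population=xr.DataArray(pop, dims=dims, coords=coords),
        share_urban=xr.DataArray(share, dims=dims, coords=coords),
    )


def _truth_cell_mean(
    truth: TruthSurface,
    pop: PopulationTable,
    country: str,
    year: int,
    sex: str,
    group: AgeGroup,
    stratum: str,
    grid: list[AgeGroup],
) -> float:
    """Population-weighted truth over the estimation ages an input group spans."""
    spans = spanned_estimation_groups(group, grid)
    idx = [i for i, _ in spans]
    frac = np.array([w / years_in_group(grid[i]) for i, w in spans])
    p = pop.population.sel(country=country, year=year, sex=sex).values[idx] * frac
    s = pop.share_urban.sel(country=country, year=year, sex=sex).values[idx]
    rural = truth.rural.sel(country=country, year=year, sex=sex).values[idx]
    urban = rural + float(truth.gap.sel(country=country, year=year, sex=sex))
    if stratum == "rural":
        w = p * (1.0 - s)
    elif stratum == "urban":
        w = p * s
    elif stratum == "mixed":
        w = p
    else:
        raise KeyError(stratum)
    vals = {"rural": rural, "urban": urban}.get(stratum)
    if vals is None:  # mixed
        vals = (1.0 - s) * rural + s * urban
    if w.sum() <= 0:
        w = np.ones_like(w)
    return float((w * vals).sum() / w.sum())


def sample_observations(
    truth: TruthSurface, pop: PopulationTable, config: WorldConfig
) -> pd.DataFrame:
    """Sample survey summary rows from the truth surfaces.

    Each survey lands at a random country-year, gets a coverage level, a
    study-level effect with coverage-specific SD, and — unless it skipped
    residence recording — reports rural and urban strata separately;
    otherwise a single "mixed" row per cell, the population-weighted mean.
    """
    config.validate()
    if truth.rural.size == 0:
        raise ValueError("empty truth surface")
    hier = truth.hierarchy
    years = config.years
    year_w = np.ones(len(years))
    if config.halve_pre2000_rate:
        year_w[years < 2000] = 0.5
    year_w = year_w / year_w.sum()

    rows = []
    for ci, country in enumerate(hier.countries):
        region = hier.country_region[country]
        super_region = hier.region_super[region]
        crng = _rng(config, _P_SURVEY, ci)
        n_surveys = int(crng.poisson(config.surveys_per_country))
        for si in range(n_surveys):
            year = int(crng.choice(years, p=year_w))
            coverage = str(
                crng.choice(("national", "subnational", "community"), p=config.coverage_probs)
            )
            stratified = crng.random() >= config.frac_unstratified
            study_id = f"{country}_s{si:02d}"
            strata = ("rural", "urban") if stratified else ("mixed",)
            for sex in config.sexes:
                eff = crng.normal(0.0, config.coverage_extra_sd[coverage])
                sd_w = config.within_sd[sex]
                for group in config.age_groups:
                    for stratum in strata:
                        mu = _truth_cell_mean(
                            truth, pop, country, year, sex, group, stratum,
                            config.estimation_age_groups,
                        )
                        n = int(crng.integers(*config.obs_n_range))
                        se = sd_w / math.sqrt(n)
                        obs = mu + config.coverage_offsets[coverage] + eff + crng.normal(0.0, se)
                        rows.append(
                            (study_id, country, region, super_region, year, sex,
                             group[0], group[1], stratum, coverage, obs, se, n, sd_w)
                        )
    df = pd.DataFrame(
        rows,
        columns=["study_id", "country", "region", "super_region", "mid_year", "sex",
                 "age_lo", "age_hi", "stratum", "coverage", "mean_bmi", "se",
                 "n_eff", "within_sd"],
    )
    return validate_observations(df)


def make_prevalence_only_subset(
    observations: pd.DataFrame, config: WorldConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Strip a random fraction of rows down to BMI-category prevalences.

    Selected rows lose mean/SE and instead report a subset of
    p(BMI >= 25), p(BMI >= 30) and p(BMI < 18.5) with binomial SEs, computed
    from the within-cell normal BMI distribution.  The stripped mean is kept
    in ``mean_bmi_true`` so recovery can be scored.  Deterministic given the
    config seed.
    """
    frac = config.frac_prevalence_only
    if not 0 <= frac <= 1:
        raise WorldConfigError("frac_prevalence_only must be in [0, 1]")
    rng = _rng(config, _P_PREV)
    take = rng.random(len(observations)) < frac
    keep = observations.loc[~take].reset_index(drop=True)
    sel = observations.loc[take].reset_index(drop=True)
    if sel.empty:
        return keep, sel

    subset_choices = [PREVALENCE_METRICS, ("ge30",), ("ge25", "ge30")]
    chosen = rng.choice(len(subset_choices), size=len(sel), p=[0.5, 0.3, 0.2])
    out = sel.copy()
    out["mean_bmi_true"] = out["mean_bmi"]
    for m in PREVALENCE_METRICS:
        out[f"prev_{m}"] = np.nan
        out[f"prev_{m}_se"] = np.nan
    for i, row in sel.iterrows():
        sd = row["within_sd"]
        n = row["n_eff"]
        for m in subset_choices[chosen[i]]:
            thr = _METRIC_THRESHOLDS[m]
            z = (row["mean_bmi"] - thr) / sd
            p = norm.cdf(z) if m != "lt185" else norm.cdf(-z)
            out.loc[i, f"prev_{m}"] = p
            out.loc[i, f"prev_{m}_se"] = max(math.sqrt(p * (1 - p) / n), 1e-9)
    out = out.drop(columns=["mean_bmi", "se"])
    return keep, out


def generate_world(config: WorldConfig | None = None, **overrides) -> SyntheticWorld:
    """Convenience end-to-end generation with optional field overrides."""
    config = replace(config or WorldConfig(), **overrides) if overrides else (
        config or WorldConfig()
    )
    truth = generate_truth(config)
    pop = generate_population_table(config)
    obs = sample_observations(truth, pop, config)
    return SyntheticWorld(config=config, truth=truth, population=pop, observations=obs)
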