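"""Bayesian hierarchical model for rural/urban mean BMI trends.

The estimand is mean BMI by country, year, sex, estimation age group and
stratum (rural/urban).  For sex-specific data the rural surface is

    mu_rural(c, t, a) = a_c + b_c (t - t0) + u_c(t) + f(a) + g_c(a)

with country intercepts ``a_c`` and slopes ``b_c`` shrunk through region and
super-region levels toward global values, ``u_c`` a second-order random walk
(RW2) deviation constrained to carry no level or linear trend, ``f`` a global
cubic B-spline age curve and ``g_c`` shrunken country-level spline
deviations.  The urban surface adds a country- and year-varying difference

    mu_urban = mu_rural + d0_c + d1_c (t - t0)

with ``d0_c``/``d1_c`` shrunk hierarchically.  An observation is a weighted
combination of these cells — 10-year input age groups map onto the 5-year
estimation groups they span with population weights, and unstratified
("mixed") rows map onto share_urban * urban + (1 - share_urban) * rural —
plus a fixed coverage effect (subnational/community vs national reference)
and a study random effect whose SD grows from national to community sources:

    y_i ~ Normal(prediction_i + beta_cov(level_i) + nu_study(i),
                 se_i^2 + tau_level(i)^2)

All SD hyperparameters get half-Normal priors with configurable scales.

Because the model is linear-Gaussian given its variance hyperparameters, it
is sampled exactly by a blocked Gibbs scheme: all regression coefficients
are drawn jointly from their Gaussian full conditional (sparse normal
equations, one Cholesky per sweep), and each SD is updated by univariate
slice sampling followed by an ancillary-sufficiency interweaving step that
removes the usual funnel stickiness of centred parameterisations.
Convergence is monitored with split-R-hat and effective sample size on a
set of scalar summaries.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp
import xarray as xr
from scipy.linalg import cholesky, solve_triangular

from .schema import (
    ESTIMATION_AGE_GROUPS,
    AgeGroup,
    Hierarchy,
    age_group_midpoint,
    spanned_estimation_groups,
    years_in_group,
)
from .splines import bspline_basis
from .synthetic_world import PopulationTable, SyntheticWorld

__all__ = [
    "ModelConfig",
    "DesignBundle",
    "PosteriorDraws",
    "build_model_inputs",
    "fit_mcmc",
    "fit_world",
    "posterior_stratum_means",
    "predict_observation_draws",
]

_LEVELS = ("national", "subnational", "community")


@dataclass
class ModelConfig:
    """Hierarchy, grids, priors and MCMC settings for one sex-specific fit."""

    hierarchy: Hierarchy
    year_start: int = 1985
    year_end: int = 2017
    age_groups_est: list[AgeGroup] = field(
        default_factory=lambda: list(ESTIMATION_AGE_GROUPS)
    )
    knots: tuple[float, ...] = (30.0, 45.0, 60.0)
    boundary: tuple[float, float] = (18.0, 85.0)
    # MCMC
    n_draws: int = 5000
    burn: int = 500
    thin: int = 1
    seed: int = 0
    # component switches (used for degenerate/oracle configurations)
    include_hierarchy: bool = True
    include_slope: bool = True
    include_rw2: bool = True
    include_spline: bool = True
    include_spline_dev: bool = True
    include_gap: bool = True
    include_coverage_effects: bool = True
    include_study_effects: bool = True
    estimate_tau: bool = True
    # fixed priors (kg m^-2)
    prior_intercept_mean: float = 25.0
    prior_intercept_sd: float = 10.0
    prior_slope_sd: float = 0.5
    prior_spline_sd: float = 4.0
    prior_gap0_sd: float = 2.0
    prior_gap1_sd: float = 0.2
    prior_coverage_sd: float = 2.0
    # half-Normal scales for SD hyperparameters
    scale_intercept_sd: float = 2.0
    scale_slope_sd: float = 0.05
    scale_rw2_sd: float = 0.1
    scale_spline_sd: float = 1.0
    scale_gap0_sd: float = 1.0
    scale_gap1_sd: float = 0.05
    scale_phi: float = 0.5
    scale_tau: float = 0.3
    rhat_threshold: float = 1.05

    def validate(self) -> "ModelConfig":
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")
        for name in (
            "prior_intercept_sd", "prior_slope_sd", "scale_intercept_sd",
            "scale_rw2_sd", "scale_phi", "scale_tau",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        return self

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.year_start, self.year_end + 1)

    @property
    def ref_year(self) -> float:
        return (self.year_start + self.year_end) / 2.0

    @classmethod
    def from_world(cls, world: SyntheticWorld, **overrides) -> "ModelConfig":
        cfg = cls(
            hierarchy=world.truth.hierarchy,
            year_start=world.config.year_start,
            year_end=world.config.year_end,
            age_groups_est=list(world.config.estimation_age_groups),
        )
        return replace(cfg, **overrides) if overrides else cfg


class _Layout:
    """Named contiguous coefficient segments of the joint parameter vector."""

    def __init__(self) -> None:
        self.slices: dict[str, slice] = {}
        self.p = 0

    def add(self, name: str, n: int) -> None:
        if n > 0:
            self.slices[name] = slice(self.p, self.p + n)
            self.p += n

    def __contains__(self, name: str) -> bool:
        return name in self.slices

    def __getitem__(self, name: str) -> slice:
        return self.slices[name]


def _rw2_basis(n_years: int) -> np.ndarray:
    """Whitened RW2 basis: u = Z theta, theta ~ N(0, sigma^2 I).

    Z spans the complement of {constant, linear} so the RW2 deviation is
    identifiable against the intercept and slope; columns are scaled so that
    sigma is the innovation SD of the underlying walk.
    """
    if n_years < 3:
        return np.zeros((n_years, 0))
    D = np.zeros((n_years - 2, n_years))
    for i in range(n_years - 2):
        D[i, i : i + 3] = (1.0, -2.0, 1.0)
    K = D.T @ D
    lam, V = np.linalg.eigh(K)
    keep = lam > 1e-8
    return V[:, keep] / np.sqrt(lam[keep])


def observation_cell_weights(
    row: pd.Series,
    pop: PopulationTable,
    config: ModelConfig,
) -> list[tuple[int, int, float]]:
    """Weights of an observation over (estimation-age, stratum) cells.

    Stratum index 0 is rural, 1 urban.  Weights are population-based and sum
    to one; a "mixed" row splits across both strata by the urban share.
    """
    grid = config.age_groups_est
    spans = spanned_estimation_groups((row["age_lo"], row["age_hi"]), grid)
    idx = [i for i, _ in spans]
    frac = np.array([w / years_in_group(grid[i]) for i, w in spans])
    year = int(row["mid_year"])
    p = pop.population.sel(country=row["country"], year=year, sex=row["sex"]).values[idx] * frac
    s = pop.share_urban.sel(country=row["country"], year=year, sex=row["sex"]).values[idx]
    out: list[tuple[int, int, float]] = []
    if row["stratum"] == "rural":
        w = p * (1.0 - s)
        if w.sum() <= 0:
            w = p
        for a, wi in zip(idx, w / w.sum()):
            out.append((a, 0, wi))
    elif row["stratum"] == "urban":
        w = p * s
        if w.sum() <= 0:
            w = p
        for a, wi in zip(idx, w / w.sum()):
            out.append((a, 1, wi))
    elif row["stratum"] == "mixed":
        tot = p.sum()
        for a, pi, si in zip(idx, p / tot, s):
            if pi * (1 - si) > 0:
                out.append((a, 0, pi * (1 - si)))
            if pi * si > 0:
                out.append((a, 1, pi * si))
        if not out:  # zero population: fall back to even rural weights
            for a, f in zip(idx, frac / frac.sum()):
                out.append((a, 0, f))
    else:
        raise ValueError(f"unknown stratum {row['stratum']!r}")
    return out


@dataclass
class DesignBundle:
    """Sparse design and index structures for one sex-specific fit."""

    X: sp.csr_matrix
    y: np.ndarray
    se: np.ndarray
    level_code: np.ndarray  # 0 national, 1 subnational, 2 community
    study_level: np.ndarray  # per study
    studies: list[str]
    layout: _Layout
    config: ModelConfig
    sex: str
    # index arrays for prediction
    region_of: np.ndarray
    super_of_region: np.ndarray
    Z: np.ndarray  # whitened RW2 basis (T, T-2)
    B: np.ndarray  # spline basis at estimation-age midpoints (A, K)
    n_obs_by_country_year: pd.DataFrame


def build_model_inputs(
    observations: pd.DataFrame,
    pop: PopulationTable,
    config: ModelConfig,
) -> DesignBundle:
    """Map observations of a single sex onto model cells and parameters."""
    config.validate()
    sexes = observations["sex"].unique()
    if len(sexes) != 1:
        raise ValueError(f"observations must be a single sex; got {sorted(sexes)}")
    sex = str(sexes[0])
    hier = config.hierarchy
    unknown = set(observations["country"]) - set(hier.countries)
    if unknown:
        raise ValueError(f"observations for countries missing from hierarchy: {sorted(unknown)}")
    if len(observations) == 0:
        raise ValueError("no observations")

    countries = list(hier.countries)
    regions = list(hier.regions)
    supers = list(hier.super_regions)
    region_of = np.array([regions.index(hier.country_region[c]) for c in countries])
    super_of_region = np.array([supers.index(hier.region_super[r]) for r in regions])
    years = config.years
    n_c, n_r, n_s, n_t = len(countries), len(regions), len(supers), len(years)

    Z = _rw2_basis(n_t) if config.include_rw2 else np.zeros((n_t, 0))
    ages = np.array([age_group_midpoint(g) for g in config.age_groups_est])
    B = (
        bspline_basis(ages, config.knots, config.boundary)
        if config.include_spline
        else np.zeros((len(ages), 0))
    )
    K = B.shape[1]
    n_z = Z.shape[1]

    lay = _Layout()
    lay.add("g_int", 1)
    if config.include_hierarchy:
        lay.add("sr_int", n_s)
        lay.add("r_int", n_r)
        lay.add("c_int", n_c)
    if config.include_slope:
        lay.add("g_slope", 1)
        if config.include_hierarchy:
            lay.add("sr_slope", n_s)
            lay.add("r_slope", n_r)
            lay.add("c_slope", n_c)
    if config.include_spline:
        lay.add("spl_g", K)
        if config.include_spline_dev:
            lay.add("spl_dev", n_c * K)
    if config.include_rw2:
        lay.add("rw2", n_c * n_z)
    if config.include_gap:
        lay.add("g_d0", 1)
        lay.add("g_d1", 1)
        if config.include_hierarchy:
            lay.add("sr_d0", n_s)
            lay.add("r_d0", n_r)
            lay.add("c_d0", n_c)
            lay.add("sr_d1", n_s)
            lay.add("r_d1", n_r)
            lay.add("c_d1", n_c)
    if config.include_coverage_effects:
        lay.add("cov_fe", 2)
    studies = sorted(observations["study_id"].unique())
    study_idx = {s: i for i, s in enumerate(studies)}
    if config.include_study_effects:
        lay.add("study", len(studies))

    year_idx = {int(yv): i for i, yv in enumerate(years)}
    rows_i: list[int] = []
    cols_i: list[int] = []
    vals: list[float] = []
    level_code = np.empty(len(observations), dtype=int)
    study_level = np.zeros(len(studies), dtype=int)

    def put(i: int, seg: str, offset: int, v: float) -> None:
        rows_i.append(i)
        cols_i.append(lay[seg].start + offset)
        vals.append(v)

    obs = observations.reset_index(drop=True)
    for i, row in obs.iterrows():
        ci = countries.index(row["country"])
        ri = region_of[ci]
        si = super_of_region[ri]
        year = int(row["mid_year"])
        if year not in year_idx:
            raise ValueError(f"mid_year {year} outside model year grid")
        ti = year_idx[year]
        tc = year - config.ref_year
        lev = _LEVELS.index(row["coverage"])
        level_code[i] = lev
        sj = study_idx[row["study_id"]]
        study_level[sj] = max(study_level[sj], lev)

        cells = observation_cell_weights(row, pop, config)
        w_urban = sum(w for _, st, w in cells if st == 1)
        wa = np.zeros(len(ages))
        for a, _, w in cells:
            wa[a] += w

        put(i, "g_int", 0, 1.0)
        if config.include_hierarchy:
            put(i, "sr_int", si, 1.0)
            put(i, "r_int", ri, 1.0)
            put(i, "c_int", ci, 1.0)
        if config.include_slope:
            put(i, "g_slope", 0, tc)
            if config.include_hierarchy:
                put(i, "sr_slope", si, tc)
                put(i, "r_slope", ri, tc)
                put(i, "c_slope", ci, tc)
        if config.include_spline:
            for k in range(K):
                bk = float(wa @ B[:, k])
                if bk != 0.0:
                    put(i, "spl_g", k, bk)
                    if config.include_spline_dev:
                        put(i, "spl_dev", ci * K + k, bk)
        if config.include_rw2 and n_z:
            for j in range(n_z):
                zj = Z[ti, j]
                if zj != 0.0:
                    put(i, "rw2", ci * n_z + j, zj)
        if config.include_gap and w_urban > 0:
            put(i, "g_d0", 0, w_urban)
            put(i, "g_d1", 0, w_urban * tc)
            if config.include_hierarchy:
                put(i, "sr_d0", si, w_urban)
                put(i, "r_d0", ri, w_urban)
                put(i, "c_d0", ci, w_urban)
                put(i, "sr_d1", si, w_urban * tc)
                put(i, "r_d1", ri, w_urban * tc)
                put(i, "c_d1", ci, w_urban * tc)
        if config.include_coverage_effects and lev > 0:
            put(i, "cov_fe", lev - 1, 1.0)
        if config.include_study_effects:
            put(i, "study", sj, 1.0)

    X = sp.csr_matrix(
        (vals, (rows_i, cols_i)), shape=(len(obs), lay.p), dtype=float
    )
    noc = obs.groupby(["country", "mid_year"]).size().rename("n_obs").reset_index()
    return DesignBundle(
        X=X, y=obs["mean_bmi"].to_numpy(float), se=obs["se"].to_numpy(float),
        level_code=level_code, study_level=study_level, studies=studies,
        layout=lay, config=config, sex=sex, region_of=region_of,
        super_of_region=super_of_region, Z=Z, B=B, n_obs_by_country_year=noc,
    )


# ---------------------------------------------------------------------------
# Gibbs sampler


def _slice_sample(logf, x0: float, rng, w: float = 1.0, max_steps: int = 50,
                  lo: float = -np.inf, hi: float = np.inf) -> float:
    """Univariate slice sampler (stepping out + shrinkage) on a bounded line."""
    y = logf(x0) + math.log(rng.random())
    left = x0 - w * rng.random()
    right = left + w
    steps = max_steps
    while left > lo and steps > 0 and logf(left) > y:
        left -= w
        steps -= 1
    while right < hi and steps > 0 and logf(right) > y:
        right += w
        steps -= 1
    left, right = max(left, lo), min(right, hi)
    for _ in range(100):
        x1 = left + rng.random() * (right - left)
        if logf(x1) > y:
            return x1
        if x1 < x0:
            left = x1
        else:
            right = x1
    return x0


def _sd_block_logf(n: int, ss: float, scale: float):
    def logf(z: float) -> float:
        s2 = math.exp(2 * z)
        return -(n - 1) * z - ss / (2 * s2) - s2 / (2 * scale**2)
    return logf


@dataclass
class PosteriorDraws:
    """Posterior draws of the stratum-specific mean BMI surfaces.

    ``mu`` has dims (draw, country, year, age, stratum) in kg m^-2; the
    ``params`` table carries per-draw scalar parameters (hyper-SDs, coverage
    effects, global terms) needed for posterior-predictive work.
    """

    mu: xr.DataArray
    params: pd.DataFrame
    diagnostics: dict
    config: ModelConfig
    sex: str

    @property
    def n_draws(self) -> int:
        return self.mu.sizes["draw"]

    @property
    def converged(self) -> bool:
        return bool(self.diagnostics.get("converged", True))


def fit_mcmc(bundle: DesignBundle, config: ModelConfig | None = None) -> PosteriorDraws:
    """Sample the posterior by blocked Gibbs; return surface draws.

    The joint Gaussian conditional of all coefficients is drawn once per
    sweep; SD hyperparameters are slice-sampled and interwoven.  Flags (but
    does not discard) the result if split-R-hat exceeds the configured
    threshold on any monitored scalar.
    """
    config = (config or bundle.config).validate()
    lay = bundle.layout
    p = lay.p
    X = bundle.X
    Xt = X.T.tocsr()
    nnz_row = np.repeat(np.arange(X.shape[0]), np.diff(X.indptr))
    y = bundle.y
    se2 = bundle.se**2
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 524287)))

    hier = config.hierarchy
    n_c = len(hier.countries)

    # hyper-SD blocks: name -> (segment, half-normal scale)
    hyper_blocks: dict[str, tuple[str, float]] = {}
    if config.include_hierarchy:
        hyper_blocks["sd_int_sr"] = ("sr_int", config.scale_intercept_sd)
        hyper_blocks["sd_int_r"] = ("r_int", config.scale_intercept_sd)
        hyper_blocks["sd_int_c"] = ("c_int", config.scale_intercept_sd)
        if config.include_slope:
            hyper_blocks["sd_slope_sr"] = ("sr_slope", config.scale_slope_sd)
            hyper_blocks["sd_slope_r"] = ("r_slope", config.scale_slope_sd)
            hyper_blocks["sd_slope_c"] = ("c_slope", config.scale_slope_sd)
        if config.include_gap:
            hyper_blocks["sd_d0_sr"] = ("sr_d0", config.scale_gap0_sd)
            hyper_blocks["sd_d0_r"] = ("r_d0", config.scale_gap0_sd)
            hyper_blocks["sd_d0_c"] = ("c_d0", config.scale_gap0_sd)
            hyper_blocks["sd_d1_sr"] = ("sr_d1", config.scale_gap1_sd)
            hyper_blocks["sd_d1_r"] = ("r_d1", config.scale_gap1_sd)
            hyper_blocks["sd_d1_c"] = ("c_d1", config.scale_gap1_sd)
    if "spl_dev" in lay:
        hyper_blocks["sd_spline"] = ("spl_dev", config.scale_spline_sd)
    if "rw2" in lay:
        hyper_blocks["sd_rw2"] = ("rw2", config.scale_rw2_sd)

    sd_state = {name: 0.5 * scale for name, (_, scale) in hyper_blocks.items()}
    phi = np.array([0.1, 0.2, 0.3]) * (1.0 if config.include_study_effects else 0.0)
    tau = np.full(3, 0.05 if config.estimate_tau else 0.0)

    # per-level study index groups
    study_groups = [
        np.where(bundle.study_level == lev)[0] for lev in range(3)
    ] if "study" in lay else [np.array([], dtype=int)] * 3
    level_rows = [np.where(bundle.level_code == lev)[0] for lev in range(3)]

    # fixed (non-hyper) prior precisions and means
    prior_prec = np.zeros(p)
    prior_mean = np.zeros(p)

    def set_fixed(seg: str, sd: float, mean: float = 0.0) -> None:
        if seg in lay:
            prior_prec[lay[seg]] = 1.0 / sd**2
            prior_mean[lay[seg]] = mean

    set_fixed("g_int", config.prior_intercept_sd, config.prior_intercept_mean)
    set_fixed("g_slope", config.prior_slope_sd)
    set_fixed("spl_g", config.prior_spline_sd)
    set_fixed("g_d0", config.prior_gap0_sd)
    set_fixed("g_d1", config.prior_gap1_sd)
    set_fixed("cov_fe", config.prior_coverage_sd)

    # per-block csc column slices for interweaving
    Xc = X.tocsc()
    block_cols = {seg: Xc[:, lay[seg]].tocsr() for seg, _ in hyper_blocks.values()}

    beta = np.zeros(p)
    beta[lay["g_int"]] = config.prior_intercept_mean
    fitted = X @ beta

    n_iter = config.burn + config.n_draws * config.thin
    keep_every = config.thin
    beta_draws = np.empty((config.n_draws, p))
    hyper_names = (
        list(sd_state) + ["phi_nat", "phi_sub", "phi_com", "tau_nat", "tau_sub", "tau_com"]
    )
    hyper_draws = np.empty((config.n_draws, len(hyper_names)))
    kept = 0

    min_sd = 1e-4  # floor keeps conditionals proper when a block collapses

    for it in range(n_iter):
        # --- 1. joint coefficient draw
        prec = prior_prec.copy()
        mean_prec = prior_prec * prior_mean
        for name, (seg, _) in hyper_blocks.items():
            prec[lay[seg]] = 1.0 / max(sd_state[name], min_sd) ** 2
        if "study" in lay:
            sl = lay["study"]
            for lev in range(3):
                idx = study_groups[lev]
                prec[sl.start + idx] = 1.0 / max(phi[lev], min_sd) ** 2

        w = 1.0 / (se2 + tau[bundle.level_code] ** 2)
        WX = sp.csr_matrix((X.data * w[nnz_row], X.indices, X.indptr), shape=X.shape)
        A = (Xt @ WX).toarray()
        A[np.diag_indices_from(A)] += prec
        b = Xt @ (w * y) + mean_prec
        L = cholesky(A, lower=True)
        mu_beta = solve_triangular(
            L.T, solve_triangular(L, b, lower=True), lower=False
        )
        z = rng.standard_normal(p)
        beta = mu_beta + solve_triangular(L.T, z, lower=False)
        fitted = X @ beta

        # --- 2. SD hyperparameters: slice + interweave
        for name, (seg, scale) in hyper_blocks.items():
            coefs = beta[lay[seg]]
            n_b = len(coefs)
            ss = float(coefs @ coefs)
            z0 = math.log(max(sd_state[name], min_sd))
            z1 = _slice_sample(_sd_block_logf(n_b, ss, scale), z0, rng, w=1.0)
            sd_old = math.exp(z1)
            # interweaving: rescale the whole block against the data
            if sd_old > 1e-8:
                g = block_cols[seg] @ (coefs / sd_old)
                r_excl = y - fitted + sd_old * g
                q = float(g @ (w * g)) + 1.0 / scale**2
                m = float(g @ (w * r_excl)) / q
                s_draw = m + rng.standard_normal() / math.sqrt(q)
                beta[lay[seg]] = coefs * (s_draw / sd_old)
                fitted = fitted + (s_draw - sd_old) * g
                sd_state[name] = abs(s_draw)
            else:
                sd_state[name] = sd_old

        # --- 3. study-effect SDs with ordering phi_nat <= phi_sub <= phi_com
        if "study" in lay:
            sl = lay["study"]
            for lev in range(3):
                idx = study_groups[lev]
                if len(idx) == 0:
                    continue
                coefs = beta[sl.start + idx]
                ss = float(coefs @ coefs)
                lo = math.log(max(phi[lev - 1], 1e-4)) if lev > 0 else math.log(1e-4)
                hi = math.log(max(phi[lev + 1], 1e-4)) if lev < 2 else math.log(10.0)
                if hi <= lo:
                    hi = lo + 1e-6
                z0 = min(max(math.log(max(phi[lev], 1e-4)), lo), hi)
                z1 = _slice_sample(
                    _sd_block_logf(len(coefs), ss, config.scale_phi), z0, rng,
                    w=0.5, lo=lo, hi=hi,
                )
                phi[lev] = math.exp(z1)

        # --- 4. extra residual SD per coverage level
        if config.estimate_tau:
            resid = y - fitted
            for lev in range(3):
                idx = level_rows[lev]
                if len(idx) == 0:
                    continue
                r2 = resid[idx] ** 2
                s2e = se2[idx]

                def logf(zt: float) -> float:
                    t2 = math.exp(2 * zt)
                    v = s2e + t2
                    return float(
                        -0.5 * np.sum(np.log(v)) - 0.5 * np.sum(r2 / v)
                        - t2 / (2 * config.scale_tau**2) + zt
                    )

                z1 = _slice_sample(logf, math.log(max(tau[lev], 1e-4)), rng, w=0.7)
                tau[lev] = math.exp(z1)

        if it >= config.burn and (it - config.burn) % keep_every == 0 and kept < config.n_draws:
            beta_draws[kept] = beta
            hyper_draws[kept] = [sd_state[n] for n in sd_state] + list(phi) + list(tau)
            kept += 1

    params = pd.DataFrame(hyper_draws[:kept], columns=hyper_names)
    params["g_int"] = beta_draws[:kept, lay["g_int"].start]
    if "g_slope" in lay:
        params["g_slope"] = beta_draws[:kept, lay["g_slope"].start]
    if "cov_fe" in lay:
        params["beta_subnational"] = beta_draws[:kept, lay["cov_fe"].start]
        params["beta_community"] = beta_draws[:kept, lay["cov_fe"].start + 1]

    mu = _predict_surfaces(beta_draws[:kept], bundle, config)
    diagnostics = _diagnose(params, config)
    if not diagnostics["converged"]:
        warnings.warn(
            f"MCMC flagged as non-converged: max split-R-hat "
            f"{diagnostics['max_rhat']:.3f} > {config.rhat_threshold}"
        )
    return PosteriorDraws(
        mu=mu, params=params, diagnostics=diagnostics, config=config, sex=bundle.sex
    )


def _predict_surfaces(
    beta_draws: np.ndarray, bundle: DesignBundle, config: ModelConfig
) -> xr.DataArray:
    lay = bundle.layout
    hier = config.hierarchy
    countries = list(hier.countries)
    years = config.years
    tc = (years - config.ref_year).astype(float)
    n_d = beta_draws.shape[0]
    n_c, n_t = len(countries), len(years)
    ages = [int(g[0]) for g in config.age_groups_est]
    n_a = len(ages)
    ri = bundle.region_of
    si = bundle.super_of_region[ri]

    def seg(name):
        return beta_draws[:, lay[name]] if name in lay else None

    a_tot = np.repeat(seg("g_int"), n_c, axis=1)
    if config.include_hierarchy:
        a_tot = a_tot + seg("sr_int")[:, si] + seg("r_int")[:, ri] + seg("c_int")
    if config.include_slope:
        b_tot = np.repeat(seg("g_slope"), n_c, axis=1)
        if config.include_hierarchy:
            b_tot = b_tot + seg("sr_slope")[:, si] + seg("r_slope")[:, ri] + seg("c_slope")
    else:
        b_tot = np.zeros((n_d, n_c))

    mu = np.empty((n_d, n_c, n_t, n_a, 2), dtype=np.float32)
    base = a_tot[:, :, None] + b_tot[:, :, None] * tc[None, None, :]
    if config.include_rw2 and bundle.Z.shape[1]:
        theta = seg("rw2").reshape(n_d, n_c, -1)
        base = base + np.einsum("dcz,tz->dct", theta, bundle.Z)
    age_eff = np.zeros((n_d, n_a))
    if config.include_spline and bundle.B.shape[1]:
        age_eff = seg("spl_g") @ bundle.B.T
    rural = base[:, :, :, None] + age_eff[:, None, None, :]
    if "spl_dev" in lay:
        dev = seg("spl_dev").reshape(n_d, n_c, -1) @ bundle.B.T
        rural = rural + dev[:, :, None, :]
    mu[..., 0] = rural
    if config.include_gap:
        d0 = np.repeat(seg("g_d0"), n_c, axis=1)
        d1 = np.repeat(seg("g_d1"), n_c, axis=1)
        if config.include_hierarchy:
            d0 = d0 + seg("sr_d0")[:, si] + seg("r_d0")[:, ri] + seg("c_d0")
            d1 = d1 + seg("sr_d1")[:, si] + seg("r_d1")[:, ri] + seg("c_d1")
        gap = d0[:, :, None] + d1[:, :, None] * tc[None, None, :]
        mu[..., 1] = rural + gap[:, :, :, None]
    else:
        mu[..., 1] = rural
    return xr.DataArray(
        mu,
        dims=("draw", "country", "year", "age", "stratum"),
        coords={
            "draw": np.arange(n_d), "country": countries, "year": years,
            "age": ages, "stratum": ["rural", "urban"],
        },
    )


def _diagnose(params: pd.DataFrame, config: ModelConfig) -> dict:
    import arviz as az

    monitored = [c for c in (
        "g_int", "g_slope", "sd_rw2", "tau_nat", "phi_nat", "beta_subnational"
    ) if c in params.columns]
    n = len(params)
    rhats, esss = {}, {}
    if n >= 4:
        half = n // 2
        for c in monitored:
            arr = params[c].to_numpy()[: 2 * half].reshape(2, half)
            if np.allclose(arr.std(), 0):
                rhats[c], esss[c] = 1.0, float(n)
                continue
            rhats[c] = float(az.rhat(arr))
            esss[c] = float(az.ess(arr))
    max_rhat = max(rhats.values(), default=1.0)
    return {
        "rhat": rhats,
        "ess": esss,
        "max_rhat": max_rhat,
        "min_ess": min(esss.values(), default=float(n)),
        "converged": bool(max_rhat <= config.rhat_threshold),
    }


def fit_world(
    world: SyntheticWorld, sex: str, observations: pd.DataFrame | None = None, **overrides
) -> PosteriorDraws:
    """Convenience: configure from a synthetic world and fit one sex."""
    config = ModelConfig.from_world(world, **overrides)
    obs = world.observations if observations is None else observations
    bundle = build_model_inputs(
        obs[obs["sex"] == sex], world.population, config
    )
    return fit_mcmc(bundle, config)


def posterior_stratum_means(
    draws: PosteriorDraws,
    pop: PopulationTable,
    country: str,
    year: int,
    sex: str,
    age_group: int | AgeGroup,
) -> dict[str, np.ndarray]:
    """Per-draw rural/urban/mixed means for one estimation cell.

    ``mixed`` is share_urban * urban + (1 - share_urban) * rural.  When the
    whole population of the cell lives in one stratum, only that stratum
    (and the coinciding mixed series) is returned.
    """
    age = int(age_group[0]) if isinstance(age_group, (tuple, list)) else int(age_group)
    cell = draws.mu.sel(country=country, year=year, age=age)
    rural = cell.sel(stratum="rural").to_numpy().astype(float)
    urban = cell.sel(stratum="urban").to_numpy().astype(float)
    s = float(pop.share_urban.sel(country=country, year=year, sex=sex, age=age))
    mixed = s * urban + (1.0 - s) * rural
    if s <= 0.0:
        return {"rural": rural, "mixed": mixed}
    if s >= 1.0:
        return {"urban": urban, "mixed": mixed}
    return {"rural": rural, "urban": urban, "mixed": mixed}


def predict_observation_draws(
    draws: PosteriorDraws,
    observations: pd.DataFrame,
    pop: PopulationTable,
) -> np.ndarray:
    """Model-predicted means for observation rows, per draw.

    Includes the coverage fixed effect for subnational/community rows but no
    study effect or sampling noise; shape (n_obs, n_draws).
    """
    config = draws.config
    n_d = draws.n_draws
    out = np.empty((len(observations), n_d))
    mu = draws.mu
    cov_cols = {"subnational": "beta_subnational", "community": "beta_community"}
    for i, (_, row) in enumerate(observations.reset_index(drop=True).iterrows()):
        cells = observation_cell_weights(row, pop, config)
        acc = np.zeros(n_d)
        arr = mu.sel(country=row["country"], year=int(row["mid_year"])).to_numpy()
        for a, st, w in cells:
            acc += w * arr[:, a, st].astype(float)
        col = cov_cols.get(row["coverage"])
        if col is not None and col in draws.params.columns:
            acc += draws.params[col].to_numpy()
        out[i] = acc
    return out
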