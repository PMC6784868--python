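"""Held-out cross-validation of the trend model.

Two designs mirror standard external-validity checks for country estimates:

* ``countries`` — withhold all data from ~10% of countries with data,
  sampled within data-richness strata (source counts per country, with
  sex-specific thresholds for data-rich / average / data-poor);
* ``sources`` — withhold ~10% of data sources: for each selected country,
  either a random third of its sources (gap filling) or all of its
  post-2000 sources (recent extrapolation), chosen at random.

Held-out study summaries are compared with posterior-predictive draws for
the same cells (estimate draws plus coverage effect, study-effect and
residual noise, and the observation's own sampling SE); the report gives
the median error, median absolute error and 95% interval coverage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .postprocess import AgeStandard, load_who_standard
from .synthetic_world import PopulationTable, SyntheticWorld
from .trend_model import PosteriorDraws, fit_world, predict_observation_draws

__all__ = [
    "HoldoutPlan",
    "ValidationReport",
    "count_sources",
    "classify_data_richness",
    "split_holdout_countries",
    "split_holdout_sources",
    "score_predictions",
    "run_holdout_experiment",
    "RICHNESS_THRESHOLDS",
]

#: Sex-specific source-count ranges: (poor_max, average_max); rich is above.
RICHNESS_THRESHOLDS = {"female": (3, 7), "male": (2, 6)}


@dataclass
class HoldoutPlan:
    design: str  # "countries" | "sources"
    withheld_countries: list[str] = field(default_factory=list)
    withheld_studies: list[str] = field(default_factory=list)
    richness: dict[str, str] = field(default_factory=dict)  # country -> stratum
    scheme: dict[str, str] = field(default_factory=dict)  # country -> holdout scheme
    seed: int = 0
    repetition: int = 0

    def split(self, observations: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
        """(retained, withheld) partition of the observation table."""
        if self.design == "countries":
            held = observations["country"].isin(self.withheld_countries)
        else:
            held = observations["study_id"].isin(self.withheld_studies)
        return (
            observations[~held].reset_index(drop=True),
            observations[held].reset_index(drop=True),
        )


def count_sources(observations: pd.DataFrame, sex: str) -> pd.Series:
    """Distinct studies contributing at least one row for the sex, per country."""
    sub = observations[observations["sex"] == sex]
    return sub.groupby("country")["study_id"].nunique()


def classify_data_richness(n_sources: int, sex: str) -> str:
    poor_max, avg_max = RICHNESS_THRESHOLDS[sex]
    if n_sources <= 0:
        return "no_data"
    if n_sources <= poor_max:
        return "data_poor"
    if n_sources <= avg_max:
        return "average"
    return "data_rich"


def _stratified_country_sample(
    counts: pd.Series, sex: str, frac: float, rng
) -> tuple[list[str], dict[str, str]]:
    richness = {c: classify_data_richness(int(n), sex) for c, n in counts.items()}
    chosen: list[str] = []
    for stratum in ("data_rich", "average", "data_poor"):
        members = sorted(c for c, r in richness.items() if r == stratum)
        if not members:
            warnings.warn(f"no countries in stratum {stratum!r}; skipped")
            continue
        k = max(1, int(round(frac * len(members))))
        chosen.extend(rng.choice(members, size=min(k, len(members)), replace=False))
    return chosen, richness


def split_holdout_countries(
    observations: pd.DataFrame, sex: str, frac: float = 0.10, seed: int = 0,
    repetition: int = 0,
) -> HoldoutPlan:
    """Withhold all data from ~``frac`` of countries with data, per stratum."""
    rng = np.random.default_rng(np.random.SeedSequence((seed, 7919, repetition)))
    counts = count_sources(observations, sex)
    chosen, richness = _stratified_country_sample(counts, sex, frac, rng)
    return HoldoutPlan(
        design="countries", withheld_countries=sorted(chosen), richness=richness,
        seed=seed, repetition=repetition,
    )


def split_holdout_sources(
    observations: pd.DataFrame, sex: str, frac: float = 0.10, seed: int = 0,
    repetition: int = 0,
) -> HoldoutPlan:
    """Withhold ~``frac`` of data sources across a mix of countries.

    Countries are visited in random order stratified by data richness; each
    visited country loses either a random third of its sources or all of
    its sources with mid-year >= 2000 (falling back to the one-third scheme
    when it has no post-2000 data), until the withheld share of all sources
    reaches ``frac``.
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 104723, repetition)))
    sub = observations[observations["sex"] == sex]
    counts = count_sources(observations, sex)
    richness = {c: classify_data_richness(int(n), sex) for c, n in counts.items()}
    order: list[str] = []
    for stratum in ("data_rich", "average", "data_poor"):
        members = sorted(c for c, r in richness.items() if r == stratum)
        rng.shuffle(members)
        order.extend(members)
    # interleave strata so the mix covers all three richness groups
    by_stratum = [
        [c for c in order if richness[c] == s]
        for s in ("data_rich", "average", "data_poor")
    ]
    mixed: list[str] = []
    for i in range(max(map(len, by_stratum), default=0)):
        for lst in by_stratum:
            if i < len(lst):
                mixed.append(lst[i])

    total_sources = int(sub["study_id"].nunique())
    target = max(1, int(round(frac * total_sources)))
    withheld: list[str] = []
    scheme: dict[str, str] = {}
    for country in mixed:
        if len(withheld) >= target:
            break
        studies = sorted(sub.loc[sub["country"] == country, "study_id"].unique())
        use_recent = bool(rng.random() < 0.5)
        if use_recent:
            years = sub[sub["study_id"].isin(studies)].groupby("study_id")["mid_year"].first()
            recent = sorted(years.index[years >= 2000])
            if recent and len(recent) < len(studies):
                withheld.extend(recent)
                scheme[country] = "post2000"
                continue
            warnings.warn(
                f"{country}: post-2000 scheme not applicable; using one-third scheme"
            )
        k = max(1, int(round(len(studies) / 3)))
        take = rng.choice(studies, size=min(k, max(len(studies) - 1, 1)), replace=False)
        withheld.extend(take)
        scheme[country] = "one_third"
    return HoldoutPlan(
        design="sources", withheld_studies=sorted(set(withheld)), richness=richness,
        scheme=scheme, seed=seed, repetition=repetition,
    )


@dataclass
class ValidationReport:
    """Error metrics for held-out study summaries vs model predictions."""

    median_error: float
    median_abs_error: float
    coverage_pct: float
    n_cells: int
    repetitions: int = 1
    by_subset: pd.DataFrame | None = None


def score_predictions(
    heldout: pd.DataFrame,
    draws: PosteriorDraws,
    pop: PopulationTable,
    standard: AgeStandard | None = None,
    mode: str = "predictive",
    seed: int = 0,
) -> pd.DataFrame:
    """Per-cell errors and interval coverage for held-out summaries.

    Held-out rows are combined into one cell per (study, stratum) —
    an age-standardised mean over the age groups the study reports, with
    standard weights renormalised over those groups — and compared against
    the identically combined posterior draws.  ``mode='predictive'``
    (default) adds study-effect, extra-residual and sampling noise to the
    draws so the interval targets coverage of *data*; ``mode='estimate'``
    scores against the estimate draws alone.  Error = posterior-mean
    prediction minus observed value.
    """
    if heldout.empty:
        raise ValueError("no held-out observations to score")
    standard = standard or load_who_standard()
    rng = np.random.default_rng(np.random.SeedSequence((seed, 15485863)))
    rows = []
    phi_cols = {"national": "phi_nat", "subnational": "phi_sub", "community": "phi_com"}
    tau_cols = {"national": "tau_nat", "subnational": "tau_sub", "community": "tau_com"}
    for (study, stratum), grp in heldout.groupby(["study_id", "stratum"], sort=True):
        grp = grp.reset_index(drop=True)
        # standard weight of an input group = summed weights of the
        # estimation groups it spans; renormalised over reported groups
        wts = np.array([
            sum(standard.weights.get(a, 0.0)
                for a in range(int(lo), int(min(hi, 84)) + 1))
            for lo, hi in zip(grp["age_lo"], grp["age_hi"])
        ])
        if wts.sum() <= 0:
            wts = np.ones(len(grp))
        wts = wts / wts.sum()
        observed = float((wts * grp["mean_bmi"].to_numpy(float)).sum())
        se_comb = float(np.sqrt(((wts * grp["se"].to_numpy(float)) ** 2).sum()))
        pred = predict_observation_draws(draws, grp, pop)  # (n_rows, n_draws)
        combined = wts @ pred
        if mode == "predictive":
            level = grp.loc[0, "coverage"]
            phi = draws.params.get(phi_cols[level], pd.Series(np.zeros(draws.n_draws)))
            tau = draws.params.get(tau_cols[level], pd.Series(np.zeros(draws.n_draws)))
            sd = np.sqrt(se_comb**2 + phi.to_numpy() ** 2 + tau.to_numpy() ** 2)
            combined = combined + rng.standard_normal(draws.n_draws) * sd
        lo, hi = np.percentile(combined, [2.5, 97.5])
        rows.append({
            "study_id": study,
            "country": grp.loc[0, "country"],
            "sex": grp.loc[0, "sex"],
            "stratum": stratum,
            "mid_year": int(grp.loc[0, "mid_year"]),
            "observed": observed,
            "predicted": float(combined.mean()),
            "error": float(combined.mean()) - observed,
            "covered": bool(lo <= observed <= hi),
        })
    return pd.DataFrame(rows)


def summarize_scores(scores: pd.DataFrame, repetitions: int = 1) -> ValidationReport:
    by = (
        scores.assign(period=np.where(scores["mid_year"] < 2000, "1985-1999", "2000-2017"))
        .groupby(["sex", "period"])
        .agg(median_error=("error", "median"),
             median_abs_error=("error", lambda e: float(np.median(np.abs(e)))),
             coverage_pct=("covered", lambda c: 100.0 * float(np.mean(c))),
             n_cells=("error", "size"))
        .reset_index()
    )
    return ValidationReport(
        median_error=float(scores["error"].median()),
        median_abs_error=float(np.abs(scores["error"]).median()),
        coverage_pct=100.0 * float(scores["covered"].mean()),
        n_cells=len(scores),
        repetitions=repetitions,
        by_subset=by,
    )


def run_holdout_experiment(
    world: SyntheticWorld,
    sex: str,
    design: str = "sources",
    repetitions: int = 5,
    frac: float = 0.10,
    seed: int = 0,
    **fit_overrides,
) -> ValidationReport:
    """Repeat split / refit / score; pool the per-cell results.

    Each repetition withholds a fresh subset, refits the model on the
    retained data only, and scores the withheld study summaries.
    """
    obs = world.observations
    obs_sex = obs[obs["sex"] == sex]
    all_scores = []
    for rep in range(repetitions):
        if design == "countries":
            plan = split_holdout_countries(obs_sex, sex, frac, seed, repetition=rep)
        elif design == "sources":
            plan = split_holdout_sources(obs_sex, sex, frac, seed, repetition=rep)
        else:
            raise ValueError(f"unknown design {design!r}")
        retained, withheld = plan.split(obs_sex)
        if withheld.empty:
            warnings.warn(f"repetition {rep}: empty holdout; skipped")
            continue
        draws = fit_world(world, sex, observations=retained,
                          seed=seed + 31 * rep + 1, **fit_overrides)
        scores = score_predictions(
            withheld, draws, world.population, seed=seed + 97 * rep
        )
        scores["repetition"] = rep
        all_scores.append(scores)
    pooled = pd.concat(all_scores, ignore_index=True)
    return summarize_scores(pooled, repetitions=len(all_scores))
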