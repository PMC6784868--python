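"""Conversion of BMI-category prevalences to mean BMI with full uncertainty.

A small fraction of survey summaries report only the prevalence of BMI
categories (overweight, BMI >= 25; obesity, BMI >= 30; underweight,
BMI < 18.5) instead of mean BMI.  This module estimates, on paired cells
where both are observed, a linear regression of mean BMI on the logit of
the available prevalences with sex and age covariates and a study-level
random intercept, then converts prevalence-only cells by Monte Carlo:
each draw samples the prevalence (sampling error), the coefficients (their
joint covariance), a study random effect and a residual, so the reported SE
carries every source of conversion uncertainty.

Separate models are kept per *metric subset* — which prevalences a source
reports — rather than imputing missing metrics across subsets.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.special import logit
from scipy.stats import norm

from .schema import age_group_midpoint

__all__ = [
    "CrosswalkModel",
    "SubsetFit",
    "fit_crosswalk",
    "convert_prevalence_to_mean",
    "make_training_pairs",
    "simulate_crosswalk_pairs",
    "CANONICAL_SUBSETS",
]

PREVALENCE_METRICS = ("ge25", "ge30", "lt185")
_THRESH = {"ge25": 25.0, "ge30": 30.0, "lt185": 18.5}
CANONICAL_SUBSETS: tuple[tuple[str, ...], ...] = (
    ("ge25", "ge30", "lt185"),
    ("ge30",),
    ("ge25", "ge30"),
)

ALL_SOURCES = frozenset({"prevalence", "coefficients", "random_effect", "residual"})


class CrosswalkFitError(RuntimeError):
    pass


@dataclass
class SubsetFit:
    """Fitted conversion regression for one metric subset."""

    metrics: tuple[str, ...]
    colnames: list[str]
    coef: np.ndarray
    cov: np.ndarray  # coefficient covariance (positive semi-definite)
    re_sd: float  # study random-intercept SD
    resid_sd: float
    n_pairs: int

    def __post_init__(self) -> None:
        if self.resid_sd <= 0:
            raise CrosswalkFitError(f"non-positive residual SD for subset {self.metrics}")
        # near-collinear logit predictors can leave tiny negative eigenvalues;
        # repair those, reject anything genuinely indefinite
        c = (self.cov + np.asarray(self.cov).T) / 2
        lam, v = np.linalg.eigh(c)
        tol = 1e-6 * max(lam.max(), 1.0)
        if lam.min() < -tol:
            raise CrosswalkFitError(f"coefficient covariance not PSD for {self.metrics}")
        self.cov = (v * np.clip(lam, 0.0, None)) @ v.T


@dataclass
class CrosswalkModel:
    fits: dict[tuple[str, ...], SubsetFit] = field(default_factory=dict)

    def fit_for(self, available: set[str]) -> SubsetFit:
        """Exact subset match, else the largest fitted subset covered."""
        key = tuple(m for m in PREVALENCE_METRICS if m in available)
        if key in self.fits:
            return self.fits[key]
        candidates = [f for k, f in self.fits.items() if set(k) <= available]
        if not candidates:
            raise CrosswalkFitError(
                f"no fitted metric subset covers available metrics {sorted(available)}"
            )
        return max(candidates, key=lambda f: len(f.metrics))

    def to_yaml(self, path) -> None:
        doc = {
            "format": "rubmi-crosswalk-v1",
            "subsets": [
                {
                    "metrics": list(f.metrics),
                    "colnames": f.colnames,
                    "coef": f.coef.tolist(),
                    "cov": f.cov.tolist(),
                    "re_sd": float(f.re_sd),
                    "resid_sd": float(f.resid_sd),
                    "n_pairs": int(f.n_pairs),
                }
                for f in self.fits.values()
            ],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh)

    @classmethod
    def from_yaml(cls, path) -> "CrosswalkModel":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        fits = {}
        for d in doc["subsets"]:
            f = SubsetFit(
                metrics=tuple(d["metrics"]), colnames=d["colnames"],
                coef=np.asarray(d["coef"]), cov=np.asarray(d["cov"]),
                re_sd=d["re_sd"], resid_sd=d["resid_sd"], n_pairs=d["n_pairs"],
            )
            fits[f.metrics] = f
        return cls(fits=fits)


def _age_centred(df: pd.DataFrame) -> np.ndarray:
    mids = np.array(
        [age_group_midpoint((lo, hi)) for lo, hi in zip(df["age_lo"], df["age_hi"])]
    )
    return (mids - 50.0) / 10.0


def _design(df: pd.DataFrame, metrics: tuple[str, ...]) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(df))]
    names = ["const"]
    # clip at half a count so extreme prevalences saturate identically in
    # training and application
    lo = 1.0 / (2.0 * df["n_eff"].to_numpy(float))
    for m in metrics:
        p = df[f"prev_{m}"].to_numpy(float)
        cols.append(logit(np.clip(p, lo, 1.0 - lo)))
        names.append(f"logit_{m}")
    cols.append((df["sex"] == "male").to_numpy(float))
    names.append("sex_male")
    x = _age_centred(df)
    cols.extend([x, x**2])
    names.extend(["age_c", "age_c2"])
    return np.column_stack(cols), names


def _fe_covariance(X: np.ndarray, groups: np.ndarray, sigma2: float, re_var: float) -> np.ndarray:
    """GLS covariance of fixed effects given fitted variance components.

    Per-group V = sigma2 I + re_var 11'; inverted with the Woodbury
    identity.  More stable than the optimiser Hessian when the random-effect
    variance sits on the boundary.
    """
    k = X.shape[1]
    info = np.zeros((k, k))
    for g in pd.unique(groups):
        Xg = X[groups == g]
        n_g = len(Xg)
        xtx = Xg.T @ Xg
        if re_var > 0:
            s = Xg.sum(axis=0)
            shrink = re_var / (sigma2 + n_g * re_var)
            info += (xtx - shrink * np.outer(s, s)) / sigma2
        else:
            info += xtx / sigma2
    return np.linalg.pinv(info, hermitian=True)


def fit_crosswalk(
    paired: pd.DataFrame,
    subsets: tuple[tuple[str, ...], ...] = CANONICAL_SUBSETS,
    min_pairs: int = 50,
) -> CrosswalkModel:
    """Fit conversion regressions on cells with both mean BMI and prevalences.

    One mixed model (study random intercept) per metric subset.  Raises
    :class:`CrosswalkFitError` naming the subset if fewer than ``min_pairs``
    paired cells carry all its metrics.
    """
    from statsmodels.regression.mixed_linear_model import MixedLM

    model = CrosswalkModel()
    for metrics in subsets:
        need = [f"prev_{m}" for m in metrics]
        sub = paired.dropna(subset=need + ["mean_bmi"])
        if len(sub) < min_pairs:
            raise CrosswalkFitError(
                f"only {len(sub)} paired cells for metric subset {metrics}; "
                f"need >= {min_pairs}"
            )
        X, names = _design(sub, metrics)
        y = sub["mean_bmi"].to_numpy(float)
        groups = sub["study_id"].to_numpy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = MixedLM(y, X, groups=groups).fit(method="bfgs", reml=True)
        re_var = float(np.asarray(res.cov_re).ravel()[0]) if res.cov_re.size else 0.0
        cov = _fe_covariance(X, groups, float(res.scale), re_var)
        model.fits[tuple(metrics)] = SubsetFit(
            metrics=tuple(metrics), colnames=names,
            coef=np.asarray(res.fe_params, dtype=float), cov=cov,
            re_sd=math.sqrt(max(re_var, 0.0)),
            resid_sd=math.sqrt(float(res.scale)),
            n_pairs=len(sub),
        )
    return model


def make_training_pairs(
    observations: pd.DataFrame, seed: int = 0, sample_noise: bool = True
) -> pd.DataFrame:
    """Derive all three prevalences for mean-bearing cells (normal within-cell).

    Used to train the crosswalk on the same world the prevalence-only rows
    came from; requires the ``within_sd`` column.  By default the
    prevalences carry binomial sampling noise, so the regression is fitted
    on features distributed like the ones it will be applied to.
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 2741)))
    out = observations.copy()
    sd = out["within_sd"].to_numpy(float)
    m = out["mean_bmi"].to_numpy(float)
    n = out["n_eff"].to_numpy(float)
    for metric, thr in _THRESH.items():
        z = (m - thr) / sd
        p = norm.cdf(z) if metric != "lt185" else norm.cdf(-z)
        if sample_noise:
            p = rng.binomial(np.round(n).astype(int), p) / np.round(n)
        out[f"prev_{metric}"] = p
        out[f"prev_{metric}_se"] = np.maximum(np.sqrt(p * (1 - p) / n), 1.0 / (2 * n))
    return out


def simulate_crosswalk_pairs(
    n_cells: int,
    resid_sd: float = 0.4,
    re_sd: float = 0.3,
    n_studies: int = 40,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic paired cells with known injected residual and study noise.

    Cell means lie on a grid; prevalences follow the normal within-cell
    model; the reported mean adds a study effect and a residual, so the
    regression's residual SD and random-effect SD are recoverable.
    """
    rng = np.random.default_rng(seed)
    mu = rng.uniform(20.0, 30.0, n_cells)
    sd = rng.uniform(3.2, 4.5, n_cells)
    study = rng.integers(0, n_studies, n_cells)
    study_eff = rng.normal(0, re_sd, n_studies)
    sex = rng.choice(["female", "male"], n_cells)
    age_lo = rng.choice([20, 30, 40, 50, 60], n_cells)
    n = rng.integers(200, 800, n_cells)
    rows = {
        "study_id": [f"S{j:03d}" for j in study],
        "sex": sex,
        "age_lo": age_lo,
        "age_hi": age_lo + 9,
        "n_eff": n,
        "mean_bmi": mu + study_eff[study] + rng.normal(0, resid_sd, n_cells),
    }
    for metric, thr in _THRESH.items():
        z = (mu - thr) / sd
        p = norm.cdf(z) if metric != "lt185" else norm.cdf(-z)
        rows[f"prev_{metric}"] = p
        rows[f"prev_{metric}_se"] = np.maximum(np.sqrt(p * (1 - p) / n), 1e-9)
    return pd.DataFrame(rows)


def _sample_prevalences(
    p_hats: dict[str, float], row: pd.Series, n_eff: float, n_draws: int, rng
) -> dict[str, np.ndarray]:
    """Joint sampling draws of the reported prevalences.

    Prevalences from one sample are strongly correlated (they are partial
    sums of the same category counts), so multiple metrics are drawn from
    the implied multinomial over BMI categories rather than independently;
    a single metric uses its normal-approximation SE.
    """
    metrics = list(p_hats)
    if len(metrics) == 1:
        m = metrics[0]
        se_p = float(row[f"prev_{m}_se"])
        return {m: rng.normal(p_hats[m], se_p, n_draws)}
    # category probabilities below/between/above the reported thresholds
    p25 = p_hats.get("ge25")
    p30 = p_hats.get("ge30")
    plt = p_hats.get("lt185", None)
    cats: list[tuple[str, float]] = []
    if plt is not None:
        cats.append(("lt185", plt))
        mid_hi = 1.0 - plt
    else:
        mid_hi = 1.0
    if p25 is not None:
        cats.append(("mid", mid_hi - p25))
        cats.append(("ovw", p25 - (p30 if p30 is not None else 0.0)))
    else:
        cats.append(("mid", mid_hi - (p30 if p30 is not None else 0.0)))
    if p30 is not None:
        cats.append(("obe", p30))
    q = np.array([max(v, 1e-9) for _, v in cats])
    q = q / q.sum()
    n = max(int(round(n_eff)), 2)
    counts = rng.multinomial(n, q, size=n_draws) / n
    cols = {name: counts[:, i] for i, (name, _) in enumerate(cats)}
    out: dict[str, np.ndarray] = {}
    if "ge30" in p_hats:
        out["ge30"] = cols.get("obe", np.zeros(n_draws))
    if "ge25" in p_hats:
        out["ge25"] = cols.get("ovw", 0.0) + cols.get("obe", 0.0)
    if "lt185" in p_hats:
        out["lt185"] = cols["lt185"]
    return out


def convert_prevalence_to_mean(
    prevalence_obs: pd.DataFrame,
    model: CrosswalkModel,
    n_draws: int = 1000,
    seed: int = 0,
    sources: frozenset[str] = ALL_SOURCES,
) -> pd.DataFrame:
    """Convert prevalence-only rows to mean-BMI rows by uncertainty propagation.

    Per row and draw: sample the prevalences from their sampling
    distribution, the coefficients from their covariance, one new-study
    random effect and one residual; the converted mean is the draw average
    and the SE the draw SD.  ``sources`` can switch off individual
    uncertainty components (empty set gives the point prediction with SE 0).
    Deterministic given ``seed``.
    """
    out_rows = []
    for i, (_, row) in enumerate(prevalence_obs.iterrows()):
        available = {
            m for m in PREVALENCE_METRICS if pd.notna(row.get(f"prev_{m}", np.nan))
        }
        fit = model.fit_for(available)
        rng = np.random.default_rng(np.random.SeedSequence((seed, 104729, i)))
        n_eff = float(row["n_eff"])
        lo_clip, hi_clip = 1.0 / (2 * n_eff), 1.0 - 1.0 / (2 * n_eff)

        p_hats = {}
        for m in fit.metrics:
            p_hat = float(row[f"prev_{m}"])
            if p_hat <= 0.0 or p_hat >= 1.0:
                warnings.warn(
                    f"prevalence {m}={p_hat} clamped to [{lo_clip:.2g}, {hi_clip:.2g}]"
                )
                p_hat = min(max(p_hat, lo_clip), hi_clip)
            p_hats[m] = p_hat
        if "prevalence" in sources:
            p_draws = _sample_prevalences(p_hats, row, n_eff, n_draws, rng)
        else:
            p_draws = {m: np.full(n_draws, p) for m, p in p_hats.items()}
        draws_x = {
            m: logit(np.clip(p, lo_clip, hi_clip)) for m, p in p_draws.items()
        }

        frame = pd.DataFrame({
            "sex": [row["sex"]], "age_lo": [row["age_lo"]], "age_hi": [row["age_hi"]],
        })
        base_cols = {"const": np.ones(n_draws),
                     "sex_male": np.full(n_draws, float(row["sex"] == "male"))}
        x_age = _age_centred(frame)[0]
        base_cols["age_c"] = np.full(n_draws, x_age)
        base_cols["age_c2"] = np.full(n_draws, x_age**2)
        X = np.column_stack(
            [draws_x[n.removeprefix("logit_")] if n.startswith("logit_") else base_cols[n]
             for n in fit.colnames]
        )
        if "coefficients" in sources:
            beta = rng.multivariate_normal(fit.coef, fit.cov, size=n_draws,
                                           method="eigh")
        else:
            beta = np.broadcast_to(fit.coef, (n_draws, len(fit.coef)))
        mean_draws = np.einsum("dk,dk->d", X, beta)
        if "random_effect" in sources:
            mean_draws = mean_draws + rng.normal(0.0, fit.re_sd, n_draws)
        if "residual" in sources:
            mean_draws = mean_draws + rng.normal(0.0, fit.resid_sd, n_draws)

        new = row.drop(
            labels=[c for c in row.index if c.startswith("prev_")], errors="ignore"
        ).copy()
        new["mean_bmi"] = float(mean_draws.mean())
        new["se"] = float(mean_draws.std(ddof=1)) if n_draws > 1 else 0.0
        new["converted_from_prevalence"] = True
        out_rows.append(new)
    out = pd.DataFrame(out_rows).reset_index(drop=True)
    return out
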