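"""Design mapping, degenerate-model oracles and shrinkage behaviour of the
hierarchical trend model."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr

from rubmi.schema import Hierarchy
from rubmi.synthetic_world import WorldConfig, generate_world
from rubmi.trend_model import (
    ModelConfig,
    PosteriorDraws,
    build_model_inputs,
    fit_mcmc,
    fit_world,
    observation_cell_weights,
    posterior_stratum_means,
)

ONE_COUNTRY = Hierarchy(country_region={"A": "R"}, region_super={"R": "S"})


def obs_row(**kw):
    base = dict(study_id="s1", country="A", region="R", super_region="S",
                mid_year=2010, sex="female", age_lo=40, age_hi=49,
                stratum="rural", coverage="national", mean_bmi=25.0, se=0.1,
                n_eff=400)
    base.update(kw)
    return base


def test_default_draw_count_and_year_grid():
    cfg = ModelConfig(hierarchy=ONE_COUNTRY)
    assert cfg.n_draws == 5000
    assert cfg.years[0] == 1985 and cfg.years[-1] == 2017


def test_observation_weights_sum_to_one(default_world):
    world = default_world
    cfg = ModelConfig.from_world(world)
    obs = world.observations[world.observations.sex == "female"].head(200)
    for _, row in obs.iterrows():
        cells = observation_cell_weights(row, world.population, cfg)
        assert sum(w for _, _, w in cells) == pytest.approx(1.0, abs=1e-12)


def test_ten_year_group_splits_by_population(make_population):
    cfg = ModelConfig(
        hierarchy=ONE_COUNTRY, year_start=2010, year_end=2010,
        age_groups_est=[(20, 24), (25, 29)],
    )
    pop = make_population(["A"], [2010], ["female"], [20, 25])
    pop.population.loc[dict(age=20)] = 300.0
    pop.population.loc[dict(age=25)] = 100.0
    row = pd.Series(obs_row(age_lo=20, age_hi=29))
    cells = observation_cell_weights(row, pop, cfg)
    assert [(a, s) for a, s, _ in cells] == [(0, 0), (1, 0)]
    np.testing.assert_allclose([w for _, _, w in cells], [0.75, 0.25])


def test_mixed_row_with_zero_urban_share_maps_to_rural(make_population):
    cfg = ModelConfig(
        hierarchy=ONE_COUNTRY, year_start=2010, year_end=2010,
        age_groups_est=[(40, 49)],
    )
    pop = make_population(["A"], [2010], ["female"], [40], share=0.0)
    row = pd.Series(obs_row(stratum="mixed", age_lo=40, age_hi=49))
    cells = observation_cell_weights(row, pop, cfg)
    assert cells == [(0, 0, 1.0)]


def test_country_missing_from_hierarchy_rejected(make_population):
    cfg = ModelConfig(hierarchy=ONE_COUNTRY, year_start=2010, year_end=2010,
                      age_groups_est=[(40, 49)])
    pop = make_population(["A"], [2010], ["female"], [40])
    obs = pd.DataFrame([obs_row(country="ELSEWHERE")])
    with pytest.raises(ValueError, match="hierarchy"):
        build_model_inputs(obs, pop, cfg)


def _degenerate_config(**kw):
    base = dict(
        hierarchy=ONE_COUNTRY, year_start=2010, year_end=2010,
        age_groups_est=[(40, 49)], include_hierarchy=False, include_slope=False,
        include_rw2=False, include_spline=False, include_spline_dev=False,
        include_gap=False, include_coverage_effects=False,
        include_study_effects=False, estimate_tau=False,
    )
    base.update(kw)
    return ModelConfig(**base)


def test_intercept_only_model_matches_conjugate_posterior(make_population):
    """Known observation variances + flat structure -> closed-form posterior."""
    rng = np.random.default_rng(42)
    ses = np.array([0.15, 0.2, 0.3, 0.25, 0.4, 0.2])
    ys = 26.0 + rng.normal(0, 1, len(ses)) * ses
    obs = pd.DataFrame([
        obs_row(study_id=f"s{i}", mean_bmi=y, se=s) for i, (y, s) in enumerate(zip(ys, ses))
    ])
    cfg = _degenerate_config(n_draws=5000, burn=200, seed=11)
    pop = make_population(["A"], [2010], ["female"], [40])
    draws = fit_mcmc(build_model_inputs(obs, pop, cfg), cfg)
    sample = draws.mu.isel(country=0, year=0, age=0).sel(stratum="rural").to_numpy()

    prec = 1 / cfg.prior_intercept_sd**2 + np.sum(1 / ses**2)
    post_mean = (cfg.prior_intercept_mean / cfg.prior_intercept_sd**2 + np.sum(ys / ses**2)) / prec
    post_sd = prec**-0.5
    assert sample.mean() == pytest.approx(post_mean, abs=0.02)
    assert sample.std() == pytest.approx(post_sd, rel=0.05)


def test_noise_free_linear_trend_is_reproduced(make_population):
    years = list(range(2000, 2011))
    truth = {y: 24.0 + 0.08 * (y - 2005) for y in years}
    obs = pd.DataFrame([
        obs_row(study_id=f"s{y}", mid_year=y, mean_bmi=truth[y], se=1e-3)
        for y in years
    ])
    cfg = _degenerate_config(
        year_start=2000, year_end=2010, include_slope=True,
        n_draws=800, burn=200, seed=2,
    )
    pop = make_population(["A"], years, ["female"], [40])
    draws = fit_mcmc(build_model_inputs(obs, pop, cfg), cfg)
    est = draws.mu.isel(country=0, age=0).sel(stratum="rural").mean("draw").to_numpy()
    expect = np.array([truth[y] for y in years])
    assert np.abs(est - expect).max() < 0.05


def test_no_data_country_shrinks_to_its_region():
    """A country without data should land near its region, not the other one."""
    world = generate_world(WorldConfig(
        n_super_regions=1, regions_per_super=2, countries_per_region=3,
        year_start=2000, year_end=2011, sexes=("female",),
        age_groups=[(30, 39), (40, 49)], estimation_age_groups=[(30, 39), (40, 49)],
        trend_sd_hierarchy=(0.1, 2.5, 0.3), surveys_per_country=6.0, seed=21,
    ))
    target = "SR0R1C2"
    obs = world.observations
    held = obs[(obs.sex == "female") & (obs.country != target)]
    draws = fit_world(world, "female", observations=held, n_draws=300, burn=250, seed=5)
    est = draws.mu.sel(country=target, year=2006, stratum="rural").mean(
        ("draw", "age")
    ).item()
    region_means = {
        reg: draws.mu.sel(
            country=[c for c in world.truth.hierarchy.countries
                     if world.truth.hierarchy.country_region[c] == reg and c != target],
            year=2006, stratum="rural",
        ).mean(("draw", "age", "country")).item()
        for reg in ("SR0R0", "SR0R1")
    }
    assert abs(est - region_means["SR0R1"]) < abs(est - region_means["SR0R0"])


def test_community_study_less_influential_than_national(make_population):
    years = list(range(2000, 2011))
    rng = np.random.default_rng(8)
    base = [obs_row(study_id=f"s{y}", mid_year=y,
                    mean_bmi=25 + rng.normal(0, 0.2), se=0.2) for y in years[:8]]
    extra_nat = obs_row(study_id="extra", mid_year=2009, mean_bmi=27.5, se=0.2)
    extra_com = {**extra_nat, "coverage": "community"}
    cfg = _degenerate_config(
        year_start=2000, year_end=2010, include_coverage_effects=True,
        include_study_effects=True, estimate_tau=True,
        n_draws=500, burn=300, seed=4,
    )
    pop = make_population(["A"], years, ["female"], [40])

    def est_2009(rows):
        d = fit_mcmc(build_model_inputs(pd.DataFrame(rows), pop, cfg), cfg)
        return d.mu.sel(year=2009, stratum="rural").mean().item()

    without = est_2009(base)
    with_nat = est_2009(base + [extra_nat])
    with_com = est_2009(base + [extra_com])
    assert abs(with_com - without) < abs(with_nat - without)


def test_urban_gap_change_sign_recovered(default_world, recovery_fit):
    """Posterior sign of the 1985-2017 gap change matches truth for most
    countries with a non-trivial true change."""
    world = default_world
    truth_gap = world.truth.gap.sel(sex="female")
    d_truth = truth_gap.sel(year=2017) - truth_gap.sel(year=1985)
    gap_draws = recovery_fit.mu.sel(stratum="urban") - recovery_fit.mu.sel(stratum="rural")
    d_est = (
        gap_draws.sel(year=2017) - gap_draws.sel(year=1985)
    ).mean(("draw", "age"))
    mask = np.abs(d_truth) > 0.1
    agree = np.sign(d_est.where(mask)) == np.sign(d_truth.where(mask))
    assert float(agree.sum()) / float(mask.sum()) >= 0.9


def test_posterior_stratum_means_definition(make_population):
    mu = xr.DataArray(
        np.stack([np.full((50, 1, 1, 1), 20.0), np.full((50, 1, 1, 1), 24.0)], axis=-1),
        dims=("draw", "country", "year", "age", "stratum"),
        coords={"draw": range(50), "country": ["A"], "year": [2010], "age": [40],
                "stratum": ["rural", "urban"]},
    )
    cfg = _degenerate_config()
    draws = PosteriorDraws(mu=mu, params=pd.DataFrame(), diagnostics={}, config=cfg,
                           sex="female")
    pop = make_population(["A"], [2010], ["female"], [40], share=0.5)
    out = posterior_stratum_means(draws, pop, "A", 2010, "female", 40)
    np.testing.assert_allclose(out["mixed"], 22.0)

    pop_all_urban = make_population(["A"], [2010], ["female"], [40], share=1.0)
    out = posterior_stratum_means(draws, pop_all_urban, "A", 2010, "female", 40)
    assert "rural" not in out
    np.testing.assert_allclose(out["mixed"], out["urban"])


def test_mixed_series_consistent_with_decomposition_reconstruction(
    default_world, recovery_fit
):
    """The share-weighted mixed series equals the decomposition identity's
    population-mean reconstruction on the same draws."""
    from rubmi.decomposition import DecompositionInput, decompose_change

    world = default_world
    country = world.truth.hierarchy.countries[0]
    age = 40
    r0 = posterior_stratum_means(recovery_fit, world.population, country, 1985, "female", age)
    r1 = posterior_stratum_means(recovery_fit, world.population, country, 2017, "female", age)
    s0 = float(world.population.share_urban.sel(country=country, year=1985, sex="female", age=age))
    s1 = float(world.population.share_urban.sel(country=country, year=2017, sex="female", age=age))
    comp = decompose_change(DecompositionInput(
        rural_start=r0["rural"], rural_end=r1["rural"],
        urban_start=r0["urban"], urban_end=r1["urban"],
        share_urban_start=s0, share_urban_end=s1,
    ))
    np.testing.assert_allclose(
        comp["total"], r1["mixed"] - r0["mixed"], atol=1e-6
    )
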