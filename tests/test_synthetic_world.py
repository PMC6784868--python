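"""Tests of the synthetic world generator: determinism, degenerate limits,
conservation of the mixed-stratum definition, and noise scaling."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from rubmi.schema import read_observations, write_observations
from rubmi.synthetic_world import (
    WorldConfig,
    WorldConfigError,
    generate_population_table,
    generate_truth,
    generate_world,
    make_prevalence_only_subset,
    sample_observations,
)

TINY = dict(
    n_super_regions=1,
    regions_per_super=2,
    countries_per_region=2,
    year_start=2000,
    year_end=2011,
    sexes=("female",),
    age_groups=[(20, 29), (30, 39), (40, 49)],
    estimation_age_groups=[(20, 29), (30, 39), (40, 49)],
    surveys_per_country=4.0,
)


def test_same_seed_reproduces_world_exactly():
    w1 = generate_world(seed=7, **TINY)
    w2 = generate_world(seed=7, **TINY)
    pd.testing.assert_frame_equal(w1.observations, w2.observations)
    assert w1.truth.rural.equals(w2.truth.rural)
    assert w1.population.share_urban.equals(w2.population.share_urban)
    w3 = generate_world(seed=8, **TINY)
    assert not w1.truth.rural.equals(w3.truth.rural)


def test_zero_variance_hierarchy_gives_one_shared_surface():
    cfg = WorldConfig(
        **TINY,
        trend_sd_hierarchy=(0, 0, 0),
        slope_sd_hierarchy=(0, 0, 0),
        rw2_innovation_sd=0.0,
        age_dev_sd=0.0,
        urban_gap_base_mean=0.0,
        urban_gap_base_sd=0.0,
        urban_gap_trend_mean=0.0,
        urban_gap_trend_sd=0.0,
    )
    truth = generate_truth(cfg)
    ref = truth.rural.isel(country=0)
    for ci in range(truth.rural.sizes["country"]):
        np.testing.assert_allclose(truth.rural.isel(country=ci).values, ref.values)
    np.testing.assert_allclose(truth.gap.values, 0.0)


def test_zero_rw2_innovation_gives_exactly_linear_trends():
    cfg = WorldConfig(**TINY, rw2_innovation_sd=0.0)
    truth = generate_truth(cfg)
    years = cfg.years.astype(float)
    X = np.column_stack([np.ones_like(years), years])
    for ci in range(truth.rural.sizes["country"]):
        for ai in range(truth.rural.sizes["age"]):
            y = truth.rural.isel(country=ci, sex=0, age=ai).values
            resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
            assert np.abs(resid).max() < 1e-9


def test_noise_free_mixed_rows_equal_share_weighted_truth():
    cfg = WorldConfig(
        **{**TINY, "age_groups": [(20, 29)], "estimation_age_groups": [(20, 29)]},
        coverage_offsets={"national": 0.0, "subnational": 0.0, "community": 0.0},
        coverage_extra_sd={"national": 0.0, "subnational": 0.0, "community": 0.0},
        frac_unstratified=1.0,
        obs_n_range=(10**14, 10**14 + 1),
        seed=5,
    )
    truth = generate_truth(cfg)
    pop = generate_population_table(cfg)
    obs = sample_observations(truth, pop, cfg)
    assert set(obs["stratum"]) == {"mixed"}
    for _, row in obs.iterrows():
        r = truth.rural.sel(country=row.country, year=row.mid_year, sex=row.sex).item()
        u = r + truth.gap.sel(country=row.country, year=row.mid_year, sex=row.sex).item()
        s = pop.share(row.country, int(row.mid_year), row.sex)
        assert row.mean_bmi == pytest.approx(s * u + (1 - s) * r, abs=1e-4)


def test_reported_se_scales_as_inverse_sqrt_n(default_world):
    obs = default_world.observations
    one_sex = obs[obs.sex == "female"]
    slope = np.polyfit(np.log(one_sex.n_eff), np.log(one_sex.se), 1)[0]
    assert slope == pytest.approx(-0.5, abs=0.02)


def test_region_level_spread_dominates_when_region_sd_larger():
    cfg = WorldConfig(
        n_super_regions=1, regions_per_super=8, countries_per_region=6,
        year_start=2000, year_end=2005, sexes=("female",),
        age_groups=[(30, 39)], estimation_age_groups=[(30, 39)],
        trend_sd_hierarchy=(0.1, 2.0, 0.2), seed=11,
    )
    truth = generate_truth(cfg)
    level = truth.rural.isel(sex=0, age=0, year=0).to_series()
    region = pd.Series(
        {c: truth.hierarchy.country_region[c] for c in level.index}
    )
    within = level.groupby(region).var().mean()
    between = level.groupby(region).mean().var()
    assert within < between


def test_urban_share_invariants_across_seeds():
    starts, ends = [], []
    for seed in range(10):
        pop = generate_population_table(WorldConfig(**TINY, seed=seed))
        s = pop.share_urban
        assert float(s.min()) >= 0.0 and float(s.max()) <= 1.0
        assert (s.diff("year") >= -1e-12).all()
        starts.append(float(s.isel(year=0).mean()))
        ends.append(float(s.isel(year=-1).mean()))
    assert np.mean(ends) > np.mean(starts)


def test_prevalence_subset_selection_and_normal_tail(default_world):
    cfg0 = dataclasses.replace(default_world.config, frac_prevalence_only=0.0)
    keep, prev = make_prevalence_only_subset(default_world.observations, cfg0)
    assert prev.empty and len(keep) == len(default_world.observations)

    keep, prev = make_prevalence_only_subset(default_world.observations, default_world.config)
    n = len(default_world.observations)
    expect = 0.02 * n
    tol = 3 * math.sqrt(n * 0.02 * 0.98)
    assert abs(len(prev) - expect) <= tol
    assert len(keep) + len(prev) == n

    # normal-tail identity for a converted cell: P(BMI >= 30) for N(25, 4)
    cell = prev.dropna(subset=["prev_ge30"]).iloc[0]
    z = (cell.mean_bmi_true - 30.0) / cell.within_sd
    assert cell.prev_ge30 == pytest.approx(norm.cdf(z), abs=1e-6)


def test_observation_csv_round_trip(tmp_path, default_world):
    path = tmp_path / "obs.csv"
    write_observations(default_world.observations, path)
    back = read_observations(path)
    pd.testing.assert_frame_equal(
        back[sorted(back.columns)],
        default_world.observations[sorted(back.columns)].reset_index(drop=True),
        check_dtype=False,
    )


@pytest.mark.parametrize(
    "field,value",
    [
        ("rw2_innovation_sd", -0.1),
        ("frac_prevalence_only", 1.5),
        ("year_end", 1980),
        ("age_groups", [(15, 19)]),
        ("age_groups", [(20, 29), (25, 34)]),
    ],
)
def test_invalid_config_raises_naming_field(field, value):
    cfg = dataclasses.replace(WorldConfig(), **{field: value})
    with pytest.raises(WorldConfigError):
        cfg.validate()
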