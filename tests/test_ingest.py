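"""Cleaning rules, age grouping and weighted stratified summaries."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from rubmi.ingest import (
    IndividualRecord,
    assign_age_group,
    clean_individual_records,
    load_summary_file,
    records_frame,
    summarize_stratified,
)
from rubmi.schema import ObservationValidationError, write_observations


def rec(**kw):
    base = dict(study_id="S1", age=30, sex="female", height=165.0, weight=65.0,
                pregnant=False, stratum="rural", weight_sample=1.0)
    base.update(kw)
    return IndividualRecord(**base)


@pytest.mark.parametrize(
    "record,reason",
    [
        (rec(height=170.0, weight=28.0), "implausible BMI"),  # BMI 9.7
        (rec(age=17), "age"),
        (rec(pregnant=True), "pregnant"),
        (rec(height=99.0), "implausible height/weight"),
        (rec(weight=301.0), "implausible height/weight"),
        (rec(weight=None), "missing"),
    ],
)
def test_records_excluded_with_reason(record, reason):
    kept, log = clean_individual_records([record])
    assert kept.empty
    assert log.set_index("reason").loc[reason, "count"] == 1


@pytest.mark.parametrize(
    "record",
    [
        rec(height=250.0, weight=100.0),  # bounds are inclusive
        rec(height=100.0, weight=12.0),
        rec(age=18),
        rec(height=160.0, weight=25.7),  # BMI just above 10
    ],
)
def test_boundary_records_are_kept(record):
    kept, _ = clean_individual_records([record])
    assert len(kept) == 1


def test_unknown_stratum_dropped_only_where_residence_recorded():
    records = [
        rec(study_id="HAS", stratum="rural"),
        rec(study_id="HAS", stratum="unknown"),
        rec(study_id="NONE", stratum="unknown"),
        rec(study_id="NONE", stratum="unknown"),
    ]
    kept, log = clean_individual_records(records)
    assert set(kept.study_id) == {"HAS", "NONE"}
    assert len(kept[kept.study_id == "NONE"]) == 2
    assert log.set_index("reason").loc["unknown stratum", "count"] == 1


def test_cleaning_is_idempotent_and_counts_balance():
    rng = np.random.default_rng(0)
    records = [
        rec(age=float(rng.integers(10, 90)), height=float(rng.uniform(90, 260)),
            weight=float(rng.uniform(10, 310)), stratum=str(rng.choice(["rural", "urban", "unknown"])))
        for _ in range(200)
    ]
    kept, log = clean_individual_records(records)
    assert log["count"].sum() + len(kept) == 200
    again, log2 = clean_individual_records(kept.drop(columns=["bmi"]))
    assert len(again) == len(kept)
    assert log2["count"].sum() == 0


@pytest.mark.parametrize(
    "age,expected",
    [(18, (18, 18)), (19, (19, 19)), (20, (20, 29)), (37, (30, 39)),
     (79, (70, 79)), (80, (80, math.inf)), (101, (80, math.inf)), (18.7, (18, 18))],
)
def test_age_group_assignment(age, expected):
    assert assign_age_group(age) == expected


def test_age_below_adult_range_rejected():
    with pytest.raises(ValueError):
        assign_age_group(17)


def test_weighted_summaries_match_hand_arithmetic():
    records = [rec(weight=w, height=100.0) for w in (20.0, 22.0, 24.0)]  # BMI == weight
    out = summarize_stratified(records_frame(records))
    assert len(out) == 1
    assert out.loc[0, "mean_bmi"] == pytest.approx(22.0)

    records = [rec(weight=20.0, height=100.0, weight_sample=1.0),
               rec(weight=30.0, height=100.0, weight_sample=3.0)]
    out = summarize_stratified(records_frame(records))
    assert out.loc[0, "mean_bmi"] == pytest.approx(27.5)
    assert out.loc[0, "n_eff"] == pytest.approx(16 / 10)


@given(st.randoms(use_true_random=False), st.floats(0.1, 10.0))
def test_summaries_invariant_to_order_and_weight_scale(rnd, scale):
    rng = np.random.default_rng(rnd.randint(0, 10**6))
    df = records_frame([
        rec(weight=float(rng.uniform(50, 90)), age=float(rng.integers(20, 60)),
            weight_sample=float(rng.uniform(0.5, 2.0)),
            stratum=str(rng.choice(["rural", "urban"])))
        for _ in range(30)
    ])
    base = summarize_stratified(df)
    shuffled = df.sample(frac=1.0, random_state=1).reset_index(drop=True)
    shuffled["weight_sample"] *= scale
    other = summarize_stratified(shuffled)
    key = ["sex", "age_lo", "stratum"]
    pd.testing.assert_frame_equal(
        base.sort_values(key).reset_index(drop=True)[["mean_bmi", "se", "n_eff"]],
        other.sort_values(key).reset_index(drop=True)[["mean_bmi", "se", "n_eff"]],
        check_exact=False, atol=1e-9,
    )


def test_weighted_se_agrees_with_bootstrap():
    rng = np.random.default_rng(3)
    # two sampling clusters with different weights, as in a small survey
    bmis = np.r_[rng.normal(25, 3, 120), rng.normal(27, 3, 80)]
    wts = np.r_[np.full(120, 1.0), np.full(80, 2.5)]
    df = records_frame([
        rec(weight=b, height=100.0, weight_sample=w) for b, w in zip(bmis, wts)
    ])
    out = summarize_stratified(df)
    se_analytic = out.loc[0, "se"]
    boots = []
    for _ in range(500):
        idx = rng.integers(0, len(bmis), len(bmis))
        boots.append(np.average(bmis[idx], weights=wts[idx]))
    assert se_analytic == pytest.approx(np.std(boots), rel=0.15)


def test_studies_without_residence_become_mixed_rows():
    records = [rec(study_id="X", stratum="unknown") for _ in range(5)]
    out = summarize_stratified(records_frame(records))
    assert set(out["stratum"]) == {"mixed"}


def test_summary_file_validation(tmp_path, default_world):
    path = tmp_path / "obs.csv"
    obs = default_world.observations.head(20).copy()
    write_observations(obs, path)
    loaded = load_summary_file(path)
    assert len(loaded) == 20
    assert (loaded["stratum"] == obs["stratum"].values).all()

    bad = obs.copy()
    bad.loc[bad.index[0], "se"] = 0.0
    write_observations(bad, tmp_path / "bad_se.csv")
    with pytest.raises(ObservationValidationError, match="se"):
        load_summary_file(tmp_path / "bad_se.csv")

    bad = obs.copy()
    bad.loc[bad.index[0], "stratum"] = "periurban"
    write_observations(bad, tmp_path / "bad_stratum.csv")
    with pytest.raises(ObservationValidationError, match="stratum"):
        load_summary_file(tmp_path / "bad_stratum.csv")
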