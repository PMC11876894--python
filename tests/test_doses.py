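"""Tests of MME arithmetic, 30-day windowing, covariates and comorbidity flags."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from opitraj.doses import (
    CovariateSeries,
    comorbidity_flags,
    mme_daily_dose,
    monthly_dose_series,
    stimulant_covariates,
    summarize_dosing,
)
from opitraj.errors import DomainError

from conftest import day_level_dose_oracle, fills_frame


@pytest.mark.parametrize(
    "strength,qty,days,factor,expected",
    [(5, 60, 30, 1.0, 10.0), (10, 30, 30, 1.5, 15.0), (15, 90, 30, 1.0, 45.0)],
)
def test_mme_daily_dose_formula(strength, qty, days, factor, expected):
    rec = {
        "drug_class": "opioid", "strength_mg": strength, "quantity": qty,
        "days_supply": days, "mme_factor": factor,
    }
    assert mme_daily_dose(rec) == pytest.approx(expected)


def test_mme_rejects_non_opioid_and_bad_factor():
    with pytest.raises(DomainError):
        mme_daily_dose({"drug_class": "stimulant", "strength_mg": 10, "quantity": 30,
                        "days_supply": 30, "mme_factor": 1.0})
    with pytest.raises(DomainError):
        mme_daily_dose({"drug_class": "opioid", "strength_mg": 10, "quantity": 30,
                        "days_supply": 30, "mme_factor": 0.0})


def test_no_fills_gives_zero_vector(member):
    assert monthly_dose_series(member, fills_frame([])).tolist() == [0.0] * 6


def test_single_fill_dispense_date_mode(member):
    fills = fills_frame([(member.index_day, "opioid", "oral", 5, 60, 30, 1.0)])
    values = monthly_dose_series(member, fills, "dispense_date")
    assert values[0] == pytest.approx(300 / 30)
    assert (values[1:] == 0).all()


def test_supply_spread_splits_across_window_boundary(member):
    fills = fills_frame([(member.index_day + 15, "opioid", "oral", 5, 60, 30, 1.0)])
    values = monthly_dose_series(member, fills, "supply_spread")
    assert values[0] == pytest.approx(10 * 15 / 30)
    assert values[1] == pytest.approx(10 * 15 / 30)
    assert (values[2:] == 0).all()


def test_modes_agree_when_supply_within_one_window(member):
    fills = fills_frame([(member.index_day + 30 * w, "opioid", "oral", 5, 30, 30, 1.0)
                         for w in range(4)])
    a = monthly_dose_series(member, fills, "dispense_date")
    b = monthly_dose_series(member, fills, "supply_spread")
    np.testing.assert_allclose(a, b)


def test_both_modes_match_day_level_oracle(member):
    rng = np.random.default_rng(12)
    rows = []
    for _ in range(30):
        day = int(member.index_day + rng.integers(-10, 200))
        cls = rng.choice(["opioid", "stimulant"], p=[0.8, 0.2])
        route = rng.choice(["oral", "patch"], p=[0.85, 0.15])
        rows.append((day, cls, route, float(rng.choice([5, 10, 15])),
                     float(rng.integers(10, 90)), int(rng.choice([7, 14, 30])), 1.5))
    fills = fills_frame(rows)
    for mode in ("dispense_date", "supply_spread"):
        np.testing.assert_allclose(
            monthly_dose_series(member, fills, mode),
            day_level_dose_oracle(member, fills, mode),
            atol=1e-10,
        )


def test_dispense_mode_conserves_dispensed_mme(member):
    rng = np.random.default_rng(5)
    rows = [(int(member.index_day + rng.integers(0, member.n_windows * 30)),
             "opioid", "oral", 10.0, float(rng.integers(1, 60)), 30, 1.0)
            for _ in range(25)]
    fills = fills_frame(rows)
    values = monthly_dose_series(member, fills, "dispense_date")
    dispensed = (fills["strength_mg"] * fills["quantity"] * fills["mme_factor"]).sum()
    assert values.sum() * 30 == pytest.approx(dispensed)


def test_summarize_dosing_examples():
    s = summarize_dosing(np.array([10.0, 0.0, 20.0]))
    assert (s.prsc_no, s.avg_mme, s.total_mme) == (2, 15.0, 30.0)
    z = summarize_dosing(np.zeros(5))
    assert (z.prsc_no, z.avg_mme, z.total_mme) == (0, 0.0, 0.0)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.lists(st.floats(min_value=0, max_value=500), min_size=1, max_size=108))
def test_summarize_dosing_matches_brute_force(values):
    s = summarize_dosing(np.array(values))
    positive = [v for v in values if v > 0]
    assert s.prsc_no == len(positive)
    assert s.total_mme == pytest.approx(sum(values))
    assert s.avg_mme == pytest.approx(sum(positive) / len(positive) if positive else 0.0)


def test_stimulant_covariates_examples(member):
    empty = stimulant_covariates(member, fills_frame([]))
    assert empty.cumulative_stimulant.tolist() == [0] * 6
    assert empty.stim_count_pre_index == 0

    one_pre = stimulant_covariates(
        member, fills_frame([(member.index_day - 100, "stimulant", "oral", 10, 30, 30, None)])
    )
    assert one_pre.cumulative_stimulant.tolist() == [1] * 6
    assert one_pre.stim_count_pre_index == 1

    stepped = stimulant_covariates(
        member,
        fills_frame([
            (member.index_day + 5, "stimulant", "oral", 10, 30, 30, None),
            (member.index_day + 65, "stimulant", "oral", 10, 30, 30, None),
        ]),
    )
    assert stepped.cumulative_stimulant.tolist() == [1, 1, 2, 2, 2, 2]


def test_covariate_series_monotone_and_consistent(member):
    rng = np.random.default_rng(8)
    rows = [(int(member.index_day + rng.integers(-365, 300)), "stimulant", "oral",
             10.0, 30.0, 30, None) for _ in range(20)]
    rows += [(member.index_day, "opioid", "oral", 5.0, 30.0, 30, 1.0),
             (member.index_day + 120, "opioid", "oral", 5.0, 30.0, 30, 1.0)]
    cov = stimulant_covariates(member, fills_frame(rows))
    assert (np.diff(cov.cumulative_stimulant) >= 0).all()
    assert cov.cumulative_stimulant[0] >= cov.stim_count_pre_index
    in_follow_up = sum(
        1 for r in rows
        if r[1] == "stimulant" and member.index_day - 365 <= r[0] < member.index_day + 180
    )
    assert cov.cumulative_stimulant[-1] == in_follow_up


def test_comorbidity_flag_windows(member):
    def dx(day, cat):
        return {"patient_id": "PX", "day": day, "code": "X", "category": cat}

    diagnoses = pd.DataFrame([
        dx(member.index_day - 10, "depression"),
        dx(member.index_day - 400, "anxiety"),   # outside the 365-day baseline
        dx(member.index_day + 100, "oud"),
        dx(member.index_day, "tud"),             # exactly on the index: post only
    ])
    flags = comorbidity_flags(member, diagnoses)
    assert flags["depression"] == {"pre_index": True, "post_index": False}
    assert flags["anxiety"] == {"pre_index": False, "post_index": False}
    assert flags["oud"] == {"pre_index": False, "post_index": True}
    assert flags["tud"] == {"pre_index": False, "post_index": True}
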