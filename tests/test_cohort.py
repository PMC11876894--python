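"""Tests of eligibility, index dates and attrition accounting."""

import pandas as pd
import pytest

from opitraj.cohort import (
    EligibilityRules,
    PatientBundle,
    build_cohort,
    check_eligibility,
    find_index_date,
    merge_enrollment_spans,
)
from opitraj.errors import DataQualityError
from opitraj.synthetic import EXCLUSION_REASONS, SimConfig, generate_population

from conftest import fills_frame

RULES = EligibilityRules()


def bundle(fills=None, spans=((0, 5000),), dx=None, birth=-365 * 30):
    rx = fills if fills is not None else fills_frame([])
    enrollment = pd.DataFrame(
        [{"patient_id": "PX", "start_day": s, "end_day": e} for s, e in spans]
    )
    diagnoses = (
        dx
        if dx is not None
        else pd.DataFrame(columns=["patient_id", "day", "code", "category"])
    )
    return PatientBundle(
        patient_id="PX", birth_offset_days=birth, sex="F", region="West",
        prescriptions=rx, enrollment=enrollment, diagnoses=diagnoses,
    )


@pytest.mark.parametrize(
    "rows,expected",
    [
        ([], None),  # no opioid fills at all
        ([(50, "opioid", "patch", 12, 10, 30, 2.4), (100, "opioid", "oral", 5, 30, 30, 1.5)], 100),
        ([(30, "opioid", "oral", 5, 30, 30, 1.5), (10, "opioid", "oral", 5, 30, 30, 1.5)], 10),
        ([(40, "stimulant", "oral", 10, 30, 30, None)], None),
    ],
)
def test_find_index_date(rows, expected):
    assert find_index_date(fills_frame(rows), RULES) == expected


def test_single_fill_fails_first_rule():
    b = bundle(fills_frame([(1000, "opioid", "oral", 5, 30, 30, 1.0)]))
    ok, rule, member = check_eligibility(b, RULES)
    assert (ok, rule, member) == (False, "min_opioid_fill_dates", None)


def test_follow_up_capped_at_nine_years():
    rows = [(400, "opioid", "oral", 5, 30, 30, 1.0), (430, "opioid", "oral", 5, 30, 30, 1.0)]
    b = bundle(fills_frame(rows), spans=((0, 4400),))
    ok, rule, member = check_eligibility(b, RULES)
    assert ok
    assert member.follow_up_end == 400 + 9 * 365  # 3285-day cap
    assert member.n_windows == 108


def test_follow_up_truncated_by_disenrollment():
    rows = [(400, "opioid", "oral", 5, 30, 30, 1.0), (430, "opioid", "oral", 5, 30, 30, 1.0)]
    b = bundle(fills_frame(rows), spans=((0, 1000),))
    ok, _, member = check_eligibility(b, RULES)
    assert ok and member.follow_up_end == 1000 and member.n_windows == 20


def test_prior_buprenorphine_excludes():
    rows = [
        (999, "buprenorphine", "oral", 2, 30, 30, None),
        (1000, "opioid", "oral", 5, 30, 30, 1.0),
        (1030, "opioid", "oral", 5, 30, 30, 1.0),
    ]
    ok, rule, _ = check_eligibility(bundle(fills_frame(rows)), RULES)
    assert (ok, rule) == (False, "excluded_prior_drug_class")


def test_cancer_any_time_before_index_excludes():
    rows = [(1000, "opioid", "oral", 5, 30, 30, 1.0), (1030, "opioid", "oral", 5, 30, 30, 1.0)]
    dx = pd.DataFrame(
        [{"patient_id": "PX", "day": 50, "code": "C", "category": "cancer"}]
    )
    ok, rule, _ = check_eligibility(bundle(fills_frame(rows), dx=dx), RULES)
    assert (ok, rule) == (False, "excluded_diagnosis")
    # baseline-window variant ignores ancient history
    baseline_rules = EligibilityRules(diagnosis_exclusion_window="baseline")
    ok, _, _ = check_eligibility(bundle(fills_frame(rows), dx=dx), baseline_rules)
    assert ok


def test_post_index_cancer_does_not_exclude():
    rows = [(1000, "opioid", "oral", 5, 30, 30, 1.0), (1030, "opioid", "oral", 5, 30, 30, 1.0)]
    dx = pd.DataFrame([{"patient_id": "PX", "day": 1500, "code": "C", "category": "cancer"}])
    ok, _, _ = check_eligibility(bundle(fills_frame(rows), dx=dx), RULES)
    assert ok


def test_minor_excluded_by_age():
    rows = [(1000, "opioid", "oral", 5, 30, 30, 1.0), (1030, "opioid", "oral", 5, 30, 30, 1.0)]
    ok, rule, _ = check_eligibility(
        bundle(fills_frame(rows), birth=1000 - 17 * 365), RULES
    )
    assert (ok, rule) == (False, "min_age_years")


def test_short_enrollment_rules():
    rows = [(1000, "opioid", "oral", 5, 30, 30, 1.0), (1030, "opioid", "oral", 5, 30, 30, 1.0)]
    ok, rule, _ = check_eligibility(bundle(fills_frame(rows), spans=((800, 5000),)), RULES)
    assert (ok, rule) == (False, "pre_index_enrollment")
    ok, rule, _ = check_eligibility(bundle(fills_frame(rows), spans=((0, 1040),)), RULES)
    assert (ok, rule) == (False, "post_index_enrollment")


def test_overlapping_enrollment_spans_error():
    spans = pd.DataFrame(
        [
            {"patient_id": "PX", "start_day": 0, "end_day": 100},
            {"patient_id": "PX", "start_day": 50, "end_day": 200},
        ]
    )
    with pytest.raises(DataQualityError):
        merge_enrollment_spans(spans)


def test_adjacent_spans_merge_with_grace():
    spans = pd.DataFrame(
        [
            {"patient_id": "PX", "start_day": 0, "end_day": 100},
            {"patient_id": "PX", "start_day": 101, "end_day": 200},
        ]
    )
    assert merge_enrollment_spans(spans, grace_days=0) == [(0, 200)]
    spans.loc[1, "start_day"] = 105
    assert merge_enrollment_spans(spans, grace_days=0) == [(0, 100), (105, 200)]
    assert merge_enrollment_spans(spans, grace_days=7) == [(0, 200)]


def test_attrition_conservation_and_no_exclusions(small_dataset):
    cohort, attrition = build_cohort(small_dataset)
    assert attrition["n_excluded"].sum() + len(cohort) == len(small_dataset.patients)
    assert (attrition["n_excluded"] == 0).all()
    assert len(cohort) == len(small_dataset.patients)
    assert attrition["n_remaining"].is_monotonic_decreasing


def test_attrition_matches_disjoint_injection_counts():
    fracs = {r: 0.04 for r in EXCLUSION_REASONS}
    ds = generate_population(
        SimConfig(n_patients=300, seed=21, exclusion_fractions=fracs,
                  exclusion_assignment="disjoint")
    )
    cohort, attrition = build_cohort(ds)
    from opitraj.cohort import REASON_TO_RULE

    expected = {rule: 0 for rule in attrition["rule"]}
    for reasons in ds.ground_truth.injected_exclusions.values():
        if reasons:
            expected[REASON_TO_RULE[reasons[0]]] += 1
    got = dict(zip(attrition["rule"], attrition["n_excluded"]))
    assert got == expected


def test_cohort_rebuild_is_idempotent(small_dataset):
    cohort, _ = build_cohort(small_dataset)
    keep = set(cohort["patient_id"])
    sub = type(small_dataset)(
        patients=small_dataset.patients[small_dataset.patients["patient_id"].isin(keep)],
        enrollment=small_dataset.enrollment[small_dataset.enrollment["patient_id"].isin(keep)],
        prescriptions=small_dataset.prescriptions[
            small_dataset.prescriptions["patient_id"].isin(keep)
        ],
        diagnoses=small_dataset.diagnoses[small_dataset.diagnoses["patient_id"].isin(keep)],
        ground_truth=small_dataset.ground_truth,
    )
    cohort2, _ = build_cohort(sub)
    pd.testing.assert_frame_equal(
        cohort.reset_index(drop=True), cohort2.reset_index(drop=True)
    )


def test_empty_dataset_empty_cohort():
    ds = generate_population(SimConfig(n_patients=0))
    cohort, attrition = build_cohort(ds)
    assert len(cohort) == 0
    assert (attrition["n_excluded"] == 0).all()
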