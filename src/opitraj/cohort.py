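"""New-user cohort construction: index dates, eligibility rules, attrition.

The eligibility algorithm reproduces the standard pharmacoepidemiologic
new-user design for an opioid cohort:

1. at least two oral-opioid fills on distinct service dates (the index date is
   the first such fill);
2. one continuous enrollment span covering the 365 days before the index;
3. the same span covering the 60 days after the index;
4. age >= 18 years at the index date;
5. no excluded diagnosis category (cancer) at any time on or before the index;
6. no excluded prior drug class (buprenorphine) filled strictly before the
   index.

Rules are evaluated in this fixed order and the first failure is reported,
which makes the attrition accounting an exact partition of the input
population.  Follow-up ends at the earlier of nine years (9 x 365 days) after
the index or the end of the enrollment span containing the index; the modelled
horizon is the number of complete 30-day windows, capped at 108.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import DataQualityError

RULE_ORDER = (
    "min_opioid_fill_dates",
    "pre_index_enrollment",
    "post_index_enrollment",
    "min_age_years",
    "excluded_diagnosis",
    "excluded_prior_drug_class",
)

#: generator injection reason -> the eligibility rule it trips
REASON_TO_RULE = {
    "single_fill": "min_opioid_fill_dates",
    "short_pre_enrollment": "pre_index_enrollment",
    "short_post_enrollment": "post_index_enrollment",
    "minor": "min_age_years",
    "cancer": "excluded_diagnosis",
    "prior_buprenorphine": "excluded_prior_drug_class",
}

COHORT_COLUMNS = [
    "patient_id",
    "index_day",
    "follow_up_end",
    "n_windows",
    "age_at_index",
    "sex",
    "region",
]


@dataclass(frozen=True)
class EligibilityRules:
    min_opioid_fill_dates: int = 2
    pre_index_enrollment_days: int = 365
    post_index_enrollment_days: int = 60
    min_age_years: int = 18
    max_follow_up_days: int = 9 * 365
    allowed_routes: frozenset = frozenset({"oral"})
    excluded_prior_drug_classes: frozenset = frozenset({"buprenorphine"})
    excluded_diagnosis_categories: frozenset = frozenset({"cancer"})
    enrollment_gap_grace_days: int = 0
    # "all_history" reproduces the unwindowed reading of the cancer rule;
    # "baseline" restricts it to the pre-index enrollment window.
    diagnosis_exclusion_window: str = "all_history"

    def __post_init__(self):
        if self.min_opioid_fill_dates < 1:
            raise ValueError("min_opioid_fill_dates must be >= 1")
        if min(self.pre_index_enrollment_days, self.post_index_enrollment_days,
               self.max_follow_up_days) <= 0:
            raise ValueError("enrollment/follow-up durations must be positive")
        if not self.allowed_routes:
            raise ValueError("allowed_routes must be nonempty")
        if self.diagnosis_exclusion_window not in ("all_history", "baseline"):
            raise ValueError("diagnosis_exclusion_window must be 'all_history' or 'baseline'")


@dataclass
class CohortMember:
    patient_id: str
    index_day: int
    follow_up_end: int
    n_windows: int
    age_at_index: int
    sex: str
    region: str


@dataclass
class PatientBundle:
    """All rows for one patient, the unit the eligibility check operates on."""

    patient_id: str
    birth_offset_days: int
    sex: str
    region: str
    prescriptions: pd.DataFrame
    enrollment: pd.DataFrame
    diagnoses: pd.DataFrame


def merge_enrollment_spans(enrollment: pd.DataFrame, grace_days: int = 0) -> list[tuple[int, int]]:
    """Merge adjacent spans (gap <= grace); overlapping spans are a data error."""
    spans = sorted(zip(enrollment["start_day"].astype(int), enrollment["end_day"].astype(int)))
    merged: list[list[int]] = []
    for s, e in spans:
        if e < s:
            raise DataQualityError(f"enrollment span with end {e} before start {s}")
        if merged and s <= merged[-1][1]:
            raise DataQualityError(f"overlapping enrollment spans at day {s}")
        if merged and s - merged[-1][1] - 1 <= grace_days:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def find_index_date(prescriptions: pd.DataFrame, rules: EligibilityRules) -> int | None:
    """Earliest fill date of an opioid with an allowed route; None if absent."""
    m = (prescriptions["drug_class"] == "opioid") & prescriptions["route"].isin(rules.allowed_routes)
    if not m.any():
        return None
    return int(prescriptions.loc[m, "day"].min())


def check_eligibility(
    bundle: PatientBundle, rules: EligibilityRules
) -> tuple[bool, str | None, CohortMember | None]:
    """Evaluate the rules in fixed order; report the first failure."""
    rx = bundle.prescriptions
    opioid = rx[(rx["drug_class"] == "opioid") & rx["route"].isin(rules.allowed_routes)]

    index_day = find_index_date(rx, rules)
    if index_day is None or opioid["day"].nunique() < rules.min_opioid_fill_dates:
        return False, "min_opioid_fill_dates", None

    spans = merge_enrollment_spans(bundle.enrollment, rules.enrollment_gap_grace_days)
    span = next(((s, e) for s, e in spans if s <= index_day <= e), None)
    if span is None or span[0] > index_day - rules.pre_index_enrollment_days:
        return False, "pre_index_enrollment", None
    if span[1] < index_day + rules.post_index_enrollment_days:
        return False, "post_index_enrollment", None

    age = (index_day - int(bundle.birth_offset_days)) // 365
    if age < rules.min_age_years:
        return False, "min_age_years", None

    dx = bundle.diagnoses
    if len(dx):
        excl = dx["category"].isin(rules.excluded_diagnosis_categories) & (dx["day"] <= index_day)
        if rules.diagnosis_exclusion_window == "baseline":
            excl &= dx["day"] >= index_day - rules.pre_index_enrollment_days
        if excl.any():
            return False, "excluded_diagnosis", None

    prior = rx[rx["drug_class"].isin(rules.excluded_prior_drug_classes) & (rx["day"] < index_day)]
    if len(prior):
        return False, "excluded_prior_drug_class", None

    follow_up_end = min(index_day + rules.max_follow_up_days, span[1])
    n_windows = min((follow_up_end - index_day) // 30, 108)
    member = CohortMember(
        patient_id=bundle.patient_id,
        index_day=index_day,
        follow_up_end=int(follow_up_end),
        n_windows=int(n_windows),
        age_at_index=int(age),
        sex=bundle.sex,
        region=bundle.region,
    )
    return True, None, member


def iter_bundles(dataset) -> "list[PatientBundle]":
    """Split the four tables into per-patient bundles (sorted by patient id)."""
    tabs = dataset.tables() if hasattr(dataset, "tables") else dataset
    groups = {
        name: dict(tuple(tabs[name].groupby("patient_id", sort=False)))
        for name in ("prescriptions", "enrollment", "diagnoses")
    }
    empties = {name: tabs[name].iloc[0:0] for name in groups}
    bundles = []
    for _, row in tabs["patients"].sort_values("patient_id").iterrows():
        pid = row["patient_id"]
        bundles.append(
            PatientBundle(
                patient_id=pid,
                birth_offset_days=int(row["birth_offset_days"]),
                sex=row["sex"],
                region=row["region"],
                prescriptions=groups["prescriptions"].get(pid, empties["prescriptions"]),
                enrollment=groups["enrollment"].get(pid, empties["enrollment"]),
                diagnoses=groups["diagnoses"].get(pid, empties["diagnoses"]),
            )
        )
    return bundles


def build_cohort(
    dataset, rules: EligibilityRules | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply eligibility to every patient; return (cohort table, attrition report).

    The attrition report has one row per rule, in evaluation order, with the
    count excluded at that rule and the population remaining after it, so that
    input population = final cohort size + sum of exclusions.
    """
    rules = rules or EligibilityRules()
    members: list[CohortMember] = []
    excluded = {rule: 0 for rule in RULE_ORDER}
    for bundle in iter_bundles(dataset):
        try:
            ok, failed, member = check_eligibility(bundle, rules)
        except DataQualityError as err:
            raise DataQualityError(f"patient {bundle.patient_id}: {err}") from err
        if ok:
            members.append(member)
        else:
            excluded[failed] += 1

    cohort = pd.DataFrame([vars(m) for m in members], columns=COHORT_COLUMNS)
    remaining = len(cohort) + sum(excluded.values())
    rows = []
    for rule in RULE_ORDER:
        remaining -= excluded[rule]
        rows.append((rule, excluded[rule], remaining))
    attrition = pd.DataFrame(rows, columns=["rule", "n_excluded", "n_remaining"])
    return cohort, attrition
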