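"""Shared fixtures: small claims datasets and recovery-study conditions."""

import numpy as np
import pandas as pd
import pytest

from opitraj.catalog import Drug
from opitraj.cohort import CohortMember
from opitraj.synthetic import SimConfig, generate_population

# Three-group truth used for estimator recovery studies: a flat low-dose
# group, a decreasing and an increasing group, intercepts separated by at
# least 3 sigma on the log(1+MME) scale.
RECOVERY_TRUTH = dict(
    mixture=(0.5, 0.3, 0.2),
    poly_coeffs=((1.0, 0.0), (2.5, -2.0), (4.0, 3.0)),
    sigma=0.3,
)

# Claims-level conditions with a stimulant effect concentrated in the
# increasing group (group 2): alpha = 0.5 per prescription, and stimulant
# prescribing 7.5x more frequent than in the other groups.
STIM_EFFECT_CONFIG = dict(
    mixture_proportions=(0.4, 0.3, 0.3),
    poly_coeffs=((1.0, 0.0), (2.5, -2.0), (2.5, 3.0)),
    covariate_effects=(0.0, 0.0, 0.5),
    sigma=0.3,
    stimulant_rates=(0.02, 0.02, 0.15),
    max_months=24,
)


@pytest.fixture(scope="session")
def small_dataset():
    """300 patients, no injected exclusions, deterministic."""
    return generate_population(SimConfig(n_patients=300, seed=7))


@pytest.fixture
def member():
    """A cohort member with 6 windows of follow-up starting at day 1000."""
    return CohortMember(
        patient_id="PX",
        index_day=1000,
        follow_up_end=1000 + 185,
        n_windows=6,
        age_at_index=40,
        sex="F",
        region="South",
    )


@pytest.fixture
def opioid_catalog_row():
    return Drug("OPI-T", "opioid", "oral", 5.0, 1.0)


FILL_COLUMNS = [
    "patient_id", "day", "drug_id", "drug_class", "route",
    "strength_mg", "quantity", "days_supply", "mme_factor",
]


def fills_frame(rows):
    """Build a prescriptions frame from (day, drug_class, route, strength, qty, supply, factor)."""
    if not rows:
        return pd.DataFrame(columns=FILL_COLUMNS)
    return pd.DataFrame(
        [
            {
                "patient_id": "PX",
                "day": day,
                "drug_id": f"D{k}",
                "drug_class": cls,
                "route": route,
                "strength_mg": s,
                "quantity": q,
                "days_supply": ds,
                "mme_factor": f,
            }
            for k, (day, cls, route, s, q, ds, f) in enumerate(rows)
        ]
    )


def day_level_dose_oracle(member, fills, mode):
    """Independent brute-force oracle: accumulate MME day by day.

    dispense_date mode credits the fill's full dispensed MME to its fill day;
    supply_spread spreads the daily dose over the supply interval.
    """
    horizon = member.n_windows * 30
    daily = np.zeros(horizon)
    for _, r in fills.iterrows():
        if r["drug_class"] != "opioid" or r["route"] != "oral":
            continue
        if r["day"] < member.index_day or r["day"] > member.follow_up_end:
            continue
        total = r["strength_mg"] * r["quantity"] * r["mme_factor"]
        start = int(r["day"] - member.index_day)
        if mode == "dispense_date":
            if start < horizon:
                daily[start] += total
        else:
            per_day = total / r["days_supply"]
            for d in range(start, min(start + int(r["days_supply"]), horizon)):
                daily[d] += per_day
    return np.array([daily[30 * w : 30 * (w + 1)].sum() / 30 for w in range(member.n_windows)])
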