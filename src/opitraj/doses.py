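"""Morphine-milligram-equivalent dose series, stimulant covariates, comorbidity flags.

The daily MME of one fill is

    strength per unit x (quantity / days supplied) x MME conversion factor,

and the per-patient dose series is the mean daily MME over consecutive,
non-overlapping 30-day windows from the index date: in the default
``dispense_date`` mode window *w* holds the total MME dispensed on days
``[index + 30w, index + 30(w+1))`` divided by 30; the ``supply_spread``
sensitivity mode instead spreads each fill's daily dose over its days-supply
interval before windowing.  A partial terminal window is dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError
from .synthetic import COMORBIDITY_CATEGORIES

logger = logging.getLogger(__name__)

WINDOW_DAYS = 30
MODES = ("dispense_date", "supply_spread")


@dataclass
class DoseSummary:
    """Per-patient dosing summary over the follow-up windows."""

    prsc_no: int  # number of windows with any opioid dispensing
    avg_mme: float  # mean of positive-window values (mg/day); 0 if none
    total_mme: float  # sum of all window values


@dataclass
class CovariateSeries:
    patient_id: str
    cumulative_stimulant: np.ndarray  # one entry per window, non-decreasing
    stim_count_pre_index: int  # fills in [index-365, index)
    stim_count_between: int  # fills between first and last opioid fill dates


def mme_daily_dose(record) -> float:
    """Daily MME (mg/day) of a single opioid fill.

    ``record`` is any mapping/row with drug_class, strength_mg, quantity,
    days_supply and mme_factor fields.
    """
    if record["drug_class"] != "opioid":
        raise DomainError(f"MME is defined for opioids, got {record['drug_class']!r}")
    strength, qty, days, factor = (
        float(record["strength_mg"]),
        float(record["quantity"]),
        float(record["days_supply"]),
        float(record["mme_factor"]),
    )
    if strength <= 0 or qty <= 0 or days <= 0 or factor <= 0:
        raise DomainError("strength, quantity, days_supply and mme_factor must be positive")
    return strength * (qty / days) * factor


def attach_mme_factors(prescriptions: pd.DataFrame, factors: dict[str, float]) -> pd.DataFrame:
    """Add an ``mme_factor`` column from a drug_id→factor catalog map."""
    out = prescriptions.copy()
    out["mme_factor"] = out["drug_id"].map(factors)
    opioid_missing = (out["drug_class"] == "opioid") & out["mme_factor"].isna()
    if opioid_missing.any():
        missing = sorted(out.loc[opioid_missing, "drug_id"].unique())
        raise DomainError(f"no MME conversion factor for opioid drug ids: {missing}")
    return out


def _eligible_opioid_fills(member, fills: pd.DataFrame, allowed_routes=("oral",)) -> pd.DataFrame:
    fills = fills[(fills["drug_class"] == "opioid") & fills["route"].isin(allowed_routes)]
    pre = fills["day"] < member.index_day
    if pre.any():
        logger.warning(
            "patient %s: %d opioid fill(s) before the index date ignored",
            member.patient_id, int(pre.sum()),
        )
    return fills[(fills["day"] >= member.index_day) & (fills["day"] <= member.follow_up_end)]


def monthly_dose_series(member, fills: pd.DataFrame, mode: str = "dispense_date") -> np.ndarray:
    """Mean daily MME per complete 30-day window from the index date.

    ``member`` needs patient_id/index_day/follow_up_end/n_windows; ``fills``
    must carry an ``mme_factor`` column (see :func:`attach_mme_factors`).
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    T = int(member.n_windows)
    values = np.zeros(T)
    fills = _eligible_opioid_fills(member, fills)
    if not len(fills) or T == 0:
        return values
    offset = fills["day"].to_numpy() - member.index_day
    total = (fills["strength_mg"] * fills["quantity"] * fills["mme_factor"]).to_numpy(float)
    if mode == "dispense_date":
        w = offset // WINDOW_DAYS
        keep = w < T
        np.add.at(values, w[keep].astype(int), total[keep] / WINDOW_DAYS)
    else:
        daily = total / fills["days_supply"].to_numpy(float)
        horizon = T * WINDOW_DAYS
        for start, days, dose in zip(offset, fills["days_supply"].to_numpy(int), daily):
            lo, hi = start, min(start + days, horizon)
            if hi <= lo:
                continue
            w_lo, w_hi = lo // WINDOW_DAYS, (hi - 1) // WINDOW_DAYS
            for w in range(w_lo, w_hi + 1):
                cov = min(hi, (w + 1) * WINDOW_DAYS) - max(lo, w * WINDOW_DAYS)
                values[w] += dose * cov / WINDOW_DAYS
    return values


def summarize_dosing(values: np.ndarray) -> DoseSummary:
    values = np.asarray(values, float)
    pos = values > 0
    n = int(pos.sum())
    return DoseSummary(
        prsc_no=n,
        avg_mme=float(values[pos].mean()) if n else 0.0,
        total_mme=float(values.sum()),
    )


def stimulant_covariates(member, fills: pd.DataFrame) -> CovariateSeries:
    """Cumulative stimulant count per window, from one year pre-index onward."""
    T = int(member.n_windows)
    stim_days = np.sort(
        fills.loc[fills["drug_class"] == "stimulant", "day"].to_numpy(int)
    )
    lo = member.index_day - 365
    stim_days = stim_days[stim_days >= lo]
    ends = member.index_day + WINDOW_DAYS * (np.arange(T) + 1)
    cumulative = np.searchsorted(stim_days, ends, side="left").astype(int)
    pre = int(np.searchsorted(stim_days, member.index_day, side="left"))

    op = fills[(fills["drug_class"] == "opioid") & (fills["day"] >= member.index_day)
               & (fills["day"] <= member.follow_up_end)]
    if len(op):
        first, last = int(op["day"].min()), int(op["day"].max())
        all_stim = np.sort(fills.loc[fills["drug_class"] == "stimulant", "day"].to_numpy(int))
        between = int(np.searchsorted(all_stim, last, side="right")
                      - np.searchsorted(all_stim, first, side="left"))
    else:
        between = 0
    return CovariateSeries(
        patient_id=member.patient_id,
        cumulative_stimulant=cumulative,
        stim_count_pre_index=pre,
        stim_count_between=between,
    )


def comorbidity_flags(
    member, diagnoses: pd.DataFrame, categories=COMORBIDITY_CATEGORIES
) -> dict[str, dict[str, bool]]:
    """Pre-index (365-day baseline) and post-index flags per category.

    A diagnosis exactly on the index date counts as post-index only.
    """
    known = set(categories)
    unknown = set(diagnoses["category"]) - known
    if unknown:
        logger.info("ignoring unknown diagnosis categories: %s", sorted(unknown))
    flags = {cat: {"pre_index": False, "post_index": False} for cat in categories}
    for _, row in diagnoses.iterrows():
        cat = row["category"]
        if cat not in known:
            continue
        day = int(row["day"])
        if member.index_day - 365 <= day < member.index_day:
            flags[cat]["pre_index"] = True
        elif day >= member.index_day:
            flags[cat]["post_index"] = True
    return flags


# ---------------------------------------------------------------------------
# Cohort-level builders (vector form consumed by the trajectory model)
# ---------------------------------------------------------------------------

def build_dose_matrix(
    cohort: pd.DataFrame,
    prescriptions: pd.DataFrame,
    factors: dict[str, float],
    mode: str = "dispense_date",
) -> tuple[np.ndarray, list[str]]:
    """Stack per-patient dose series into an (n, T_max) matrix, NaN-padded."""
    fills = attach_mme_factors(prescriptions, factors)
    groups = dict(tuple(fills.groupby("patient_id", sort=False)))
    empty = fills.iloc[0:0]
    T_max = int(cohort["n_windows"].max()) if len(cohort) else 0
    X = np.full((len(cohort), T_max), np.nan)
    ids = []
    for i, member in enumerate(cohort.itertuples(index=False)):
        series = monthly_dose_series(member, groups.get(member.patient_id, empty), mode)
        X[i, : len(series)] = series
        ids.append(member.patient_id)
    return X, ids


def build_covariate_matrix(
    cohort: pd.DataFrame, prescriptions: pd.DataFrame
) -> tuple[np.ndarray, pd.DataFrame]:
    """Stack cumulative stimulant counts into (n, T_max); also return summary counts."""
    groups = dict(tuple(prescriptions.groupby("patient_id", sort=False)))
    empty = prescriptions.iloc[0:0]
    T_max = int(cohort["n_windows"].max()) if len(cohort) else 0
    C = np.full((len(cohort), T_max), np.nan)
    rows = []
    for i, member in enumerate(cohort.itertuples(index=False)):
        cov = stimulant_covariates(member, groups.get(member.patient_id, empty))
        C[i, : len(cov.cumulative_stimulant)] = cov.cumulative_stimulant
        end = int(cov.cumulative_stimulant[-1]) if len(cov.cumulative_stimulant) else cov.stim_count_pre_index
        rows.append((member.patient_id, cov.stim_count_pre_index, cov.stim_count_between, end))
    summary = pd.DataFrame(
        rows, columns=["patient_id", "stim_count_pre_index", "stim_count_between", "stim_tv_summary"]
    )
    return C, summary


def build_comorbidity_table(cohort: pd.DataFrame, diagnoses: pd.DataFrame) -> pd.DataFrame:
    """Wide per-patient table of pre-/post-index comorbidity flags (0/1)."""
    groups = dict(tuple(diagnoses.groupby("patient_id", sort=False)))
    empty = diagnoses.iloc[0:0]
    rows = []
    for member in cohort.itertuples(index=False):
        flags = comorbidity_flags(member, groups.get(member.patient_id, empty))
        row = {"patient_id": member.patient_id}
        for cat, f in flags.items():
            row[f"pre_{cat}"] = int(f["pre_index"])
            row[f"post_{cat}"] = int(f["post_index"])
        rows.append(row)
    cols = ["patient_id"] + [f"{w}_{c}" for c in COMORBIDITY_CATEGORIES for w in ("pre", "post")]
    return pd.DataFrame(rows, columns=cols if rows else cols)
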