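"""Synthetic longitudinal pharmacy-claims generator with known trajectory structure.

The generator emulates the structure of commercial-claims extracts (per-patient
enrollment spans, dated pharmacy fills with strength/quantity/days-supply,
dated diagnosis categories, demographics) while driving each patient's opioid
dose dynamics from a latent trajectory group:

    y*_w = poly_g(t_w) + alpha_g * cumstim_w + eps,   eps ~ N(0, sigma),
    target mean daily MME in window w = expm1(max(y*_w, 0)),

with t_w = w / time_scale and cumstim_w the cumulative stimulant fill count
from one year pre-index through window w.  Fills are emitted so the dispensed
MME total of each 30-day window reproduces the target up to catalog
quantization; windows whose target rounds below one dispensable unit stay
empty (zero-dose months).  Stimulant fills are Poisson per window with a
group-specific rate, so stimulant exposure is informative about group
membership — the ground truth against which the cohort, dose, trajectory and
association stages are all testable.

Every patient is generated from an RNG stream keyed by ``(seed, patient
index)``, so output is deterministic and per-patient rows do not depend on
``n_patients``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io
from .catalog import Drug, default_drug_catalog
from .errors import ConfigurationError

EXCLUSION_REASONS = (
    "minor",
    "cancer",
    "prior_buprenorphine",
    "short_pre_enrollment",
    "short_post_enrollment",
    "single_fill",
)

REGIONS = ("Northeast", "North Central", "South", "West")

COMORBIDITY_CATEGORIES = (
    "depression",
    "anxiety",
    "bipolar",
    "schizophrenia_psychoses",
    "chronic_acute_pain",
    "adhd",
    "opioid_overdose",
    "oud",
    "tud",
    "aud",
    "cud",
    "other_sud",
    "cancer",
)

# Baseline (pre-index, 1y) and post-index prevalences typical of a commercial
# opioid new-user cohort; cancer is zero because cancer is an exclusion.
DEFAULT_COMORBIDITY_PREVALENCE: dict[str, tuple[float, float]] = {
    "depression": (0.097, 0.204),
    "anxiety": (0.122, 0.304),
    "bipolar": (0.019, 0.049),
    "schizophrenia_psychoses": (0.003, 0.007),
    "chronic_acute_pain": (0.577, 0.803),
    "adhd": (0.026, 0.047),
    "opioid_overdose": (0.0003, 0.002),
    "oud": (0.002, 0.011),
    "tud": (0.062, 0.129),
    "aud": (0.012, 0.031),
    "cud": (0.003, 0.012),
    "other_sud": (0.004, 0.015),
    "cancer": (0.0, 0.0),
}

# Default latent structure: five groups on the log(1+MME) scale over t in
# [0, 1] (t = window/107) — a dominant very-low group, decreasing and
# increasing low-dose groups, an increasing moderate group and a sustained
# high-dose group, with stimulant prescribing concentrated in the
# increasing/high groups.
DEFAULT_MIXTURE = (0.775, 0.102, 0.085, 0.024, 0.014)
DEFAULT_POLY_COEFFS = (
    (1.70, -0.25, 0.0),
    (2.76, -2.40, 0.60),
    (2.72, 1.00, -0.30),
    (3.83, 0.90, -0.20),
    (4.67, 0.20, -0.20),
)
DEFAULT_COVARIATE_EFFECTS = (0.0, 0.0, 0.10, 0.10, 0.0)
DEFAULT_STIMULANT_RATES = (0.005, 0.005, 0.015, 0.018, 0.018)


@dataclass
class SimConfig:
    """Generator configuration; defaults are the package's reference conditions."""

    n_patients: int = 1000
    seed: int = 0
    mixture_proportions: Sequence[float] = DEFAULT_MIXTURE
    poly_coeffs: Sequence[Sequence[float]] = DEFAULT_POLY_COEFFS
    covariate_effects: Sequence[float] = DEFAULT_COVARIATE_EFFECTS
    sigma: float = 0.35
    stimulant_rates: Sequence[float] = DEFAULT_STIMULANT_RATES
    exclusion_fractions: Mapping[str, float] = field(
        default_factory=lambda: {r: 0.0 for r in EXCLUSION_REASONS}
    )
    exclusion_assignment: str = "independent"  # or "disjoint"
    max_months: int = 108
    drug_catalog: Sequence[Drug] = field(default_factory=default_drug_catalog)
    region_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            "Northeast": 0.128,
            "North Central": 0.202,
            "South": 0.497,
            "West": 0.162,
        }
    )
    sex_probs: Mapping[str, float] = field(default_factory=lambda: {"F": 0.57, "M": 0.43})
    age_mean: float = 44.0
    age_sd: float = 13.0
    age_min: int = 18
    age_max: int = 80
    comorbidity_prevalence: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_COMORBIDITY_PREVALENCE)
    )
    pre_enrollment_days: int = 400
    follow_up_mean_days: float = 1277.0
    other_fill_rate: float = 0.01
    time_scale: float = 107.0

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        if self.n_patients < 0:
            raise ConfigurationError("n_patients must be >= 0")
        mix = np.asarray(self.mixture_proportions, dtype=float)
        if mix.ndim != 1 or mix.size < 1 or np.any(mix <= 0):
            raise ConfigurationError("mixture_proportions must be strictly positive")
        if not math.isclose(mix.sum(), 1.0, abs_tol=1e-8):
            raise ConfigurationError("mixture_proportions must sum to 1")
        k = mix.size
        if len(self.poly_coeffs) != k:
            raise ConfigurationError("poly_coeffs must have one coefficient vector per group")
        if len(self.covariate_effects) != k:
            raise ConfigurationError("covariate_effects must have one entry per group")
        if len(self.stimulant_rates) != k or np.any(np.asarray(self.stimulant_rates) < 0):
            raise ConfigurationError("stimulant_rates must be non-negative, one per group")
        if not self.sigma >= 0:
            raise ConfigurationError("sigma must be >= 0")
        if not 1 <= self.max_months <= 108:
            raise ConfigurationError("max_months must be in [1, 108]")
        for reason, frac in self.exclusion_fractions.items():
            if reason not in EXCLUSION_REASONS:
                raise ConfigurationError(f"exclusion_fractions: unknown reason {reason!r}")
            if not 0 <= frac <= 1:
                raise ConfigurationError(f"exclusion_fractions[{reason}] must be in [0, 1]")
        if self.exclusion_assignment not in ("independent", "disjoint"):
            raise ConfigurationError("exclusion_assignment must be 'independent' or 'disjoint'")
        if self.exclusion_assignment == "disjoint" and sum(self.exclusion_fractions.values()) > 1:
            raise ConfigurationError("exclusion_fractions must sum to <= 1 in disjoint mode")
        for d in self.drug_catalog:
            d.validate()
        if not any(d.drug_class == "opioid" and d.route == "oral" for d in self.drug_catalog):
            raise ConfigurationError("drug_catalog must contain at least one oral opioid")
        for name in ("region_probs", "sex_probs"):
            probs = np.asarray(list(getattr(self, name).values()), dtype=float)
            if np.any(probs < 0) or probs.sum() <= 0:
                raise ConfigurationError(f"{name} must be non-negative with positive sum")
        for cat, (p0, p1) in self.comorbidity_prevalence.items():
            if not (0 <= p0 <= 1 and 0 <= p1 <= 1):
                raise ConfigurationError(f"comorbidity_prevalence[{cat}] must be in [0, 1]")
        if self.age_min < 18:
            raise ConfigurationError("age_min must be >= 18 (minors enter only via injection)")

    @property
    def n_groups(self) -> int:
        return len(self.mixture_proportions)


@dataclass
class GroundTruth:
    """The latent structure the generator used; the oracle for downstream tests."""

    n_groups: int
    mixture_proportions: tuple[float, ...]
    poly_coeffs: tuple[tuple[float, ...], ...]
    covariate_effect: tuple[float, ...]
    sigma: float
    stimulant_rate: tuple[float, ...]
    group_labels: dict[str, int]  # patient_id -> true group
    injected_exclusions: dict[str, list[str]]  # patient_id -> injected reasons
    index_days: dict[str, int]  # patient_id -> intended index day

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            n_groups=int(d["n_groups"]),
            mixture_proportions=tuple(d["mixture_proportions"]),
            poly_coeffs=tuple(tuple(c) for c in d["poly_coeffs"]),
            covariate_effect=tuple(d["covariate_effect"]),
            sigma=float(d["sigma"]),
            stimulant_rate=tuple(d["stimulant_rate"]),
            group_labels={k: int(v) for k, v in d["group_labels"].items()},
            injected_exclusions={k: list(v) for k, v in d["injected_exclusions"].items()},
            index_days={k: int(v) for k, v in d["index_days"].items()},
        )


@dataclass
class SyntheticDataset:
    patients: pd.DataFrame
    enrollment: pd.DataFrame
    prescriptions: pd.DataFrame
    diagnoses: pd.DataFrame
    ground_truth: GroundTruth

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "patients": self.patients,
            "enrollment": self.enrollment,
            "prescriptions": self.prescriptions,
            "diagnoses": self.diagnoses,
        }

    def validate(self) -> None:
        """Referential and containment invariants of a well-formed dataset."""
        from .errors import DataQualityError

        pids = set(self.patients["patient_id"])
        for name in ("enrollment", "prescriptions", "diagnoses"):
            tab = getattr(self, name)
            extra = set(tab["patient_id"]) - pids
            if extra:
                raise DataQualityError(f"{name} references unknown patients: {sorted(extra)[:5]}")
        spans = {
            pid: list(zip(grp["start_day"], grp["end_day"]))
            for pid, grp in self.enrollment.groupby("patient_id")
        }
        for _, row in self.prescriptions.iterrows():
            ok = any(s <= row["day"] <= e for s, e in spans.get(row["patient_id"], ()))
            if not ok:
                raise DataQualityError(
                    f"prescription for {row['patient_id']} on day {row['day']} outside enrollment"
                )


def _draw_reasons(rng, fractions: Mapping[str, float], mode: str) -> list[str]:
    if mode == "independent":
        return [r for r in EXCLUSION_REASONS if fractions.get(r, 0.0) > 0 and rng.random() < fractions[r]]
    u = rng.random()
    acc = 0.0
    for r in EXCLUSION_REASONS:
        acc += fractions.get(r, 0.0)
        if u < acc:
            return [r]
    return []


def generate_population(config: SimConfig) -> SyntheticDataset:
    """Generate a synthetic claims dataset with known latent-group structure."""
    config.validate()
    mix = np.asarray(config.mixture_proportions, dtype=float)
    mix = mix / mix.sum()
    regions = list(config.region_probs)
    region_p = np.asarray(list(config.region_probs.values()), float)
    region_p = region_p / region_p.sum()
    sexes = list(config.sex_probs)
    sex_p = np.asarray(list(config.sex_probs.values()), float)
    sex_p = sex_p / sex_p.sum()
    oral_opioids = [d for d in config.drug_catalog if d.drug_class == "opioid" and d.route == "oral"]
    stimulants = [d for d in config.drug_catalog if d.drug_class == "stimulant"]
    bupes = [d for d in config.drug_catalog if d.drug_class == "buprenorphine"]
    others = [d for d in config.drug_catalog if d.drug_class == "other"]

    pat_rows, enr_rows, rx_rows, dx_rows = [], [], [], []
    labels: dict[str, int] = {}
    injected: dict[str, list[str]] = {}
    index_days: dict[str, int] = {}

    for i in range(config.n_patients):
        rng = np.random.default_rng([config.seed, i])
        pid = f"P{i:07d}"
        g = int(rng.choice(mix.size, p=mix))
        reasons = _draw_reasons(rng, config.exclusion_fractions, config.exclusion_assignment)

        age = int(np.clip(round(rng.normal(config.age_mean, config.age_sd)),
                          config.age_min, config.age_max))
        if "minor" in reasons:
            age = int(rng.integers(10, 18))
        sex = sexes[int(rng.choice(len(sexes), p=sex_p))]
        region = regions[int(rng.choice(len(regions), p=region_p))]

        index_day = int(config.pre_enrollment_days + rng.integers(0, 365))
        birth_offset = index_day - (age * 365 + int(rng.integers(0, 365)))

        # enrollment may not outlive the emitted trajectory horizon: the last
        # (partial) window ends within max_months * 30 + 29 days of the index
        post_days = int(np.clip(rng.gamma(2.0, config.follow_up_mean_days / 2.0),
                                60, config.max_months * 30 + 29))
        enroll_start = index_day - config.pre_enrollment_days
        enroll_end = index_day + post_days
        if "short_pre_enrollment" in reasons:
            enroll_start = index_day - int(rng.integers(30, 365))
        if "short_post_enrollment" in reasons:
            enroll_end = index_day + int(rng.integers(30, 60))
        n_win = min(config.max_months, (min(enroll_end, index_day + 3285) - index_day) // 30)

        # --- stimulant fills (group-dependent rate) ------------------------
        rate = float(config.stimulant_rates[g])
        pre_lo = max(enroll_start, index_day - 365)
        n_pre_stim = rng.poisson(rate * (index_day - pre_lo) / 30.0) if stimulants else 0
        stim_days: list[int] = sorted(
            int(d) for d in rng.integers(pre_lo, index_day, size=n_pre_stim)
        )
        post_stim_days: list[int] = []
        for w in range(n_win):
            kw = rng.poisson(rate) if stimulants else 0
            lo = index_day + 30 * w
            post_stim_days.extend(int(d) for d in np.sort(rng.integers(lo, lo + 30, size=kw)))
        all_stim_days = stim_days + post_stim_days

        # --- opioid fills driven by the latent trajectory ------------------
        my_rx: list[tuple] = []
        drug = oral_opioids[int(rng.integers(len(oral_opioids)))]
        unit_mme = drug.strength_mg * drug.mme_factor
        coeffs = np.asarray(config.poly_coeffs[g], float)
        alpha = float(config.covariate_effects[g])
        cum = n_pre_stim
        stim_iter = iter(post_stim_days)
        pending = next(stim_iter, None)
        opioid_days: list[int] = []
        for w in range(n_win):
            win_end = index_day + 30 * (w + 1)
            while pending is not None and pending < win_end:
                cum += 1
                pending = next(stim_iter, None)
            t = w / config.time_scale
            eta = float(np.polyval(coeffs[::-1], t)) + alpha * cum
            if config.sigma > 0:
                eta += rng.normal(0.0, config.sigma)
            target_daily = math.expm1(max(eta, 0.0))
            units = round(target_daily * 30.0 / unit_mme)
            if w == 0 and units == 0:
                units = 1  # anchor the index date with a minimal fill
            if units > 0:
                day = index_day + 30 * w
                my_rx.append((pid, day, drug.drug_id, "opioid", drug.route,
                              drug.strength_mg, float(units), 30))
                opioid_days.append(day)

        if "single_fill" in reasons:
            my_rx = my_rx[:1]
            opioid_days = opioid_days[:1]
        elif len(set(opioid_days)) < 2 and enroll_end >= index_day + 1:
            sd = oral_opioids[0]
            my_rx.append((pid, index_day + 1, sd.drug_id, "opioid", sd.route,
                          sd.strength_mg, 1.0, 30))
            opioid_days.append(index_day + 1)

        for d in all_stim_days:
            sdrug = stimulants[int(rng.integers(len(stimulants)))]
            my_rx.append((pid, d, sdrug.drug_id, "stimulant", sdrug.route,
                          sdrug.strength_mg, 30.0, 30))

        if "prior_buprenorphine" in reasons and bupes:
            b = bupes[0]
            back = int(rng.integers(1, max(2, min(300, index_day - enroll_start))))
            my_rx.append((pid, index_day - back, b.drug_id, "buprenorphine", b.route,
                          b.strength_mg, 30.0, 30))

        if others and config.other_fill_rate > 0:
            n_other = rng.poisson(config.other_fill_rate * n_win)
            for d in rng.integers(index_day, max(index_day + 1, enroll_end), size=n_other):
                o = others[int(rng.integers(len(others)))]
                my_rx.append((pid, int(d), o.drug_id, "other", o.route,
                              o.strength_mg, 30.0, 30))
        rx_rows.extend(my_rx)

        # --- diagnoses ------------------------------------------------------
        for cat, (p_pre, p_post) in config.comorbidity_prevalence.items():
            if p_pre > 0 and rng.random() < p_pre and pre_lo < index_day:
                d = int(rng.integers(pre_lo, index_day))
                dx_rows.append((pid, d, f"SYN-{cat.upper()}", cat))
            if p_post > 0 and rng.random() < p_post:
                d = int(rng.integers(index_day, enroll_end + 1))
                dx_rows.append((pid, d, f"SYN-{cat.upper()}", cat))
        if "cancer" in reasons:
            d = int(rng.integers(enroll_start, index_day + 1))
            dx_rows.append((pid, d, "SYN-CANCER", "cancer"))

        pat_rows.append((pid, birth_offset, sex, region))
        enr_rows.append((pid, enroll_start, enroll_end))
        labels[pid] = g
        injected[pid] = reasons
        index_days[pid] = index_day

    patients = pd.DataFrame(pat_rows, columns=list(io.PATIENT_SCHEMA)) if pat_rows else io.empty_table("patients")
    enrollment = pd.DataFrame(enr_rows, columns=list(io.ENROLLMENT_SCHEMA)) if enr_rows else io.empty_table("enrollment")
    prescriptions = pd.DataFrame(rx_rows, columns=list(io.PRESCRIPTION_SCHEMA)) if rx_rows else io.empty_table("prescriptions")
    diagnoses = pd.DataFrame(dx_rows, columns=list(io.DIAGNOSIS_SCHEMA)) if dx_rows else io.empty_table("diagnoses")
    prescriptions = prescriptions.sort_values(["patient_id", "day", "drug_id"], kind="stable")
    diagnoses = diagnoses.sort_values(["patient_id", "day", "category"], kind="stable")

    truth = GroundTruth(
        n_groups=int(mix.size),
        mixture_proportions=tuple(float(p) for p in mix),
        poly_coeffs=tuple(tuple(float(c) for c in row) for row in config.poly_coeffs),
        covariate_effect=tuple(float(a) for a in config.covariate_effects),
        sigma=float(config.sigma),
        stimulant_rate=tuple(float(r) for r in config.stimulant_rates),
        group_labels=labels,
        injected_exclusions=injected,
        index_days=index_days,
    )
    return SyntheticDataset(
        patients=io.coerce_table("patients", patients),
        enrollment=io.coerce_table("enrollment", enrollment),
        prescriptions=io.coerce_table("prescriptions", prescriptions),
        diagnoses=io.coerce_table("diagnoses", diagnoses),
        ground_truth=truth,
    )


def write_dataset(dataset: SyntheticDataset, directory: str | Path) -> dict[str, int]:
    """Write the four tables plus the ground-truth sidecar; returns file→row-count."""
    directory = Path(directory)
    manifest = io.write_tables(dataset.tables(), directory)
    io.write_json(dataset.ground_truth.to_dict(), directory / "ground_truth.json")
    manifest["ground_truth.json"] = len(dataset.ground_truth.group_labels)
    return manifest


def read_dataset(directory: str | Path) -> SyntheticDataset:
    directory = Path(directory)
    tables = io.read_tables(directory)
    truth = GroundTruth.from_dict(io.read_json(directory / "ground_truth.json"))
    return SyntheticDataset(ground_truth=truth, **tables)


def simulate_dose_series(
    n_patients: int,
    n_windows: int,
    mixture: Sequence[float],
    poly_coeffs: Sequence[Sequence[float]],
    sigma: float,
    covariate_effects: Sequence[float] | None = None,
    stimulant_rates: Sequence[float] | None = None,
    pre_index_windows: float = 365.0 / 30.0,
    seed: int = 0,
    time_scale: float = 107.0,
):
    """Draw dose series directly from the trajectory model (no claims plumbing).

    Returns ``(X, C, labels)``: mean-daily-MME matrix (n, T), cumulative
    stimulant counts (n, T) or None, and the true group of each row.  This is
    the noise-exact analogue of :func:`generate_population` (no catalog
    quantization), intended for estimator recovery studies.
    """
    rng = np.random.default_rng(seed)
    mix = np.asarray(mixture, float)
    mix = mix / mix.sum()
    k = mix.size
    labels = rng.choice(k, size=n_patients, p=mix)
    t = np.arange(n_windows) / time_scale
    X = np.empty((n_patients, n_windows))
    C = None
    if stimulant_rates is not None:
        rates = np.asarray(stimulant_rates, float)[labels]
        pre = rng.poisson(rates * pre_index_windows)
        per_win = rng.poisson(np.repeat(rates[:, None], n_windows, axis=1))
        C = pre[:, None] + np.cumsum(per_win, axis=1)
    alpha = np.zeros(k) if covariate_effects is None else np.asarray(covariate_effects, float)
    for j in range(k):
        m = labels == j
        if not m.any():
            continue
        eta = np.polyval(np.asarray(poly_coeffs[j], float)[::-1], t)[None, :]
        eta = np.broadcast_to(eta, (m.sum(), n_windows)).copy()
        if C is not None:
            eta += alpha[j] * C[m]
        eta += rng.normal(0.0, sigma, size=eta.shape)
        X[m] = np.expm1(np.maximum(eta, 0.0))
    return X, C, labels
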