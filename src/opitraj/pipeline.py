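"""End-to-end orchestration: simulate → cohort → doses → trajectory fits → association.

Two trajectory models are fitted on the identical cohort and dose series: the
*opioid baseline model* (no covariate) and the *opioid–stimulant model* (with
the cumulative stimulant count as a time-varying covariate), so membership
shifts between them are attributable solely to the covariate.  All stage
outputs are plain delimited/JSON text, pure functions of (inputs, config,
seed), and a run manifest records row counts, wall-clock and file checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io, doses, association
from .catalog import Drug, catalog_from_dicts, mme_factor_map
from .cohort import EligibilityRules, build_cohort
from .errors import ConfigurationError
from .gbtm import select_model, posterior_assign
from .synthetic import SimConfig, SyntheticDataset, generate_population, write_dataset

logger = logging.getLogger(__name__)

STAGES = ("simulate", "cohort", "doses", "fit", "associate")


@dataclass
class PipelineConfig:
    """One structured config drives every stage; see ``default_config_yaml``."""

    input: str = "synthetic"  # "synthetic" or a directory of claims tables
    output_dir: str = "output"
    seed: int = 0
    log_level: str = "INFO"
    sim: SimConfig = field(default_factory=SimConfig)
    rules: EligibilityRules = field(default_factory=EligibilityRules)
    dose_mode: str = "dispense_date"
    k_grid: tuple[int, ...] = (1, 2, 3, 4, 5)
    poly_order: int = 2
    transform: str = "log1p"
    n_starts: int = 3
    max_iter: int = 200
    tol: float = 1e-7
    confidence: float = 0.99
    predictors: tuple[str, ...] | None = None
    reference_group: int | str = "auto"  # "auto": most negative linear trend
    target_group: int | str = "auto"  # "auto": most positive linear trend

    def validate(self) -> None:
        if not self.input:
            raise ConfigurationError("input must be 'synthetic' or a directory path")
        if self.input == "synthetic":
            self.sim.validate()
        elif not Path(self.input).is_dir():
            raise ConfigurationError(f"input directory not found: {self.input}")
        if not self.k_grid:
            raise ConfigurationError("k_grid must be nonempty")
        if self.dose_mode not in doses.MODES:
            raise ConfigurationError(f"dose_mode must be one of {doses.MODES}")
        if not isinstance(self.seed, int):
            raise ConfigurationError("seed must be an integer")

    # ---- (de)serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["sim"]["drug_catalog"] = [drug.to_dict() for drug in self.sim.drug_catalog]
        for key in ("allowed_routes", "excluded_prior_drug_classes", "excluded_diagnosis_categories"):
            d["rules"][key] = sorted(d["rules"][key])
        return json.loads(json.dumps(d))  # normalise tuples to lists

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = dict(d.pop("sim", {}))
        if "drug_catalog" in sim:
            sim["drug_catalog"] = catalog_from_dicts(sim["drug_catalog"])
        if "exclusion_fractions" in sim:
            sim["exclusion_fractions"] = dict(sim["exclusion_fractions"])
        if "comorbidity_prevalence" in sim:
            sim["comorbidity_prevalence"] = {
                k: tuple(v) for k, v in sim["comorbidity_prevalence"].items()
            }
        rules = dict(d.pop("rules", {}))
        for key in ("allowed_routes", "excluded_prior_drug_classes", "excluded_diagnosis_categories"):
            if key in rules:
                rules[key] = frozenset(rules[key])
        for key in ("k_grid", "predictors"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(sim=SimConfig(**sim), rules=EligibilityRules(**rules), **d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    stages: list = field(default_factory=list)
    files: dict = field(default_factory=dict)
    versions: dict = field(default_factory=dict)
    error: str | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _long_table(matrix: np.ndarray, ids) -> pd.DataFrame:
    rows = []
    for i, pid in enumerate(ids):
        obs = np.isfinite(matrix[i])
        for w in np.nonzero(obs)[0]:
            rows.append((pid, int(w), float(matrix[i, w])))
    return pd.DataFrame(rows, columns=["patient_id", "window", "value"])


def _model_to_dict(model) -> dict:
    return {
        "n_groups": model.n_groups,
        "poly_order": model.poly_order,
        "include_covariate": model.include_covariate,
        "transform": model.transform,
        "weights": model.weights_.tolist(),
        "coefficients": model.coefficients_.tolist(),
        "covariate_effects": (
            None if model.covariate_effects_ is None else model.covariate_effects_.tolist()
        ),
        "sigma": model.sigma_ if np.isscalar(model.sigma_) else model.sigma_.tolist(),
        "log_likelihood": model.log_likelihood_,
        "bic": model.bic_,
        "n_params": model.n_params_,
        "n_iter": model.n_iter_,
        "converged": model.converged_,
    }


def _pick_groups(model, reference, target):
    """Resolve 'auto' group choices from fitted linear trends."""
    if reference != "auto" and target != "auto":
        return int(reference), int(target)
    if model.n_groups < 2 or model.poly_order < 1:
        return None
    slopes = model.coefficients_[:, 1]
    ref = int(np.argmin(slopes)) if reference == "auto" else int(reference)
    tgt = int(np.argmax(slopes)) if target == "auto" else int(target)
    if ref == tgt:
        return None
    return ref, tgt


def run_pipeline(config: PipelineConfig, last_stage: str = "associate") -> RunManifest:
    """Execute stages through ``last_stage``; write outputs and a manifest."""
    if last_stage not in STAGES:
        raise ConfigurationError(f"last_stage must be one of {STAGES}")
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_hash=config.config_hash(),
        seed=config.seed,
        versions={
            "opitraj": _version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    )
    try:
        _run_stages(config, out, manifest, last_stage)
    except Exception as err:
        manifest.error = f"{type(err).__name__}: {err}"
        _write_manifest(manifest, out)
        raise
    _write_manifest(manifest, out)
    return manifest


def _version() -> str:
    from . import __version__

    return __version__


def _write_manifest(manifest: RunManifest, out: Path) -> None:
    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest.files[str(path.relative_to(out))] = _sha256(path)
    io.write_json(manifest.to_dict(), out / "manifest.json")


def _stage(manifest, name, t0, **counts):
    manifest.stages.append({"stage": name, "seconds": round(time.time() - t0, 3), **counts})
    logger.info("stage %s done: %s", name, counts)


def _run_stages(
    config: PipelineConfig, out: Path, manifest: RunManifest, last_stage: str = "associate"
) -> None:
    stop_after = STAGES.index(last_stage)
    # -- simulate / load -----------------------------------------------------
    t0 = time.time()
    if config.input == "synthetic":
        sim = dataclasses.replace(config.sim, seed=config.seed)
        dataset = generate_population(sim)
        write_dataset(dataset, out / "data")
        tables = dataset.tables()
    else:
        tables = io.read_tables(config.input)
        dataset = tables
    _stage(manifest, "simulate", t0, **{k: len(v) for k, v in tables.items()})
    if stop_after < 1:
        return

    # -- cohort --------------------------------------------------------------
    t0 = time.time()
    cohort, attrition = build_cohort(
        dataset if isinstance(dataset, SyntheticDataset) else tables, config.rules
    )
    cohort.to_csv(out / "cohort.csv", index=False)
    attrition.to_csv(out / "attrition.csv", index=False)
    _stage(manifest, "cohort", t0, patients_in=len(tables["patients"]), cohort=len(cohort))
    if stop_after < 2:
        return

    # -- dose series and covariates ------------------------------------------
    t0 = time.time()
    factors = mme_factor_map(config.sim.drug_catalog)
    X, ids = doses.build_dose_matrix(cohort, tables["prescriptions"], factors, config.dose_mode)
    C, stim_summary = doses.build_covariate_matrix(cohort, tables["prescriptions"])
    comorbid = doses.build_comorbidity_table(cohort, tables["diagnoses"])
    _long_table(X, ids).to_csv(out / "dose_series.csv", index=False)
    _long_table(C, ids).to_csv(out / "covariates.csv", index=False)
    summaries = pd.DataFrame(
        [
            {"patient_id": pid, **vars(doses.summarize_dosing(X[i][np.isfinite(X[i])]))}
            for i, pid in enumerate(ids)
        ]
    )
    summaries.to_csv(out / "dose_summaries.csv", index=False)
    comorbid.to_csv(out / "comorbidity.csv", index=False)
    stim_summary.to_csv(out / "stimulant_summary.csv", index=False)
    _stage(manifest, "doses", t0, series=len(ids))
    if stop_after < 3:
        return

    # -- trajectory models ----------------------------------------------------
    t0 = time.time()
    common = dict(
        poly_orders=(config.poly_order,),
        transform=config.transform,
        n_starts=config.n_starts,
        max_iter=config.max_iter,
        tol=config.tol,
        random_state=config.seed,
    )
    fits = {}
    for label, cov in (("baseline", None), ("stimulant", C)):
        sel = select_model(X, cov, k_grid=config.k_grid,
                           include_covariate=cov is not None, **common)
        sel.table.to_csv(out / f"selection_{label}.csv", index=False)
        io.write_json(_model_to_dict(sel.chosen), out / f"model_{label}.json")
        assign = posterior_assign(sel.chosen, X, cov, ids)
        assign.to_csv(out / f"assignments_{label}.csv", index=False)
        curves = []
        for g in range(sel.chosen.n_groups):
            curve = sel.chosen.predicted_trajectory(g, confidence=config.confidence)
            curve.insert(0, "group", g)
            curves.append(curve)
        pd.concat(curves).to_csv(out / f"trajectories_{label}.csv", index=False)
        fits[label] = (sel, assign)
    _stage(
        manifest, "fit", t0,
        baseline_groups=fits["baseline"][0].chosen.n_groups,
        stimulant_groups=fits["stimulant"][0].chosen.n_groups,
    )
    if stop_after < 4:
        return

    # -- association -----------------------------------------------------------
    t0 = time.time()
    sel, assign = fits["stimulant"]
    features = association.build_predictor_table(cohort, stim_summary, comorbid)
    features = features.merge(summaries, on="patient_id")
    features = features.merge(assign[["patient_id", "modal_group"]], on="patient_id")
    features["stim_exposed"] = np.where(features["stim_count_between"] > 0, "w/STM", "w/o STM")
    features["sex"] = np.where(features["sex_male"] == 1, "M", "F")
    features = features.merge(cohort[["patient_id", "region"]], on="patient_id")

    measures = ["age_at_index", "prsc_no", "avg_mme", "total_mme", "stim_count_between"]
    comparisons = []
    for grouping in ("region", "sex", "stim_exposed", "modal_group"):
        if features[grouping].nunique() < 2:
            logger.info("skipping %s comparison: fewer than two levels", grouping)
            continue
        comparisons.append(association.subgroup_compare(features, grouping, measures))
    (pd.concat(comparisons) if comparisons else pd.DataFrame()).to_csv(
        out / "comparisons.csv", index=False
    )

    binary_cols = [c for c in features.columns if c.startswith("pre_")] + ["stim_tv_binary"]
    association.descriptive_table(
        features, "modal_group", numeric=measures, binary=binary_cols
    ).to_csv(out / "descriptives.csv", index=False)

    picked = _pick_groups(sel.chosen, config.reference_group, config.target_group)
    if picked is None:
        logger.info("membership regression skipped: no distinct increasing/decreasing groups")
        regression = pd.DataFrame(
            columns=["predictor", "coef", "se", "odds_ratio", "ci_lower", "ci_upper", "p_value"]
        )
    else:
        ref, tgt = picked
        regression = association.membership_regression(
            features.drop(columns=["modal_group"]), assign, ref, tgt,
            predictors=config.predictors,
        )
    regression.to_csv(out / "regression.csv", index=False)
    if len(regression):
        regression[["predictor", "odds_ratio", "ci_lower", "ci_upper"]].to_csv(
            out / "forest.csv", index=False
        )
    _stage(manifest, "associate", t0, regressions=len(regression))


def default_config_yaml() -> str:
    """Annotated default configuration (the documented reference conditions)."""
    cfg = PipelineConfig()
    header = (
        "# opitraj pipeline configuration\n"
        "# input: 'synthetic' generates claims from the bundled simulator;\n"
        "#        otherwise a directory containing patients/enrollment/\n"
        "#        prescriptions/diagnoses CSV tables.\n"
        "# Eligibility defaults: >=2 oral opioid fill dates, 365d pre / 60d\n"
        "# post continuous enrollment, age >=18, no cancer history, no prior\n"
        "# buprenorphine, 9-year follow-up cap (108 x 30-day windows).\n"
        "# Dose windows: mean daily MME per 30-day window from the index date.\n"
    )
    return header + yaml.safe_dump(cfg.to_dict(), sort_keys=False)
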