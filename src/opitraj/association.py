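"""Post-assignment statistics: descriptive tables, rank tests, membership regression.

After patients are assigned to trajectory groups, three analyses quantify how
patient characteristics relate to the groups:

* descriptive tables — n (%), mean (SD), median (IQR) per stratum;
* rank-based comparisons — Mann-Whitney U for two groups, Kruskal-Wallis for
  more, two-sided, midranks for ties, significance at P < 0.05 (no
  multiple-testing adjustment; see docs/methods.md);
* trajectory-membership logistic regression — a binary logistic model
  restricted to patients assigned to a reference and a target group, fitted by
  Newton/IRLS maximum likelihood, reporting per-predictor odds ratios with
  Wald 95% confidence intervals exp(beta +/- z * SE).

The "time-varying" stimulant exposure enters a (static) logistic model as its
end-of-follow-up cumulative count plus a binary any-exposure indicator.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import CollinearityError, SeparationError

DEFAULT_PREDICTORS = (
    "age_at_index",
    "sex_male",
    "stim_count_pre_index",
    "stim_tv_summary",
    "stim_tv_binary",
)


def build_predictor_table(
    cohort: pd.DataFrame,
    stim_summary: pd.DataFrame,
    comorbidity: pd.DataFrame | None = None,
    reference_region: str = "South",
) -> pd.DataFrame:
    """Assemble the per-patient predictor vector for membership regression.

    Columns: age_at_index, sex_male, region dummies (reference omitted),
    pre-index comorbidity flags, stimulant counts (pre-index, end-of-follow-up
    cumulative, and its binary form).
    """
    out = cohort[["patient_id", "age_at_index", "sex", "region"]].copy()
    out["sex_male"] = (out.pop("sex") == "M").astype(int)
    for region in sorted(out["region"].unique()):
        if region != reference_region:
            out[f"region_{region.replace(' ', '_')}"] = (out["region"] == region).astype(int)
    out = out.drop(columns=["region"])
    out = out.merge(stim_summary, on="patient_id", how="left")
    for col in ("stim_count_pre_index", "stim_count_between", "stim_tv_summary"):
        if col in out:
            out[col] = out[col].fillna(0).astype(int)
    out["stim_tv_binary"] = (out["stim_tv_summary"] > 0).astype(int)
    if comorbidity is not None:
        pre_cols = [c for c in comorbidity.columns if c.startswith("pre_")]
        out = out.merge(comorbidity[["patient_id"] + pre_cols], on="patient_id", how="left")
        out[pre_cols] = out[pre_cols].fillna(0).astype(int)
    return out


def _check_collinearity(X: pd.DataFrame) -> None:
    arr = np.column_stack([np.ones(len(X)), X.to_numpy(float)])
    _, R = np.linalg.qr(arr)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(arr.shape) * np.finfo(float).eps
    if (diag <= tol).any():
        # an (unpivoted) QR flags the later of each linearly dependent pair
        dependent = [(["const"] + list(X.columns))[i] for i in np.where(diag <= tol)[0]]
        raise CollinearityError(f"collinear predictor columns: {dependent}")


def membership_regression(
    features: pd.DataFrame,
    assignments: pd.DataFrame,
    reference_group: int,
    target_group: int,
    predictors=None,
    conf_level: float = 0.95,
) -> pd.DataFrame:
    """Logistic regression of target-vs-reference trajectory membership.

    Restricted to patients whose modal group is the reference or the target;
    outcome 1 = target group.  Returns one row per predictor with log-odds
    coefficient, SE, odds ratio, Wald CI and p-value.
    """
    df = features.merge(assignments[["patient_id", "modal_group"]], on="patient_id")
    df = df[df["modal_group"].isin([reference_group, target_group])]
    for grp, name in ((reference_group, "reference"), (target_group, "target")):
        if not (df["modal_group"] == grp).any():
            raise ValueError(f"{name} group {grp} has no assigned patients")
    y = (df["modal_group"] == target_group).astype(int).to_numpy()
    cols = list(predictors) if predictors is not None else [
        c for c in DEFAULT_PREDICTORS if c in df.columns
    ]
    X = df[cols]
    _check_collinearity(X)
    design = sm.add_constant(X.to_numpy(float), has_constant="add")
    try:
        fit = sm.Logit(y, design).fit(disp=0, method="newton", maxiter=200, tol=1e-10)
    except Exception as err:  # statsmodels raises on perfect separation
        raise SeparationError(f"logistic fit failed ({err}); check predictors {cols}") from err
    params, bse = np.asarray(fit.params), np.asarray(fit.bse)
    if not (np.isfinite(params).all() and np.isfinite(bse).all()) or np.abs(params).max() > 30:
        worst = (["const"] + cols)[int(np.nanargmax(np.abs(params)))]
        raise SeparationError(f"separation detected for predictor {worst!r}")
    z = stats.norm.ppf(0.5 + conf_level / 2.0)
    names = ["intercept"] + cols
    return pd.DataFrame(
        {
            "predictor": names,
            "coef": params,
            "se": bse,
            "odds_ratio": np.exp(params),
            "ci_lower": np.exp(params - z * bse),
            "ci_upper": np.exp(params + z * bse),
            "p_value": np.asarray(fit.pvalues),
        }
    )


def subgroup_compare(
    df: pd.DataFrame, grouping: str, measures, alpha: float = 0.05
) -> pd.DataFrame:
    """Rank-based comparison of ``measures`` across the levels of ``grouping``.

    Mann-Whitney U for two levels, Kruskal-Wallis for more; two-sided.
    """
    if isinstance(df[grouping].dtype, pd.CategoricalDtype):
        levels = list(df[grouping].cat.categories)
    else:
        levels = sorted(df[grouping].dropna().unique())
    if len(levels) < 2:
        raise ValueError(f"grouping {grouping!r} needs at least two levels")
    samples = {lev: df.loc[df[grouping] == lev] for lev in levels}
    for lev, sub in samples.items():
        if not len(sub):
            raise ValueError(f"group {lev!r} has zero observations")
    rows = []
    for measure in measures:
        groups = [sub[measure].dropna().to_numpy(float) for sub in samples.values()]
        if len(groups) == 2:
            stat, p = stats.mannwhitneyu(groups[0], groups[1], alternative="two-sided")
            test = "mann_whitney_u"
        else:
            stat, p = stats.kruskal(*groups)
            test = "kruskal_wallis"
        rows.append((measure, grouping, test, float(stat), float(p), bool(p < alpha)))
    return pd.DataFrame(
        rows, columns=["measure", "grouping", "test", "statistic", "p_value", "significant"]
    )


def descriptive_table(
    df: pd.DataFrame,
    stratifier: str,
    numeric=(),
    binary=(),
) -> pd.DataFrame:
    """n (%), mean (SD), median (IQR) per measure and stratum.

    The top ``n`` row is each stratum's share of the cohort (percentages sum
    to 100 across strata); binary measures report within-stratum n (%).  With
    a single observation the SD is reported as 0 and flagged ``degenerate``.
    """
    strata = sorted(df[stratifier].dropna().unique())
    total = len(df)
    rows = []
    for stratum in strata:
        sub = df[df[stratifier] == stratum]
        n = len(sub)
        rows.append((stratum, "n", "count", float(n), n < 2))
        rows.append((stratum, "n", "pct_of_total", 100.0 * n / total if total else 0.0, n < 2))
        for col in numeric:
            vals = sub[col].dropna().to_numpy(float)
            degen = len(vals) < 2
            sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
            q1, med, q3 = (
                np.percentile(vals, [25, 50, 75]) if len(vals) else (np.nan,) * 3
            )
            rows.extend(
                [
                    (stratum, col, "mean", float(np.mean(vals)) if len(vals) else np.nan, degen),
                    (stratum, col, "sd", sd, degen),
                    (stratum, col, "median", float(med), degen),
                    (stratum, col, "q1", float(q1), degen),
                    (stratum, col, "q3", float(q3), degen),
                ]
            )
        for col in binary:
            k = int(sub[col].sum())
            rows.append((stratum, col, "count", float(k), n < 2))
            rows.append((stratum, col, "pct", 100.0 * k / n if n else 0.0, n < 2))
    return pd.DataFrame(rows, columns=["stratum", "measure", "statistic", "value", "degenerate"])
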