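# Methods

This note documents the statistical model, the design choices behind each
pipeline stage, and what the synthetic-data generator does and does not
emulate.  It states no empirical result beyond what the test suite and
`scripts/acceptance.py` compute.

## Cohort construction

The new-user design anchors every patient at the **index date**, the first
opioid fill with an allowed route (default: oral only; patches, injections
and other routes are invisible to all counting rules, including the ≥2-fill
requirement).  "Two independent prescriptions at different times" is read as
opioid fills on at least two distinct service dates; same-day fills count
once.  Eligibility rules are evaluated in a fixed order and the first failure
is recorded, so the attrition report partitions the input population exactly:

1. ≥ 2 distinct oral-opioid fill dates;
2. one continuous enrollment span covering the 365 days before the index;
3. the same span covering the 60 days after the index;
4. age ≥ 18 years at the index (integer years of 365 days from the birth
   offset);
5. no excluded diagnosis category (default: cancer) on or before the index —
   the exclusion window is all available history by default, with a
   `baseline` option restricting it to the 365-day pre-index window, since
   an unwindowed cancer rule is the stricter and more common new-user
   convention;
6. no excluded prior drug class (default: buprenorphine) strictly before the
   index.

Enrollment spans are merged when the gap between them is at most a
configurable grace (default 0 days, i.e. only back-to-back spans merge);
overlapping spans are a data-quality error.  Follow-up ends at
`min(index + 9×365 days, end of the enrollment span containing the index)`;
the modelled horizon is the number of complete 30-day windows, capped at 108.
Nine years of days (3285) would admit a 109th window, but the analysis
horizon is defined in windows, not calendar years, so 108 is the cap and the
remaining days are never used.

## Dose series

Daily dose of a fill (mg/day MME) = strength per unit × (quantity / days
supplied) × conversion factor.  Conversion factors live in the drug-catalog
configuration, not in code, because published conversion tables are
versioned externally.

Window `w` covers days `[index + 30w, index + 30(w+1))`.  Two windowing
modes exist:

* `dispense_date` (default): window value = total MME dispensed on days in
  the window / 30.  This is the reading of "monthly MME of all opioids
  dispensed in the period"; it conserves total dispensed MME across windows.
* `supply_spread` (sensitivity): each fill contributes its daily dose on
  each day of its days-supply interval before windowing.  Both modes agree
  exactly whenever each supply interval lies inside one window.

A partial terminal window is dropped (a complete 30-day denominator is
required).  Fills before the index define the index only and are ignored
with a logged warning; fills after follow-up end are ignored.

Per-patient summaries follow the usual claims conventions: `prsc_no` =
number of windows with any dispensing, `avg_mme` = mean of positive-window
values, `total_mme` = sum of all window values.

The time-varying stimulant covariate at window `w` is the cumulative count
of stimulant fills from 365 days before the index through the end of window
`w`; it is non-decreasing by construction.  A diagnosis exactly on the index
date counts as post-index (the index visit is the start of exposure);
comorbidity flags are computed for the 365-day baseline window and for any
time after the index.

## Trajectory model

GBTM is a K-component finite mixture in which group *j* follows its own mean
trajectory.  Doses are heavily right-skewed with many zero months, so the
outcome family is a **censored normal on `y* = log(1 + MME)`** with lower
censoring bound at `y* = 0`: an observed zero contributes `Φ((0 − μ_jt)/σ)`,
a positive dose contributes the normal density.  The group mean is

    μ_jt = β_j′ x_t + α_j c_it,   x_t = (1, t, …, t^p),   t = window / 107,

with time rescaled to [0, 1] over the 108-window horizon for conditioning.
The polynomial order is shared across groups (default 2, grid 0–3
available); the covariate coefficient is group-specific by default — adding
the covariate is expected to reshape individual group trajectories, which a
single shared coefficient cannot express — with a shared-coefficient flag.
The residual SD is shared across groups for parsimony (per-group SD behind a
flag).  Patients contribute only their observed windows; series lengths may
vary and nothing is imputed.

**Fitting.**  EM on the observed-data likelihood.  The E-step computes
posterior memberships from the current mixture weights and per-patient group
log-likelihoods.  The M-step maximises the expected complete-data
log-likelihood: when no observation is censored this is exact weighted least
squares per group (plus a closed-form σ), otherwise a damped Newton ascent
on (β, α, log σ) with analytic censored-normal derivatives, accepting only
steps that increase the objective, so the observed log-likelihood is
monotone to numerical precision (asserted at 1e-8 throughout the tests).
Mixture weights update to mean posteriors; a weight falling below 1/N
signals a collapsed group and triggers a restart.  Initialisation is
k-means++ on standardized per-patient (mean, slope) summaries; the default
is 5 restarts and the best restart by log-likelihood is kept.  Everything is
deterministic given `random_state`.

**Selection and assignment.**  Candidates over a K grid (and optionally an
order grid) are compared by `BIC = −2 log L + k ln N`, with N = number of
patients and k counting polynomial coefficients, covariate coefficients,
σ parameters and K−1 mixture logits; the convention is fixed here because
BIC definitions differ across software.  The minimal-BIC converged fit is
chosen.  Patients are assigned to their modal posterior group, ties breaking
toward the lower group index.  Groups are always reported in ascending order
of mean fitted dose, which makes labels comparable across fits.

**Uncertainty.**  The parameter covariance is the inverse observed
information of the mixture likelihood: the score is computed analytically
via the Fisher identity (posterior-weighted complete-data score, plus the
mixture-logit block) and differentiated centrally.  Predicted trajectories
are reported on the original dose scale by inverse-transforming
`μ_jt ± z·SE(μ_jt)` with SE from the delta method on the (β_j, α_j)
sub-block; the default band level is 99%.

## Association analyses

Rank-based comparisons use Mann–Whitney U for two groups and Kruskal–Wallis
for more, two-sided, midranks for ties, significance at P < 0.05 with **no
multiple-testing adjustment** — this mirrors the conventional reporting rule
for cohort descriptions, and is a known caveat: with dozens of comparisons
some significant results are expected under the null.

The membership regression is a binary logistic model restricted to patients
assigned to a reference and a target trajectory group (e.g. the
decreasing-dose group as reference versus the increasing-dose group),
fitted by Newton maximum likelihood, with Wald CIs `exp(β ± z·SE)`.  A
static regression cannot take a vector-valued covariate, so the
"time-varying" stimulant exposure is summarised as the cumulative count at
end of follow-up plus its binary any-exposure form; pre-index exposure
enters as the count in the 365-day baseline window.  Age enters linearly per
year.  Collinear predictors are rejected with the dependent columns named;
perfect separation is detected and reported rather than returning divergent
estimates.

## Synthetic-data generator

The generator emulates the *structure* of commercial-claims extracts:
per-patient enrollment spans, dated pharmacy fills carrying drug
class/route/strength/quantity/days-supply, dated diagnosis categories (a
configurable code→category map stands in for real ICD code lists), and
demographics over four U.S. regions.  Dose dynamics are driven by the same
model the estimator fits: a latent group drawn from the mixture, a monthly
latent mean `poly_g(t) + α_g · cumstim + N(0, σ)` floored at 0 on the
transformed scale and inverse-transformed to a target mean daily MME.  One
opioid fill per active window, dated at the window start, is emitted with
quantity chosen to reproduce the window's dispensed total up to catalog
quantization; a window whose target rounds below one dispensable unit stays
empty, producing the zero-dose months real series contain.  Stimulant fills
are Poisson per window with a group-specific rate (also applied to the
365-day pre-index window), so stimulant exposure is informative about group
membership, as in real co-prescription data.

Default conditions: five groups with proportions
77.5/10.2/8.5/2.4/1.4% — a dominant very-low-dose group (~4.5 MME),
decreasing and increasing low-dose groups (~15 MME at entry), an increasing
moderate group (~45 MME) and a sustained high-dose group (~105 MME) — σ =
0.35 on the log scale, demographics (57% female; mean age 44 ± 13, truncated
at 18; region shares 12.8/20.2/49.7/16.2%), baseline/post-index comorbidity
prevalences typical of a commercial opioid cohort, mean follow-up ≈ 1277
days, and stimulant rates 2–4× higher in the increasing/high-dose groups.
Zero-month prevalence is not fixed separately: it emerges from the group
intercepts, σ and the catalog quantization, all of which are configurable.

Determinism contracts: each patient is generated from an RNG stream keyed by
`(seed, patient index)`, so output is byte-identical across runs and
per-patient rows are invariant to `n_patients`.  Two technical guarantees
keep the ground truth aligned with what the eligibility stage sees: the
window-0 fill is forced to at least one unit (a cohort entry is defined by a
fill, so the intended index date must carry one), and patients not injected
with the single-fill exclusion receive a minimal top-up fill on index+1 if
censoring would otherwise leave fewer than two fill dates.  Enrollment ends
within the terminal partial window of the emission horizon, so the
downstream series never contains windows the latent model did not generate.

Exclusion injection: each reason (minor, cancer history, prior
buprenorphine, short pre-/post-index enrollment, single fill) is injected at
a configurable fraction, independently across reasons by default; a
`disjoint` mode assigns at most one reason per patient, which makes the
expected attrition row of each rule equal its injected count exactly — the
form used by the attrition tests.

**What passing tests do and do not show.**  The generator draws from the
same family the model fits, so parameter-recovery results demonstrate
correctness of the estimator and pipeline plumbing, not robustness to the
misspecification real claims exhibit (irregular fill timing, dose tapering
within months, drug switching, enrollment churn, coding noise).  Fill
emission is one fill per window at the window start; real data interleave
overlapping supplies and multiple prescribers.  NDC-level semantics,
pricing/adjudication fields and inpatient records are out of scope.

## Problem sizes and numerical choices

Test and acceptance problem sizes are chosen to estimate each property with
comfortable statistical margins on a single CPU: recovery at n = 2000
patients × 24 windows, selection consistency over 20 replicates of n = 1000
× 12 windows with K grid 1–5, covariate recovery on a 2000-patient claims
dataset, calibration over 1000 null replicates, and a 150-patient smoke run
for bit-identical reproducibility.  EM tolerance is 1e-7 relative with at
most 200 iterations; the M-step Newton uses at most 8 inner ascent steps
(generalised EM) with Levenberg damping and step halving; log σ is bounded
in [−10, 5].  Dates are integer day offsets from an arbitrary epoch, making
window arithmetic exact.

## Known limitations

* Causality is out of scope: the pipeline quantifies associations between
  stimulant exposure and dose-trajectory membership, nothing more.
* The censored-normal family with a shared σ can misfit dose distributions
  with group-dependent dispersion (a per-group σ flag exists but is not the
  default).
* BIC with N = patients is one of several defensible conventions
  (alternatives use total observations); selection results are only
  comparable within one convention.
* The observed-information covariance assumes a correctly specified model
  and a converged, non-degenerate fit; near-collapsed groups make the Wald
  bands unreliable.
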