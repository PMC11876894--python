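# opitraj

Opioid dose-trajectory modelling and stimulant co-prescription analysis for
longitudinal pharmacy claims.

## What this package is for

Pharmacoepidemiologists studying the "twin epidemic" — the co-occurring rise
of opioid and central-nervous-system stimulant prescribing — need to turn raw
claims extracts into answers to two questions: *what distinct long-term
opioid-dose patterns exist in a new-user cohort*, and *is stimulant exposure
associated with escalating opioid doses*?  opitraj implements that full
analysis as a tested, reusable pipeline:

1. **Cohort construction** — new-user design: the index date is the first
   oral opioid fill; eligibility requires ≥2 opioid fill dates, 12 months of
   continuous enrollment before and 2 months after the index, age ≥ 18, no
   cancer history and no prior buprenorphine; follow-up is capped at 9 years.
   Every exclusion is accounted for in an ordered attrition report.
2. **Dose series** — each fill's daily morphine-milligram-equivalent dose is
   `strength per unit × (quantity / days supplied) × MME conversion factor`;
   doses are aggregated into consecutive non-overlapping 30-day windows from
   the index date and divided by 30 to give mean daily MME per window.
3. **Group-based trajectory modelling (GBTM)** — a censored-normal finite
   mixture on the `log(1 + MME)` scale: group *j* has mean
   `μ_jt = β_j′x_t + α_j c_it` with polynomial time basis `x_t` and an
   optional time-varying covariate `c_it` (cumulative stimulant fills from
   one year pre-index).  Zero-dose months contribute censoring mass
   `Φ((0 − μ_jt)/σ)` rather than a density.  Fitting is by EM with k-means++
   restarts; the number of groups and polynomial order are selected by
   `BIC = −2 log L + k ln N`.
4. **Association statistics** — descriptive tables, Kruskal–Wallis /
   Mann–Whitney comparisons, and a trajectory-membership logistic regression
   yielding odds ratios with Wald 95% CIs (e.g. increasing-dose vs
   decreasing-dose group membership against pre-index stimulant counts).
5. **Synthetic claims generator** — real claims are proprietary, so the
   package bundles a generator that emulates their structure (enrollment
   spans, dated fills with strength/quantity/days-supply, diagnosis
   categories, demographics) with dose dynamics driven by a known latent
   trajectory mixture.  Every downstream stage is testable against this
   ground truth.

The GBTM estimator follows scikit-learn conventions (`fit`, `predict_proba`,
`predict`, `get_params`, fitted attributes with trailing underscores) and
composes with sklearn model-selection tooling; the rest of the pipeline is
plain functions over pandas tables.

## Worked example

```python
import numpy as np
from opitraj import simulate_dose_series, select_model, posterior_assign

# three latent groups: flat low dose, decreasing, increasing
X, _, truth = simulate_dose_series(
    n_patients=1000, n_windows=24,
    mixture=(0.5, 0.3, 0.2),
    poly_coeffs=((1.0, 0.0), (2.5, -2.0), (4.0, 3.0)),
    sigma=0.3, seed=42,
)
sel = select_model(X, k_grid=(1, 2, 3, 4), poly_orders=(1,), n_starts=3, random_state=0)
print(sel.table.to_string(index=False))
m = sel.chosen
print("weights:", np.round(m.weights_, 3))
print("coefficients (log1p scale):")
print(np.round(m.coefficients_, 3))
print("sigma:", round(m.sigma_, 3), " BIC:", round(m.bic_, 1))
```

prints

```
 n_groups  poly_order  n_params  log_likelihood          bic  converged
        3           1         9    -6243.507210 12549.184217       True
        4           1        12    -6240.591052 12564.075168      False
        2           1         6   -23905.123481 47851.693494       True
        1           1         3   -40434.153880 80889.031025       True
weights: [0.503 0.3   0.197]
coefficients (log1p scale):
[[ 0.995  0.012]
 [ 2.509 -1.965]
 [ 4.006  2.997]]
sigma: 0.301  BIC: 12549.2
```

BIC picks the true three-group model (the four-group fit collapses to an
empty group); the recovered mixture weights (0.503/0.300/0.197) and
intercepts/slopes on the transformed scale match the generating values, and
`posterior_assign(m, X)` classifies patients with near-unit posterior
probabilities.  Groups are always reported in ascending order of mean fitted
dose.

The same analysis runs end-to-end from claims tables via the CLI:

```bash
opitraj init-config config.yaml   # annotated defaults
opitraj run-all --config config.yaml --seed 11 --out results/
```

which writes the cohort, attrition report, dose series, BIC selection tables,
trajectory curves with 99% confidence bands, posterior assignments for the
baseline and opioid–stimulant models, descriptive tables, rank tests, a
membership-regression odds-ratio table, and a checksummed run manifest.

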