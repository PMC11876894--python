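"""Tests of the censored-normal trajectory mixture: likelihood, EM, selection."""

import math

import numpy as np
import pytest
from scipy.stats import norm
from sklearn.metrics import adjusted_rand_score

from opitraj.errors import ConvergenceError
from opitraj.gbtm import (
    GroupTrajectoryModel,
    _Params,
    patient_group_loglik,
    posterior_assign,
    select_model,
)
from opitraj.synthetic import simulate_dose_series

from conftest import RECOVERY_TRUTH


def naive_patient_loglik(values, beta, sigma, covariates=None, alpha=0.0, time_scale=107.0):
    """Independent window-by-window recomputation of the censored-normal density."""
    total = 0.0
    for w, v in enumerate(values):
        if not np.isfinite(v):
            continue
        t = w / time_scale
        mu = sum(b * t**p for p, b in enumerate(beta))
        if covariates is not None:
            mu += alpha * covariates[w]
        y = math.log1p(v)
        if y <= 0:
            total += norm.logcdf((0.0 - mu) / sigma)
        else:
            total += norm.logpdf(y, mu, sigma)
    return total


def test_loglik_closed_forms():
    # uncensored with mu exactly matching y*, sigma = 1: each term is log phi(0)
    values = np.expm1([1.0, 1.0, 1.0])
    ll = patient_group_loglik(values, beta=[1.0], sigma=1.0)
    assert ll == pytest.approx(3 * (-0.5 * math.log(2 * math.pi)))
    # single censored observation with mu at the bound: log Phi(0) = log(1/2)
    ll0 = patient_group_loglik([0.0], beta=[0.0], sigma=0.7)
    assert ll0 == pytest.approx(math.log(0.5))


def test_loglik_matches_naive_oracle():
    rng = np.random.default_rng(3)
    values = np.maximum(rng.normal(5, 8, size=20), 0.0)
    cov = rng.integers(0, 5, size=20).astype(float)
    beta = [1.2, -0.8, 0.5]
    ll = patient_group_loglik(values, beta, 0.6, covariates=cov, alpha=0.1)
    assert ll == pytest.approx(naive_patient_loglik(values, beta, 0.6, cov, 0.1), abs=1e-10)


def test_loglik_rejects_bad_sigma():
    from opitraj.errors import DomainError

    with pytest.raises(DomainError):
        patient_group_loglik([1.0], beta=[0.0], sigma=0.0)


def _manual_model(beta, pi, sigma, **kwargs):
    """Fabricate a fitted model with given parameters (for oracle checks)."""
    m = GroupTrajectoryModel(n_groups=len(pi), **kwargs)
    m._params_ = _Params(
        beta=np.asarray(beta, float),
        alpha=None,
        logsig=np.array([math.log(sigma)]),
        pi=np.asarray(pi, float),
    )
    m.weights_ = m._params_.pi
    m.converged_ = True
    return m


def test_mixture_equals_enumeration_on_tiny_instance():
    """Total mixture likelihood = per-patient sum over group assignments."""
    rng = np.random.default_rng(9)
    X = np.maximum(rng.normal(5, 6, size=(3, 4)), 0.0)
    beta = [[1.0, 0.5], [2.0, -1.0]]
    pi = [0.3, 0.7]
    m = _manual_model(beta, pi, 0.5, poly_order=1)
    model_ll = m.score(X) * X.shape[0]
    oracle = 0.0
    for i in range(3):
        per_group = [
            math.log(pi[j]) + naive_patient_loglik(X[i], beta[j], 0.5) for j in range(2)
        ]
        oracle += math.log(sum(math.exp(v) for v in per_group))
    assert model_ll == pytest.approx(oracle, abs=1e-10)


def test_label_permutation_leaves_likelihood_unchanged():
    rng = np.random.default_rng(4)
    X = np.maximum(rng.normal(8, 6, size=(10, 6)), 0.0)
    beta = [[1.0, 0.0], [2.5, 1.0]]
    a = _manual_model(beta, [0.4, 0.6], 0.5, poly_order=1)
    b = _manual_model(beta[::-1], [0.6, 0.4], 0.5, poly_order=1)
    assert a.score(X) == pytest.approx(b.score(X), abs=1e-12)


def test_single_group_equals_pooled_regression():
    """K=1, identity transform, no censoring: EM = ordinary least squares."""
    rng = np.random.default_rng(17)
    n, T = 80, 12
    t = np.arange(T) / 107.0
    X = 50 + 30 * t[None, :] + rng.normal(0, 2, size=(n, T))  # all positive
    m = GroupTrajectoryModel(
        n_groups=1, poly_order=1, transform="identity", censor_lower=-np.inf,
        n_starts=1, random_state=0,
    ).fit(X)
    design = np.column_stack([np.ones(n * T), np.tile(t, n)])
    y = X.ravel()
    beta_ols, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta_ols
    sigma_ml = math.sqrt(float(resid @ resid) / len(y))
    np.testing.assert_allclose(m.coefficients_[0], beta_ols, atol=1e-6)
    assert m.sigma_ == pytest.approx(sigma_ml, abs=1e-6)
    assert m.converged_


@pytest.fixture(scope="module")
def recovery_fit():
    X, _, labels = simulate_dose_series(
        n_patients=800, n_windows=24,
        mixture=RECOVERY_TRUTH["mixture"],
        poly_coeffs=RECOVERY_TRUTH["poly_coeffs"],
        sigma=RECOVERY_TRUTH["sigma"],
        seed=101,
    )
    model = GroupTrajectoryModel(
        n_groups=3, poly_order=1, n_starts=3, random_state=5
    ).fit(X)
    return X, labels, model


def test_em_monotone_and_recovers_truth(recovery_fit):
    X, labels, m = recovery_fit
    assert (np.diff(m.loglik_history_) >= -1e-8).all()
    assert m.converged_
    # canonical order = ascending fitted dose = generator group order here
    np.testing.assert_allclose(m.weights_, RECOVERY_TRUTH["mixture"], atol=0.05)
    np.testing.assert_allclose(
        m.coefficients_[:, 0], [b[0] for b in RECOVERY_TRUTH["poly_coeffs"]], atol=0.1
    )
    assert adjusted_rand_score(labels, m.predict(X)) > 0.9


def test_restart_stability(recovery_fit):
    X, _, m = recovery_fit
    other = GroupTrajectoryModel(n_groups=3, poly_order=1, n_starts=3, random_state=99).fit(X)
    assert other.log_likelihood_ == pytest.approx(m.log_likelihood_, rel=1e-6)


def test_posterior_assignment(recovery_fit):
    X, labels, m = recovery_fit
    table = posterior_assign(m, X, patient_ids=[f"P{i}" for i in range(len(X))])
    probs = table[[f"p_{j}" for j in range(3)]].to_numpy()
    np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)
    assert (table["modal_group"] == probs.argmax(axis=1)).all()
    # a patient deep inside the top group is assigned with near certainty
    deep = np.argmax(np.nanmean(X, axis=1))
    assert table.loc[deep, "modal_group"] == 2
    assert table.loc[deep, "max_posterior"] > 0.99


def test_posterior_single_group_is_unit():
    X = np.maximum(np.random.default_rng(0).normal(5, 3, size=(20, 5)), 0.0)
    m = GroupTrajectoryModel(n_groups=1, poly_order=0, n_starts=1, random_state=0).fit(X)
    np.testing.assert_allclose(m.predict_proba(X), 1.0)


def test_tie_breaks_toward_lower_group_index():
    # two symmetric groups; a patient exactly between them
    m = _manual_model([[1.0], [3.0]], [0.5, 0.5], 0.5, poly_order=0)
    X = np.array([[math.expm1(2.0)]])
    post = m.predict_proba(X)
    np.testing.assert_allclose(post, [[0.5, 0.5]], atol=1e-12)
    assert m.predict(X)[0] == 0


def test_predicted_trajectory_flat_group_and_zero_confidence(recovery_fit):
    X, _, m = recovery_fit
    curve = m.predicted_trajectory(0, confidence=0.0)
    expected = np.expm1(np.polyval(m.coefficients_[0][::-1], np.arange(24) / 107.0))
    np.testing.assert_allclose(curve["mean"], expected, rtol=1e-10)
    np.testing.assert_allclose(curve["lower"], curve["mean"])
    np.testing.assert_allclose(curve["upper"], curve["mean"])


def test_predicted_trajectory_band_covers_truth(recovery_fit):
    X, _, m = recovery_fit
    t = np.arange(24) / 107.0
    for j, coeffs in enumerate(RECOVERY_TRUTH["poly_coeffs"]):
        curve = m.predicted_trajectory(j, confidence=0.99)
        truth = np.expm1(np.polyval(np.asarray(coeffs)[::-1], t))
        covered = (curve["lower"] <= truth) & (truth <= curve["upper"])
        assert covered.mean() >= 0.9, j


def test_select_model_trivial_grid(recovery_fit):
    X, _, _ = recovery_fit
    sel = select_model(X[:100], k_grid=(1,), poly_orders=(1,), n_starts=1, random_state=0)
    assert sel.chosen.n_groups == 1
    assert len(sel.table) == 1


def test_select_model_prefers_one_group_for_flat_data():
    X, _, _ = simulate_dose_series(
        n_patients=300, n_windows=10, mixture=(1.0,),
        poly_coeffs=((2.0, 0.0),), sigma=0.3, seed=7,
    )
    sel = select_model(X, k_grid=(1, 2), poly_orders=(1,), n_starts=2, random_state=0)
    assert sel.chosen.n_groups == 1
    assert sel.table.iloc[0]["bic"] <= sel.table["bic"].min() + 1e-9


def test_empty_k_grid_rejected():
    with pytest.raises(ValueError):
        select_model(np.ones((5, 3)), k_grid=())


def test_covariate_effect_estimation():
    X, C, labels = simulate_dose_series(
        n_patients=600, n_windows=18,
        mixture=(0.5, 0.5),
        poly_coeffs=((1.0, 0.0), (3.0, 1.0)),
        sigma=0.3,
        covariate_effects=(0.0, 0.4),
        stimulant_rates=(0.05, 0.15),
        seed=23,
    )
    m = GroupTrajectoryModel(
        n_groups=2, poly_order=1, include_covariate=True, n_starts=2, random_state=3
    ).fit(X, C)
    assert m.covariate_effects_ is not None
    # canonical order: group 1 (higher dose) carries the positive effect
    assert m.covariate_effects_[1] == pytest.approx(0.4, abs=0.1)
    assert abs(m.covariate_effects_[0]) < 0.1
    assert (np.diff(m.loglik_history_) >= -1e-8).all()


def test_all_collapse_raises_convergence_error():
    X = np.full((4, 3), 5.0)  # four identical flat patients, K=3 cannot survive
    with pytest.raises((ConvergenceError, ValueError)):
        GroupTrajectoryModel(n_groups=3, poly_order=0, n_starts=2, random_state=0).fit(
            X + np.random.default_rng(0).normal(0, 1e-6, X.shape)
        )
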