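"""Group-based trajectory modelling (GBTM) for semicontinuous dose series.

The model is a K-component finite mixture in which latent group *j* follows
its own polynomial mean trajectory on a transformed dose scale.  With
``y* = log(1 + MME)`` (default transform) and a lower censoring bound at
``y* = 0`` (zero-dose months), the per-observation density for group *j* is
censored normal:

    y*_it > c:  phi((y*_it - mu_jt) / sigma) / sigma
    y*_it = c:  Phi((c - mu_jt) / sigma)

    mu_jt = beta_j' x_t + alpha_j * cov_it,
    x_t   = (1, t, t^2, ...),  t = window / time_scale in [0, 1].

Patients are independent; a patient's group log-likelihood sums over their
observed windows, and the mixture weights pi_j are shared.  Estimation is by
EM: the E-step computes posterior group memberships, the M-step maximises the
expected complete-data log-likelihood by weighted censored-normal (Tobit)
Newton updates (closed-form weighted least squares when nothing is censored),
and the mixture weights update to the mean posteriors.  Model choice across
K and polynomial order uses BIC = -2 log L + k ln N with N the number of
patients.

The estimator follows scikit-learn conventions: ``fit(X, C)`` on an
(n_patients, n_windows) matrix of mean daily MME (NaN marks unobserved
windows), fitted attributes carry trailing underscores, and
``predict_proba``/``predict`` return posterior memberships / modal groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import log_ndtr, logsumexp
from scipy.stats import norm
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans

from .errors import ConvergenceError, DomainError, SelectionError

_LOG2PI = math.log(2.0 * math.pi)

TRANSFORMS = {
    "log1p": (np.log1p, np.expm1),
    "identity": (lambda v: np.asarray(v, float), lambda v: np.asarray(v, float)),
}


def _check_transform(name):
    if name not in TRANSFORMS:
        raise ValueError(f"transform must be one of {tuple(TRANSFORMS)}")
    return TRANSFORMS[name]


@dataclass
class _ModelData:
    """Long-format arrays for one dataset."""

    y: np.ndarray      # transformed dose per observation
    pidx: np.ndarray   # patient index per observation
    P: np.ndarray      # polynomial design rows
    c: np.ndarray | None  # covariate per observation
    cens: np.ndarray   # censored indicator (y at the lower bound)
    n: int
    T: int


def _prepare(X, C, transform, censor_lower, poly_order, time_scale) -> _ModelData:
    X = np.asarray(X, float)
    if X.ndim != 2:
        raise ValueError("X must be 2-d (patients x windows)")
    fwd, _ = _check_transform(transform)
    mask = np.isfinite(X)
    if not mask.any(axis=1).all():
        raise ValueError("every patient needs at least one observed window")
    pidx, tvec = np.nonzero(mask)
    y = fwd(X[mask])
    P = np.vander(tvec / time_scale, poly_order + 1, increasing=True)
    c = None
    if C is not None:
        C = np.asarray(C, float)
        if C.shape != X.shape:
            raise ValueError("C must have the same shape as X")
        c = C[mask]
        if not np.isfinite(c).all():
            raise ValueError("covariate missing on an observed window")
    cens = y <= censor_lower + 1e-12
    return _ModelData(y=y, pidx=pidx, P=P, c=c, cens=cens, n=X.shape[0], T=X.shape[1])


def _obs_terms(y, mu, sigma, cens, censor_lower):
    """Per-observation censored-normal log density."""
    z = (y - mu) / sigma
    dens = -0.5 * z * z - math.log(sigma) - 0.5 * _LOG2PI
    if cens.any():
        zc = (censor_lower - mu) / sigma
        return np.where(cens, log_ndtr(zc), dens)
    return dens


def _obs_derivs(y, mu, sigma, cens, censor_lower):
    """First/second derivatives of the log density wrt mu and log sigma."""
    r = (y - mu) / sigma
    dmu = r / sigma
    dls = r * r - 1.0
    d2mu = np.full_like(r, -1.0 / sigma**2)
    d2mls = -2.0 * r / sigma
    d2ls = -2.0 * r * r
    if cens.any():
        z = (censor_lower - mu[cens]) / sigma
        h = np.exp(-0.5 * z * z - 0.5 * _LOG2PI - log_ndtr(z))  # phi/Phi
        u = 1.0 - z * (z + h)
        dmu[cens] = -h / sigma
        dls[cens] = -z * h
        d2mu[cens] = -h * (z + h) / sigma**2
        d2mls[cens] = h * u / sigma
        d2ls[cens] = z * h * u
    return dmu, dls, d2mu, d2mls, d2ls


class _Collapse(Exception):
    def __init__(self, params, ll, history):
        self.params, self.ll, self.history = params, ll, history


@dataclass
class _Params:
    beta: np.ndarray            # (K, nb)
    alpha: np.ndarray | None    # (K,) or (1,) when shared; None without covariate
    logsig: np.ndarray          # (1,) shared or (K,)
    pi: np.ndarray              # (K,)


def patient_group_loglik(
    values,
    beta,
    sigma,
    covariates=None,
    alpha=0.0,
    transform="log1p",
    censor_lower=0.0,
    time_scale=107.0,
) -> float:
    """Censored-normal log density of one patient's series under one group.

    ``values`` are original-scale doses for windows 0..T-1 (NaN = unobserved);
    ``beta`` the group's polynomial coefficients on the transformed scale.
    """
    if sigma <= 0:
        raise DomainError("sigma must be positive")
    fwd, _ = _check_transform(transform)
    values = np.asarray(values, float)
    obs = np.isfinite(values)
    t = np.nonzero(obs)[0] / time_scale
    y = fwd(values[obs])
    mu = np.vander(t, len(np.atleast_1d(beta)), increasing=True) @ np.atleast_1d(beta)
    if covariates is not None:
        mu = mu + alpha * np.asarray(covariates, float)[obs]
    cens = y <= censor_lower + 1e-12
    return float(_obs_terms(y, mu, sigma, cens, censor_lower).sum())


class GroupTrajectoryModel(BaseEstimator):
    """Censored-normal group-based trajectory mixture with EM fitting.

    Parameters
    ----------
    n_groups : int
        Number of latent trajectory groups K.
    poly_order : int
        Polynomial order of the mean trajectory (same for all groups, 0-3).
    include_covariate : bool
        If True, ``fit`` requires a covariate matrix ``C`` (e.g. cumulative
        stimulant count) entering the group means linearly.
    shared_covariate : bool
        Single covariate coefficient shared by all groups instead of one per
        group.
    transform : {"log1p", "identity"}
        Dose-scale transform; the censoring bound applies on this scale.
    censor_lower : float
        Lower censoring bound on the transformed scale (transform(0) = 0).
    per_group_sigma : bool
        One residual SD per group instead of a shared SD.
    n_starts : int
        EM restarts from k-means++ initialisations of per-patient summaries.
    time_scale : float
        Window index divisor mapping the full horizon onto [0, 1].

    Attributes (after ``fit``)
    --------------------------
    weights_, coefficients_, covariate_effects_, sigma_, log_likelihood_,
    loglik_history_, n_iter_, converged_, n_params_, bic_, n_patients_,
    n_windows_.
    """

    def __init__(
        self,
        n_groups=2,
        poly_order=2,
        include_covariate=False,
        shared_covariate=False,
        transform="log1p",
        censor_lower=0.0,
        per_group_sigma=False,
        n_starts=5,
        max_iter=200,
        tol=1e-7,
        time_scale=107.0,
        random_state=None,
    ):
        self.n_groups = n_groups
        self.poly_order = poly_order
        self.include_covariate = include_covariate
        self.shared_covariate = shared_covariate
        self.transform = transform
        self.censor_lower = censor_lower
        self.per_group_sigma = per_group_sigma
        self.n_starts = n_starts
        self.max_iter = max_iter
        self.tol = tol
        self.time_scale = time_scale
        self.random_state = random_state

    # ------------------------------------------------------------------ util
    def _layout(self):
        """Index layout of the stacked M-step parameter vector."""
        nb = self.poly_order + 1
        K = self.n_groups
        a_dim = 0
        if self.include_covariate:
            a_dim = 1 if self.shared_covariate else K
        s_dim = K if self.per_group_sigma else 1
        return nb, K, a_dim, s_dim

    def _pack(self, params: _Params) -> np.ndarray:
        parts = [params.beta.ravel()]
        if params.alpha is not None:
            parts.append(params.alpha)
        parts.append(params.logsig)
        return np.concatenate(parts)

    def _unpack(self, theta: np.ndarray, pi) -> _Params:
        nb, K, a_dim, s_dim = self._layout()
        beta = theta[: K * nb].reshape(K, nb)
        pos = K * nb
        alpha = theta[pos : pos + a_dim] if a_dim else None
        pos += a_dim
        logsig = theta[pos : pos + s_dim]
        return _Params(beta=beta, alpha=alpha, logsig=logsig, pi=np.asarray(pi))

    def _group_mu(self, data: _ModelData, params: _Params, j: int) -> np.ndarray:
        mu = data.P @ params.beta[j]
        if params.alpha is not None:
            a = params.alpha[0] if self.shared_covariate else params.alpha[j]
            mu = mu + a * data.c
        return mu

    def _group_sigma(self, params: _Params, j: int) -> float:
        ls = params.logsig[j] if self.per_group_sigma else params.logsig[0]
        return float(np.exp(ls))

    # ---------------------------------------------------------------- E-step
    def _loglik_matrix(self, data: _ModelData, params: _Params) -> np.ndarray:
        K = self.n_groups
        L = np.empty((data.n, K))
        for j in range(K):
            terms = _obs_terms(
                data.y, self._group_mu(data, params, j), self._group_sigma(params, j),
                data.cens, self.censor_lower,
            )
            L[:, j] = np.bincount(data.pidx, weights=terms, minlength=data.n)
        return L

    def _estep(self, data, params):
        logw = np.log(params.pi)[None, :] + self._loglik_matrix(data, params)
        norm_ = logsumexp(logw, axis=1)
        post = np.exp(logw - norm_[:, None])
        return float(norm_.sum()), post

    # ---------------------------------------------------------------- M-step
    def _qvalue(self, data, theta, W):
        params = self._unpack(theta, None)
        q = 0.0
        for j in range(self.n_groups):
            terms = _obs_terms(
                data.y, self._group_mu(data, params, j), self._group_sigma(params, j),
                data.cens, self.censor_lower,
            )
            q += float(W[:, j] @ terms)
        return q

    def _qgrad_hess(self, data, theta, W):
        nb, K, a_dim, s_dim = self._layout()
        d = K * nb + a_dim + s_dim
        g = np.zeros(d)
        H = np.zeros((d, d))
        params = self._unpack(theta, None)
        for j in range(K):
            w = W[:, j]
            mu = self._group_mu(data, params, j)
            sig = self._group_sigma(params, j)
            dmu, dls, d2mu, d2mls, d2ls = _obs_derivs(
                data.y, mu, sig, data.cens, self.censor_lower
            )
            bsl = slice(j * nb, (j + 1) * nb)
            ai = K * nb + (0 if self.shared_covariate else j) if a_dim else None
            si = K * nb + a_dim + (j if self.per_group_sigma else 0)
            wd = w * dmu
            g[bsl] += data.P.T @ wd
            g[si] += float(w @ dls)
            Pw = data.P * (w * d2mu)[:, None]
            H[bsl, bsl.start : bsl.stop] += data.P.T @ Pw
            hbs = data.P.T @ (w * d2mls)
            H[bsl, si] += hbs
            H[si, bsl] += hbs
            H[si, si] += float(w @ d2ls)
            if ai is not None:
                g[ai] += float(wd @ data.c)
                hba = data.P.T @ (w * d2mu * data.c)
                H[bsl, ai] += hba
                H[ai, bsl] += hba
                H[ai, ai] += float((w * d2mu) @ (data.c * data.c))
                has_ = float((w * d2mls) @ data.c)
                H[ai, si] += has_
                H[si, ai] += has_
        return g, H

    def _mstep_closed_form(self, data, W, theta):
        """Exact weighted-LS M-step, valid when no observation is censored."""
        nb, K, a_dim, s_dim = self._layout()
        beta = np.empty((K, nb))
        alpha = np.empty(K) if a_dim else None
        rss = np.zeros(K)
        wsum = np.zeros(K)
        Z = data.P if not a_dim else np.column_stack([data.P, data.c])
        for j in range(K):
            w = W[:, j]
            Zw = Z * w[:, None]
            coef, *_ = np.linalg.lstsq(Zw.T @ Z, Zw.T @ data.y, rcond=None)
            beta[j] = coef[:nb]
            if a_dim:
                alpha[j] = coef[nb]
            r = data.y - Z @ coef
            rss[j] = float(w @ (r * r))
            wsum[j] = float(w.sum())
        if self.per_group_sigma:
            logsig = 0.5 * np.log(np.maximum(rss / np.maximum(wsum, 1e-12), 1e-12))
        else:
            logsig = np.array([0.5 * math.log(max(rss.sum() / len(data.y), 1e-12))])
        return np.concatenate(
            [beta.ravel()] + ([alpha] if a_dim else []) + [logsig]
        )

    def _mstep(self, data, post, theta):
        W = post[data.pidx]  # per-observation weights
        if not data.cens.any() and not (self.include_covariate and self.shared_covariate):
            return self._mstep_closed_form(data, W, theta)
        q = self._qvalue(data, theta, W)
        for _ in range(8):  # generalized EM: a few ascent steps suffice
            g, H = self._qgrad_hess(data, theta, W)
            if np.max(np.abs(g)) < 1e-9 * (1.0 + abs(q)):
                break
            A = -H
            lam = 0.0
            for _trial in range(8):
                try:
                    step = np.linalg.solve(A + lam * np.eye(len(A)), g)
                except np.linalg.LinAlgError:
                    step = None
                if step is not None and np.isfinite(step).all():
                    new = theta + step
                    s_dim = self._layout()[3]
                    new[-s_dim:] = np.clip(new[-s_dim:], -10.0, 5.0)  # log sigma bounds
                    qn = self._qvalue(data, new, W)
                    if np.isfinite(qn) and qn >= q - 1e-12:
                        theta, q = new, qn
                        break
                lam = max(lam * 10.0, 1e-4 * (1.0 + np.abs(np.diag(A)).max()))
            else:
                # Newton failed to improve: fall back to damped gradient steps
                scale = 1.0 / (1.0 + np.abs(np.diag(H)).max())
                improved = False
                for _half in range(20):
                    new = theta + scale * g
                    qn = self._qvalue(data, new, W)
                    if np.isfinite(qn) and qn > q:
                        theta, q, improved = new, qn, True
                        break
                    scale *= 0.5
                if not improved:
                    break
        return theta

    # ------------------------------------------------------------------ init
    def _patient_features(self, data: _ModelData) -> np.ndarray:
        n = data.n
        sums = np.bincount(data.pidx, weights=data.y, minlength=n)
        cnts = np.bincount(data.pidx, minlength=n).astype(float)
        mean = sums / cnts
        t = data.P[:, 1] if data.P.shape[1] > 1 else np.zeros(len(data.y))
        tbar = np.bincount(data.pidx, weights=t, minlength=n) / cnts
        dt = t - tbar[data.pidx]
        dy = data.y - mean[data.pidx]
        num = np.bincount(data.pidx, weights=dt * dy, minlength=n)
        den = np.bincount(data.pidx, weights=dt * dt, minlength=n)
        slope = np.divide(num, den, out=np.zeros(n), where=den > 1e-12)
        feats = np.column_stack([mean, slope])
        sd = feats.std(axis=0)
        sd[sd == 0] = 1.0
        return (feats - feats.mean(axis=0)) / sd

    def _init_params(self, data: _ModelData, seed: int) -> _Params:
        nb, K, a_dim, s_dim = self._layout()
        if K == 1:
            labels = np.zeros(data.n, dtype=int)
        else:
            feats = self._patient_features(data)
            km = KMeans(n_clusters=K, n_init=1, init="k-means++", random_state=seed)
            labels = km.fit_predict(feats)
        beta = np.zeros((K, nb))
        rss, nobs = 0.0, 0
        Z = data.P
        for j in range(K):
            rows = labels[data.pidx] == j
            if rows.sum() < nb + 1:
                rows = np.ones(len(data.y), bool)
            coef, *_ = np.linalg.lstsq(Z[rows], data.y[rows], rcond=None)
            beta[j] = coef
            r = data.y[rows] - Z[rows] @ coef
            rss += float(r @ r)
            nobs += int(rows.sum())
        sig = max(math.sqrt(rss / max(nobs, 1)), 0.05)
        logsig = np.full(s_dim, math.log(sig))
        alpha = np.zeros(a_dim) if a_dim else None
        counts = np.bincount(labels, minlength=K).astype(float)
        pi = np.maximum(counts, 0.5) / np.maximum(counts, 0.5).sum()
        return _Params(beta=beta, alpha=alpha, logsig=logsig, pi=pi)

    # -------------------------------------------------------------------- EM
    def _run_em(self, data: _ModelData, seed: int):
        params = self._init_params(data, seed)
        history: list[float] = []
        ll_prev = -np.inf
        converged = False
        for it in range(self.max_iter):
            ll, post = self._estep(data, params)
            history.append(ll)
            if abs(ll - ll_prev) <= self.tol * (1.0 + abs(ll)):
                converged = True
                break
            ll_prev = ll
            pi = post.mean(axis=0)
            if np.min(pi) < 1.0 / data.n:
                raise _Collapse(params, ll, history)
            theta = self._mstep(data, post, self._pack(params))
            params = self._unpack(theta, pi)
        return params, history[-1], history, len(history), converged

    def fit(self, X, C=None, y=None):
        """Fit the mixture to dose series ``X`` (original scale, NaN-padded)."""
        if self.include_covariate and C is None:
            raise ValueError("include_covariate=True requires a covariate matrix C")
        data = _prepare(
            X, C if self.include_covariate else None,
            self.transform, self.censor_lower, self.poly_order, self.time_scale,
        )
        if data.n < self.n_groups:
            raise ValueError("need at least n_groups patients")
        seeds = np.random.SeedSequence(self.random_state).generate_state(max(self.n_starts, 1))
        best = None
        partial = None
        for s in seeds:
            seed = int(s % (2**31 - 1))
            try:
                result = self._run_em(data, seed)
            except _Collapse as col:
                if partial is None or col.ll > partial[1]:
                    partial = (col.params, col.ll, col.history)
                continue
            if best is None or result[1] > best[1]:
                best = result
        if best is None:
            self._finalize(data, partial[0], partial[1], partial[2], len(partial[2]), False)
            raise ConvergenceError(
                "all EM restarts collapsed to an empty group", best_model=self
            )
        self._finalize(data, *best)
        return self

    def _finalize(self, data, params, ll, history, n_iter, converged):
        nb, K, a_dim, s_dim = self._layout()
        _, inv = _check_transform(self.transform)
        grid = np.vander(np.arange(data.T) / self.time_scale, nb, increasing=True)
        level = inv(grid @ params.beta.T).mean(axis=0)  # mean fitted dose per group
        order = np.argsort(level, kind="stable")
        beta = params.beta[order]
        pi = params.pi[order]
        alpha = None
        if params.alpha is not None:
            alpha = params.alpha if self.shared_covariate else params.alpha[order]
        logsig = params.logsig[order] if self.per_group_sigma else params.logsig

        self.weights_ = pi
        self.coefficients_ = beta
        self.covariate_effects_ = (
            None if alpha is None else (np.repeat(alpha, K) if self.shared_covariate else alpha)
        )
        self.sigma_ = np.exp(logsig) if self.per_group_sigma else float(np.exp(logsig[0]))
        self.log_likelihood_ = float(ll)
        self.loglik_history_ = list(history)
        self.n_iter_ = int(n_iter)
        self.converged_ = bool(converged)
        self.n_params_ = K * nb + a_dim + s_dim + (K - 1)
        self.n_patients_ = int(data.n)
        self.n_windows_ = int(data.T)
        self.bic_ = float(-2.0 * ll + self.n_params_ * math.log(data.n))
        self._params_ = _Params(beta=beta, alpha=alpha, logsig=logsig, pi=pi)
        self._data_ = data
        return self

    # ------------------------------------------------------------- inference
    def _check_fitted(self):
        if not hasattr(self, "weights_"):
            raise AttributeError("model is not fitted")

    def predict_proba(self, X, C=None) -> np.ndarray:
        """Posterior group-membership probabilities, one row per patient."""
        self._check_fitted()
        data = _prepare(
            X, C if self.include_covariate else None,
            self.transform, self.censor_lower, self.poly_order, self.time_scale,
        )
        _, post = self._estep(data, self._params_)
        return post

    def predict(self, X, C=None) -> np.ndarray:
        """Modal group per patient; ties break toward the lower group index."""
        return np.argmax(self.predict_proba(X, C), axis=1)

    def score(self, X, C=None) -> float:
        """Mean per-patient observed-data log-likelihood."""
        self._check_fitted()
        data = _prepare(
            X, C if self.include_covariate else None,
            self.transform, self.censor_lower, self.poly_order, self.time_scale,
        )
        ll, _ = self._estep(data, self._params_)
        return ll / data.n

    # ---- observed information ------------------------------------------
    def _full_theta(self):
        eta = np.log(self._params_.pi[:-1]) - math.log(self._params_.pi[-1])
        return np.concatenate([self._pack(self._params_), eta])

    def _obs_grad(self, theta_full):
        nb, K, a_dim, s_dim = self._layout()
        d = K * nb + a_dim + s_dim
        eta = np.concatenate([theta_full[d:], [0.0]])
        pi = np.exp(eta - logsumexp(eta))
        params = self._unpack(theta_full[:d], pi)
        data = self._data_
        _, post = self._estep(data, params)
        g, _ = self._qgrad_hess(data, theta_full[:d], post[data.pidx])
        # mixture-logit block
        g_eta = (post.mean(axis=0) - pi)[:-1] * data.n
        return np.concatenate([g, g_eta])

    def parameter_covariance(self) -> tuple[np.ndarray, list[str]]:
        """Observed-information covariance of all fitted parameters.

        Gradient by the Fisher identity (posterior-weighted complete-data
        score); Hessian by central finite differences of that gradient.
        """
        self._check_fitted()
        theta = self._full_theta()
        d = len(theta)
        H = np.empty((d, d))
        h = 1e-5 * np.maximum(1.0, np.abs(theta))
        for k in range(d):
            tp, tm = theta.copy(), theta.copy()
            tp[k] += h[k]
            tm[k] -= h[k]
            H[:, k] = (self._obs_grad(tp) - self._obs_grad(tm)) / (2 * h[k])
        H = 0.5 * (H + H.T)
        cov = np.linalg.pinv(-H)
        nb, K, a_dim, s_dim = self._layout()
        names = [f"beta_{j}_{p}" for j in range(K) for p in range(nb)]
        if a_dim == 1:
            names += ["alpha"]
        else:
            names += [f"alpha_{j}" for j in range(a_dim)]
        names += (["log_sigma"] if s_dim == 1 else [f"log_sigma_{j}" for j in range(s_dim)])
        names += [f"eta_{j}" for j in range(K - 1)]
        return cov, names

    def covariate_effect_se(self) -> np.ndarray:
        """Standard errors of the per-group covariate coefficients."""
        cov, names = self.parameter_covariance()
        idx = [i for i, n in enumerate(names) if n.startswith("alpha")]
        se = np.sqrt(np.maximum(np.diag(cov)[idx], 0.0))
        return np.repeat(se, self.n_groups) if self.shared_covariate else se

    def predicted_trajectory(
        self, group: int, covariate_path=None, confidence: float = 0.99
    ) -> pd.DataFrame:
        """Fitted mean dose curve (original scale) with a delta-method band."""
        self._check_fitted()
        if not self.converged_:
            raise ConvergenceError("predicted_trajectory requires a converged model")
        if not 0 <= group < self.n_groups:
            raise ValueError("group out of range")
        nb, K, a_dim, s_dim = self._layout()
        T = self.n_windows_
        grid = np.vander(np.arange(T) / self.time_scale, nb, increasing=True)
        path = np.zeros(T) if covariate_path is None else np.asarray(covariate_path, float)
        mu = grid @ self.coefficients_[group]
        G = grid
        if self.include_covariate:
            a = self.covariate_effects_[group]
            mu = mu + a * path
            G = np.column_stack([grid, path])
        if confidence <= 0:
            sd = np.zeros(T)
        else:
            cov, names = self.parameter_covariance()
            idx = list(range(group * nb, (group + 1) * nb))
            if self.include_covariate:
                idx.append(K * nb + (0 if self.shared_covariate else group))
            sub = cov[np.ix_(idx, idx)]
            sd = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", G, sub, G), 0.0))
        z = norm.ppf(0.5 + confidence / 2.0) if confidence > 0 else 0.0
        _, inv = _check_transform(self.transform)
        return pd.DataFrame(
            {
                "window": np.arange(T),
                "mean": inv(mu),
                "lower": inv(mu - z * sd),
                "upper": inv(mu + z * sd),
            }
        )


# ---------------------------------------------------------------------------
# Functional wrappers
# ---------------------------------------------------------------------------

def fit_gbtm(X, C=None, **kwargs) -> GroupTrajectoryModel:
    """Fit a :class:`GroupTrajectoryModel`; keyword args are estimator params."""
    return GroupTrajectoryModel(**kwargs).fit(X, C)


@dataclass
class SelectionTable:
    """BIC comparison of candidate specifications; ``chosen`` minimises BIC."""

    table: pd.DataFrame
    chosen: GroupTrajectoryModel
    models: dict = field(default_factory=dict)


def select_model(
    X,
    C=None,
    k_grid=(1, 2, 3, 4, 5),
    poly_orders=(2,),
    keep_models: bool = False,
    **kwargs,
) -> SelectionTable:
    """Fit every (K, order) candidate and choose the converged fit with minimal BIC."""
    if not len(k_grid):
        raise ValueError("k_grid must be nonempty")
    rows = []
    best = None
    models = {}
    for K in k_grid:
        for order in poly_orders:
            model = GroupTrajectoryModel(n_groups=K, poly_order=order, **kwargs)
            try:
                model.fit(X, C)
                ok = model.converged_
            except ConvergenceError:
                ok = False
            ll = getattr(model, "log_likelihood_", np.nan)
            bic = getattr(model, "bic_", np.nan)
            rows.append((K, order, getattr(model, "n_params_", np.nan), ll, bic, ok))
            if keep_models:
                models[(K, order)] = model
            if ok and (best is None or bic < best.bic_):
                best = model
    table = pd.DataFrame(
        rows, columns=["n_groups", "poly_order", "n_params", "log_likelihood", "bic", "converged"]
    ).sort_values("bic", kind="stable").reset_index(drop=True)
    if best is None:
        raise SelectionError("no candidate specification converged")
    return SelectionTable(table=table, chosen=best, models=models)


def posterior_assign(model: GroupTrajectoryModel, X, C=None, patient_ids=None) -> pd.DataFrame:
    """Posterior membership table: probabilities, modal group and its probability."""
    if not model.converged_:
        raise ConvergenceError("posterior_assign requires a converged model")
    post = model.predict_proba(X, C)
    n, K = post.shape
    ids = list(patient_ids) if patient_ids is not None else list(range(n))
    out = pd.DataFrame({"patient_id": ids})
    for j in range(K):
        out[f"p_{j}"] = post[:, j]
    out["modal_group"] = np.argmax(post, axis=1)
    out["max_posterior"] = post.max(axis=1)
    return out


def predicted_trajectory(model, group, covariate_path=None, confidence=0.99) -> pd.DataFrame:
    return model.predicted_trajectory(group, covariate_path, confidence)
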