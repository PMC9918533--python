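"""Nonlinear mixed-effects disease progression model (disease course map).

Each endpoint k follows a population logistic curve on the (0, 1)
pathology scale, with its own progression rate ``a_k`` and inflexion
delay ``delta_k`` relative to a reference age ``t0``.  A subject warps
the common time line through an acceleration factor ``exp(xi)`` and a
time shift ``tau``::

    psi(t)   = t0 + exp(xi) * (t - t0 - tau)
    curve_k  = sigmoid( a_k * (psi - t0 - delta_k) + w_k )

and shifts the relative severity of the endpoints through a space shift
``w = A @ s`` lying in the low-rank column space of the mixing matrix
``A`` (q source dimensions).  Observations are the curves plus
independent Gaussian noise per endpoint; missing entries simply drop out
of the likelihood, so neither calibration nor personalization requires
imputation.

Identifiability conventions: ``mean(delta) = 0`` (ties t0 to the average
inflexion age), columns of ``A`` orthogonal to the rate vector
``(a_1..a_K)`` (separates presentation from dynamics), random effects
zero-mean.

Calibration alternates joint penalized least squares over fixed and
individual effects (L-BFGS with analytic gradients) with closed-form
variance updates; individual-effect variances use a Laplace correction
(MAP second moment plus posterior variance) so that weakly informative
subjects do not bias the heterogeneity estimates downwards.
Personalization of an unseen subject is the MAP estimate of
``(xi, tau, s)`` under the learnt random-effect prior.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .preprocessing import EndpointNormalizer
from .registry import EndpointRegistry, default_registry


class CalibrationError(RuntimeError):
    """Raised when model calibration cannot proceed; carries diagnostics."""


@dataclass
class PopulationParams:
    """Fixed effects and random-effect scales of the progression model."""

    t0: float
    delta: np.ndarray          # (K,) inflexion delays, mean 0
    rates: np.ndarray          # (K,) logistic rates a_k > 0, per year
    mixing: np.ndarray         # (K, q) space-shift mixing matrix
    sigma_xi: float            # s.d. of log-acceleration
    sigma_tau: float           # s.d. of time shift (years)
    sigma_noise: np.ndarray    # (K,) residual s.d. on the (0,1) scale
    endpoints: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.delta = np.asarray(self.delta, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        self.mixing = np.asarray(self.mixing, dtype=float)
        self.sigma_noise = np.asarray(self.sigma_noise, dtype=float)
        if np.any(self.rates <= 0):
            raise ValueError("progression rates must be positive")
        if self.sigma_xi < 0 or self.sigma_tau < 0 or np.any(self.sigma_noise <= 0):
            raise ValueError("scale parameters must be positive")

    @property
    def n_endpoints(self) -> int:
        return self.rates.size

    @property
    def n_sources(self) -> int:
        return self.mixing.shape[1] if self.mixing.ndim == 2 else 0


@dataclass
class IndividualEffects:
    """Per-subject random effects of the progression model."""

    xi: float                  # log-acceleration
    tau: float                 # time shift (years)
    sources: np.ndarray        # (q,)
    space_shift: np.ndarray    # (K,) w = A @ sources

    def __post_init__(self) -> None:
        self.sources = np.asarray(self.sources, dtype=float)
        self.space_shift = np.asarray(self.space_shift, dtype=float)

    @classmethod
    def null(cls, params: PopulationParams) -> "IndividualEffects":
        return cls(0.0, 0.0, np.zeros(params.n_sources), np.zeros(params.n_endpoints))


def time_reparam(t, xi: float, tau: float, t0: float):
    """Subject-specific disease age: ``t0 + exp(xi) * (t - t0 - tau)``."""
    return t0 + np.exp(xi) * (np.asarray(t, dtype=float) - t0 - tau)


def individual_curve(t, params: PopulationParams, effects: IndividualEffects, k: int):
    """Value of endpoint ``k`` on the (0,1) scale along the subject's curve."""
    psi = time_reparam(t, effects.xi, effects.tau, params.t0)
    u = params.rates[k] * (psi - params.t0 - params.delta[k]) + effects.space_shift[k]
    return expit(u)


def average_instances(forecasts: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Arithmetic mean of forecasts from several model instances.

    All forecasts must share the same ages (index) and endpoints (columns).
    """
    if len(forecasts) == 0:
        raise ValueError("need at least one forecast")
    ref = forecasts[0]
    for f in forecasts[1:]:
        if f.shape != ref.shape or list(f.columns) != list(ref.columns) \
                or not np.allclose(f.index.to_numpy(float), ref.index.to_numpy(float)):
            raise ValueError("forecasts have mismatched ages or endpoints")
    mean = sum(f.to_numpy(dtype=float) for f in forecasts) / len(forecasts)
    return pd.DataFrame(mean, index=ref.index, columns=ref.columns)


# ---------------------------------------------------------------------------
# internal dense representation
# ---------------------------------------------------------------------------

@dataclass
class _Packed:
    ids: list[str]
    T: np.ndarray        # (N, J) ages, padded with 0 where no visit
    Y: np.ndarray        # (N, J, K) values, 0 where unobserved
    M: np.ndarray        # (N, J, K) observation mask


def _pack(df: pd.DataFrame, endpoints: Sequence[str]) -> _Packed:
    ids, groups = [], []
    for sid, grp in df.groupby("subject_id", sort=True):
        ids.append(str(sid))
        groups.append(grp.sort_values("age"))
    N, J, K = len(ids), max(len(g) for g in groups), len(endpoints)
    T = np.zeros((N, J))
    Y = np.zeros((N, J, K))
    M = np.zeros((N, J, K), dtype=bool)
    for i, grp in enumerate(groups):
        n = len(grp)
        T[i, :n] = grp["age"].to_numpy(dtype=float)
        for k, name in enumerate(endpoints):
            if name in grp.columns:
                vals = grp[name].to_numpy(dtype=float)
                obs = np.isfinite(vals)
                Y[i, :n, k] = np.where(obs, vals, 0.0)
                M[i, :n, k] = obs
    return _Packed(ids=ids, T=T, Y=Y, M=M)


def _unpack_theta(theta: np.ndarray, N: int, K: int, q: int):
    t0 = theta[0]
    a = np.exp(theta[1:1 + K])
    draw = theta[1 + K:1 + 2 * K]
    delta = draw - draw.mean()
    off = 1 + 2 * K
    A = theta[off:off + K * q].reshape(K, q)
    off += K * q
    xi = theta[off:off + N]; off += N
    tau = theta[off:off + N]; off += N
    s = theta[off:off + N * q].reshape(N, q)
    return t0, a, delta, A, xi, tau, s


def _objective(theta, packed: _Packed, sig_k, sig_xi, sig_tau, freeze_sources: bool):
    """Penalized weighted SSE and its gradient (variances held fixed)."""
    T, Y, M = packed.T, packed.Y, packed.M
    N, J, K = Y.shape
    q = (theta.size - 1 - 2 * K - 2 * N) // (K + N) if (K + N) else 0
    t0, a, delta, A, xi, tau, s = _unpack_theta(theta, N, K, q)

    phi = np.exp(xi)                              # (N,)
    z = phi[:, None] * (T - t0 - tau[:, None])    # (N, J)
    w = s @ A.T                                   # (N, K)
    u = a[None, None, :] * (z[:, :, None] - delta[None, None, :]) + w[:, None, :]
    p = expit(u)
    r = np.where(M, Y - p, 0.0)
    inv_var = 1.0 / sig_k ** 2                    # (K,)
    loss = 0.5 * np.einsum("ijk,k->", r ** 2, inv_var)
    loss += 0.5 * np.sum(xi ** 2) / sig_xi ** 2
    loss += 0.5 * np.sum(tau ** 2) / sig_tau ** 2
    loss += 0.5 * np.sum(s ** 2)

    G = -(r * p * (1.0 - p)) * inv_var[None, None, :]   # dloss/du, (N,J,K)
    Gk = G.sum(axis=(0, 1))                              # (K,)
    Ga = np.einsum("ijk,k->ij", G, a)                    # (N,J)

    grad_a = np.einsum("ijk,ij->k", G, z) - Gk * delta
    grad_loga = grad_a * a
    grad_delta = -a * Gk
    grad_draw = grad_delta - grad_delta.mean()
    grad_t0 = -float(np.sum(Ga * phi[:, None]))
    grad_tau = -phi * Ga.sum(axis=1) + tau / sig_tau ** 2
    grad_xi = np.einsum("ij,ij->i", Ga, z) + xi / sig_xi ** 2
    Gw = G.sum(axis=1)                                   # (N, K)
    if freeze_sources or q == 0:
        grad_A = np.zeros((K, q))
        grad_s = np.zeros((N, q))
    else:
        grad_A = Gw.T @ s
        grad_s = Gw @ A + s
    grad = np.concatenate([
        [grad_t0], grad_loga, grad_draw, grad_A.ravel(),
        grad_xi, grad_tau, grad_s.ravel()])
    return loss, grad


def _posterior_covariances(packed: _Packed, t0, a, delta, A, xi, tau, s,
                           sig_k, sig_xi, sig_tau) -> np.ndarray:
    """Gauss-Newton (Laplace) posterior covariance of (xi, tau, s) per subject."""
    T, Y, M = packed.T, packed.Y, packed.M
    N, J, K = Y.shape
    q = A.shape[1]
    phi = np.exp(xi)
    z = phi[:, None] * (T - t0 - tau[:, None])
    w = s @ A.T
    u = a[None, None, :] * (z[:, :, None] - delta[None, None, :]) + w[:, None, :]
    p = expit(u)
    d = 2 + q
    D = np.empty((N, J, K, d))
    D[..., 0] = a[None, None, :] * z[:, :, None]
    D[..., 1] = -a[None, None, :] * phi[:, None, None]
    D[..., 2:] = A[None, None, :, :]
    W = np.where(M, (p * (1.0 - p)) ** 2, 0.0) / sig_k[None, None, :] ** 2
    H = np.einsum("ijka,ijk,ijkb->iab", D, W, D)
    prior = np.diag(np.concatenate([[1.0 / sig_xi ** 2, 1.0 / sig_tau ** 2], np.ones(q)]))
    return np.linalg.inv(H + prior[None, :, :])


def _canonicalize(t0, a, delta, A, xi, tau, s):
    """Move to the identifiable representation without changing predictions:
    zero-mean tau and xi (absorbed into t0 and the rates/delays), mixing
    columns orthogonal to the rate vector (parallel part absorbed into tau),
    unit-variance sources (scale absorbed into the mixing columns)."""
    phi = np.exp(xi)
    if A.size:
        c = A.T @ a / (a @ a)                 # (q,) parallel coordinates
        A = A - np.outer(a, c)
        tau = tau - (s @ c) / phi
        std = s.std(axis=0, ddof=0)
        keep = std > 1e-10
        A[:, keep] = A[:, keep] * std[keep]
        s[:, keep] = s[:, keep] / std[keep]
    tbar = tau.mean()
    t0, tau = t0 + tbar, tau - tbar
    xbar = xi.mean()
    a, delta, xi = a * np.exp(xbar), delta * np.exp(-xbar), xi - xbar
    delta = delta - delta.mean()
    return t0, a, delta, A, xi, tau, s


class CourseMap(BaseEstimator):
    """Disease course map estimator with scikit-learn conventions.

    Parameters
    ----------
    n_sources : int
        Dimension q of the presentation (space-shift) subspace.
    max_outer : int
        Maximum outer iterations (joint optimization + variance update).
    inner_maxiter : int
        L-BFGS iterations per joint-optimization call.
    tol : float
        Relative change of the penalized objective that stops the outer loop.
    random_state : int
        Seed for the deterministic, data-driven initialization tie-breaks.
    normalizer : EndpointNormalizer, optional
        When given, ``fit`` expects native-scale data, normalizes internally
        (fitting the normalizer on the training data if necessary) and
        forecasts are returned on the native scale.  Without it the model
        works directly on the (0, 1) scale.
    endpoints : sequence of str, optional
        Endpoint columns to model; defaults to the registry endpoints
        present in the training table.

    Attributes
    ----------
    params_ : PopulationParams
        Fixed effects and random-effect scales after calibration.
    effects_ : dict[str, IndividualEffects]
        MAP random effects of the training subjects.
    history_ : list[float]
        Penalized objective after each outer iteration.
    converged_ : bool
    """

    def __init__(self, n_sources: int = 2, max_outer: int = 30,
                 inner_maxiter: int = 200, tol: float = 1e-6,
                 random_state: int = 0,
                 normalizer: EndpointNormalizer | None = None,
                 endpoints: Sequence[str] | None = None):
        self.n_sources = n_sources
        self.max_outer = max_outer
        self.inner_maxiter = inner_maxiter
        self.tol = tol
        self.random_state = random_state
        self.normalizer = normalizer
        self.endpoints = endpoints

    # -- helpers -----------------------------------------------------------
    def _resolve_endpoints(self, X: pd.DataFrame) -> list[str]:
        if self.endpoints is not None:
            return list(self.endpoints)
        registry = default_registry()
        return [c for c in X.columns if c in registry]

    def _maybe_normalize(self, X: pd.DataFrame, fit: bool = False) -> pd.DataFrame:
        if self.normalizer is None:
            return X
        if fit and not hasattr(self.normalizer, "entries_"):
            self.normalizer.fit(X)
        return self.normalizer.transform(X)

    # -- calibration -------------------------------------------------------
    def fit(self, X: pd.DataFrame, y=None) -> "CourseMap":
        endpoints = self._resolve_endpoints(X)
        if len(endpoints) < 2:
            raise CalibrationError("need at least two endpoints to calibrate")
        Xn = self._maybe_normalize(X, fit=True)
        packed = _pack(Xn, endpoints)
        if not packed.M.any(axis=(0, 1)).all():
            dead = [endpoints[k] for k in np.flatnonzero(~packed.M.any(axis=(0, 1)))]
            raise CalibrationError(f"endpoint(s) with no observation: {dead}")
        N, J, K = packed.Y.shape
        q = int(self.n_sources)

        t0, a, delta = self._init_fixed(packed)
        A = np.zeros((K, q))
        xi = np.zeros(N)
        tau = np.zeros(N)
        s = np.zeros((N, q))
        sig_k = np.full(K, 0.1)
        sig_xi, sig_tau = 0.5, 5.0

        history: list[float] = []
        state = (t0, a, delta, A, xi, tau, s)
        # stage 1: no presentation shifts, lock the time line first
        state, sig_k, sig_xi, sig_tau, _ = self._outer_loop(
            packed, state, sig_k, sig_xi, sig_tau, n_iter=min(8, self.max_outer),
            freeze_sources=True, history=history)
        if q > 0:
            state = self._init_sources(packed, state, sig_k)
        # stage 2: full model
        state, sig_k, sig_xi, sig_tau, converged = self._outer_loop(
            packed, state, sig_k, sig_xi, sig_tau, n_iter=self.max_outer,
            freeze_sources=False, history=history)

        t0, a, delta, A, xi, tau, s = state
        self.endpoints_ = endpoints
        self.params_ = PopulationParams(
            t0=float(t0), delta=delta, rates=a, mixing=A,
            sigma_xi=float(sig_xi), sigma_tau=float(sig_tau),
            sigma_noise=sig_k, endpoints=list(endpoints))
        self.effects_ = {
            sid: IndividualEffects(float(xi[i]), float(tau[i]), s[i].copy(),
                                   (A @ s[i]) if q else np.zeros(K))
            for i, sid in enumerate(packed.ids)}
        self.history_ = history
        self.n_iter_ = len(history)
        self.converged_ = bool(converged)
        return self

    def _init_fixed(self, packed: _Packed):
        T, Y, M = packed.T, packed.Y, packed.M
        visit_mask = M.any(axis=2)
        t0 = float(T[visit_mask].mean())
        K = Y.shape[2]
        a = np.empty(K)
        delta = np.empty(K)
        for k in range(K):
            m = M[:, :, k]
            t = T[m]
            ly = logit(np.clip(Y[:, :, k][m], 0.025, 0.975))
            slope, intercept = np.polyfit(t, ly, 1) if t.size > 2 else (0.1, 0.0)
            a[k] = float(np.clip(slope, 0.02, 2.0))
            t_half = -intercept / slope if abs(slope) > 1e-8 else t0
            delta[k] = float(np.clip(t_half - t0, -15.0, 15.0))
        delta -= delta.mean()
        return t0, a, delta

    def _init_sources(self, packed: _Packed, state, sig_k):
        """Principal directions of per-subject logit-scale residuals."""
        t0, a, delta, A, xi, tau, s = state
        T, Y, M = packed.T, packed.Y, packed.M
        N, J, K = Y.shape
        q = A.shape[1]
        phi = np.exp(xi)
        z = phi[:, None] * (T - t0 - tau[:, None])
        u = a[None, None, :] * (z[:, :, None] - delta[None, None, :])
        p = expit(u)
        du = np.where(M, (Y - p) / np.clip(p * (1 - p), 5e-2, None), 0.0)
        cnt = M.sum(axis=1)
        R = du.sum(axis=1) / np.maximum(cnt, 1)           # (N, K)
        R -= R.mean(axis=0, keepdims=True)
        # rotate out the component parallel to the rates (a time-like shift)
        R -= np.outer(R @ a / (a @ a), a)
        U, S, Vt = np.linalg.svd(R, full_matrices=False)
        q_eff = min(q, S.size)
        A = np.zeros((K, q))
        s = np.zeros((N, q))
        A[:, :q_eff] = (Vt[:q_eff].T * (S[:q_eff] / np.sqrt(N)))
        s[:, :q_eff] = U[:, :q_eff] * np.sqrt(N)
        return t0, a, delta, A, xi, tau, s

    def _outer_loop(self, packed: _Packed, state, sig_k, sig_xi, sig_tau,
                    n_iter: int, freeze_sources: bool, history: list[float]):
        N, J, K = packed.Y.shape
        converged = False
        prev = np.inf
        for _ in range(n_iter):
            t0, a, delta, A, xi, tau, s = state
            q = A.shape[1]
            theta0 = np.concatenate([
                [t0], np.log(a), delta, A.ravel(), xi, tau, s.ravel()])
            res = minimize(_objective, theta0,
                           args=(packed, sig_k, sig_xi, sig_tau, freeze_sources),
                           jac=True, method="L-BFGS-B",
                           options={"maxiter": self.inner_maxiter})
            t0, a, delta, A, xi, tau, s = _unpack_theta(res.x, N, K, q)
            t0, a, delta, A, xi, tau, s = _canonicalize(t0, a, delta, A, xi, tau, s)
            state = (t0, a, delta, A, xi, tau, s)

            cov = _posterior_covariances(packed, t0, a, delta, A, xi, tau, s,
                                         sig_k, sig_xi, sig_tau)
            sig_xi = float(np.sqrt(max(np.mean(xi ** 2 + cov[:, 0, 0]), 1e-6)))
            sig_tau = float(np.sqrt(max(np.mean(tau ** 2 + cov[:, 1, 1]), 1e-4)))
            sig_k = self._noise_update(packed, state)

            objective = self._full_objective(packed, state, sig_k, sig_xi, sig_tau)
            history.append(objective)
            if np.isfinite(prev) and abs(prev - objective) <= self.tol * abs(prev):
                converged = True
                break
            prev = objective
        return state, sig_k, sig_xi, sig_tau, converged

    def _noise_update(self, packed: _Packed, state) -> np.ndarray:
        t0, a, delta, A, xi, tau, s = state
        T, Y, M = packed.T, packed.Y, packed.M
        phi = np.exp(xi)
        z = phi[:, None] * (T - t0 - tau[:, None])
        u = a[None, None, :] * (z[:, :, None] - delta[None, None, :]) + (s @ A.T)[:, None, :]
        r = np.where(M, Y - expit(u), 0.0)
        sse = np.einsum("ijk->k", r ** 2)
        cnt = M.sum(axis=(0, 1))
        return np.sqrt(np.maximum(sse / np.maximum(cnt, 1), 1e-6))

    def _full_objective(self, packed: _Packed, state, sig_k, sig_xi, sig_tau) -> float:
        t0, a, delta, A, xi, tau, s = state
        theta = np.concatenate([[t0], np.log(a), delta, A.ravel(), xi, tau, s.ravel()])
        loss, _ = _objective(theta, packed, sig_k, sig_xi, sig_tau, True)
        N = xi.size
        cnt = packed.M.sum(axis=(0, 1))
        loss += float(cnt @ np.log(sig_k)) + N * (np.log(sig_xi) + np.log(sig_tau))
        return float(loss)

    # -- personalization and forecasting -----------------------------------
    def personalize(self, visits: pd.DataFrame, trace: list[float] | None = None
                    ) -> IndividualEffects:
        """MAP random effects of one subject given a subset of visits.

        ``visits`` is a long-format table (one subject) with ``age`` and
        endpoint columns; any missingness pattern is allowed as long as at
        least one measurement is observed.  ``trace``, when given, collects
        the objective value across optimizer iterations.
        """
        check_is_fitted(self, "params_")
        visits = self._maybe_normalize(visits)
        pp = self.params_
        q = pp.n_sources
        sub = visits.copy()
        sub["subject_id"] = "_one"
        packed = _pack(sub, self.endpoints_)
        if not packed.M.any():
            raise ValueError("no observed measurement to personalize on")
        T, Y, M = packed.T[0], packed.Y[0], packed.M[0]

        inv_var = 1.0 / pp.sigma_noise ** 2
        sxi = max(pp.sigma_xi, 1e-3)
        stau = max(pp.sigma_tau, 1e-3)

        def fun(psi):
            xi, tau = psi[0], psi[1]
            s = psi[2:]
            phi = np.exp(xi)
            z = phi * (T - pp.t0 - tau)
            u = pp.rates[None, :] * (z[:, None] - pp.delta[None, :]) \
                + (pp.mixing @ s)[None, :]
            p = expit(u)
            r = np.where(M, Y - p, 0.0)
            loss = 0.5 * np.einsum("jk,k->", r ** 2, inv_var)
            loss += 0.5 * (xi / sxi) ** 2 + 0.5 * (tau / stau) ** 2 + 0.5 * s @ s
            G = -(r * p * (1 - p)) * inv_var[None, :]
            Ga = G @ pp.rates
            grad_xi = float(Ga @ z) + xi / sxi ** 2
            grad_tau = -phi * float(Ga.sum()) + tau / stau ** 2
            grad_s = G.sum(axis=0) @ pp.mixing + s
            return loss, np.concatenate([[grad_xi, grad_tau], grad_s])

        x0 = np.zeros(2 + q)
        if trace is not None:
            trace.append(fun(x0)[0])
            callback = (lambda xk: trace.append(fun(xk)[0]))
        else:
            callback = None
        res = minimize(fun, x0, jac=True, method="L-BFGS-B", callback=callback,
                       options={"maxiter": 500})
        xi, tau = float(res.x[0]), float(res.x[1])
        s = res.x[2:]
        return IndividualEffects(xi, tau, s, pp.mixing @ s if q else np.zeros(pp.n_endpoints))

    def forecast(self, effects: IndividualEffects, ages: Sequence[float],
                 endpoints: Sequence[str] | None = None) -> pd.DataFrame:
        """Evaluate the individual curves at ``ages`` and denormalize.

        Returns a DataFrame indexed by age with one column per endpoint,
        on the native scale when a normalizer is attached.
        """
        check_is_fitted(self, "params_")
        endpoints = list(endpoints) if endpoints is not None else list(self.endpoints_)
        ages = np.asarray(ages, dtype=float)
        out = {}
        for name in endpoints:
            k = self.endpoints_.index(name)
            values = individual_curve(ages, self.params_, effects, k)
            if self.normalizer is not None:
                values = self.normalizer.denormalize_value(name, values)
            out[name] = values
        return pd.DataFrame(out, index=pd.Index(ages, name="age"))

    def predict(self, visits: pd.DataFrame, ages: Sequence[float],
                endpoints: Sequence[str] | None = None) -> pd.DataFrame:
        """Personalize on ``visits`` then forecast at ``ages``."""
        return self.forecast(self.personalize(visits), ages, endpoints)

    def population_curve(self, ages: Sequence[float],
                         endpoints: Sequence[str] | None = None) -> pd.DataFrame:
        """Forecast with all random effects at zero."""
        check_is_fitted(self, "params_")
        return self.forecast(IndividualEffects.null(self.params_), ages, endpoints)

    # -- serialization ------------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        check_is_fitted(self, "params_")
        pp = self.params_
        payload = {
            "params": {
                "t0": pp.t0, "delta": pp.delta.tolist(), "rates": pp.rates.tolist(),
                "mixing": pp.mixing.tolist(), "sigma_xi": pp.sigma_xi,
                "sigma_tau": pp.sigma_tau, "sigma_noise": pp.sigma_noise.tolist(),
                "endpoints": pp.endpoints,
            },
            "normalizer": self.normalizer.to_dict() if self.normalizer is not None else None,
            "config": {"n_sources": self.n_sources, "max_outer": self.max_outer,
                       "inner_maxiter": self.inner_maxiter, "tol": self.tol,
                       "random_state": self.random_state},
            "diagnostics": {"objective": self.history_[-1] if self.history_ else None,
                            "n_iter": self.n_iter_, "converged": self.converged_},
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "CourseMap":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        cfg = payload["config"]
        normalizer = None
        if payload["normalizer"] is not None:
            normalizer = EndpointNormalizer.from_dict(payload["normalizer"])
        obj = cls(normalizer=normalizer, **{k: cfg[k] for k in
                                            ("n_sources", "max_outer", "inner_maxiter",
                                             "tol", "random_state")})
        p = payload["params"]
        obj.params_ = PopulationParams(
            t0=p["t0"], delta=np.array(p["delta"]), rates=np.array(p["rates"]),
            mixing=np.array(p["mixing"]), sigma_xi=p["sigma_xi"],
            sigma_tau=p["sigma_tau"], sigma_noise=np.array(p["sigma_noise"]),
            endpoints=list(p["endpoints"]))
        obj.endpoints_ = list(p["endpoints"])
        obj.effects_ = {}
        diag = payload["diagnostics"]
        obj.history_ = [diag["objective"]] if diag["objective"] is not None else []
        obj.n_iter_ = diag["n_iter"]
        obj.converged_ = diag["converged"]
        return obj


def calibrate(training_table: pd.DataFrame, **config) -> CourseMap:
    """Calibrate a :class:`CourseMap` on a normalized long-format table."""
    return CourseMap(**config).fit(training_table)


def personalize(model: CourseMap, visits: pd.DataFrame) -> IndividualEffects:
    """MAP individual effects for one subject's visit subset."""
    return model.personalize(visits)


def forecast(model: CourseMap, effects: IndividualEffects, ages: Sequence[float],
             endpoints: Sequence[str] | None = None) -> pd.DataFrame:
    """Native-scale forecasts at the requested ages."""
    return model.forecast(effects, ages, endpoints)
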