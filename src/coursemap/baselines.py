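"""Comparator forecasters: no-change carry-forward and a linear mixed model.

Both are strong baselines in a slowly progressing disease.  The linear
mixed model regresses each endpoint on age with a random intercept and
random slope per subject (fitted by REML on the native scale); an unseen
subject is personalized with the exact conjugate-normal maximum a
posteriori estimate of their random effects, which for a Gaussian model
coincides with the posterior mean, and then extrapolated linearly.

All forecasters share one call signature,
``forecast(visits, endpoint, target_age)``, where ``visits`` is the
long-format table of the subject's unblinded visits, so the evaluation
harness treats every method uniformly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .registry import default_registry


@dataclass
class LmmParams:
    """Per-endpoint linear mixed model: fixed line, random-effect
    covariance (intercept, slope) and residual variance."""

    intercept: float
    slope: float
    cov_re: np.ndarray        # (2, 2), symmetric PSD
    resid_var: float

    def __post_init__(self) -> None:
        self.cov_re = np.asarray(self.cov_re, dtype=float)
        if self.resid_var <= 0:
            raise ValueError("residual variance must be positive")
        if not np.allclose(self.cov_re, self.cov_re.T):
            raise ValueError("random-effect covariance must be symmetric")
        if np.linalg.eigvalsh(self.cov_re).min() < -1e-8:
            raise ValueError("random-effect covariance must be PSD")


class NoChangeForecaster:
    """Carry the last observed value forward, regardless of horizon."""

    def forecast(self, visits: pd.DataFrame, endpoint: str, target_age: float) -> float:
        observed = visits.sort_values("age").dropna(subset=[endpoint])
        if observed.empty:
            raise ValueError(f"endpoint {endpoint!r} never observed in the unblinded visits")
        return float(observed[endpoint].iloc[-1])


def nochange_forecast(visits: pd.DataFrame, endpoint: str, target_age: float = np.nan) -> float:
    """Value at the latest unblinded visit where ``endpoint`` is observed."""
    return NoChangeForecaster().forecast(visits, endpoint, target_age)


class LinearMixedForecaster(BaseEstimator):
    """Per-endpoint random intercept + random slope model over age.

    Parameters
    ----------
    endpoints : sequence of str, optional
        Endpoints to model; defaults to registry endpoints in the table.
    reml : bool
        Restricted (default) vs full maximum likelihood.

    Attributes
    ----------
    params_ : dict[str, LmmParams]
    """

    def __init__(self, endpoints: Sequence[str] | None = None, reml: bool = True):
        self.endpoints = endpoints
        self.reml = reml

    def fit(self, X: pd.DataFrame, y=None) -> "LinearMixedForecaster":
        import statsmodels.api as sm

        registry = default_registry()
        endpoints = (list(self.endpoints) if self.endpoints is not None
                     else [c for c in X.columns if c in registry])
        self.params_ = {}
        for name in endpoints:
            data = X.dropna(subset=[name])[["subject_id", "age", name]]
            if data["subject_id"].nunique() < 3:
                raise RuntimeError(f"{name}: not enough subjects for a mixed model")
            exog = sm.add_constant(data["age"].astype(float))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = sm.MixedLM(data[name].astype(float), exog,
                                   groups=data["subject_id"],
                                   exog_re=exog)
                result = model.fit(reml=self.reml)
            cov_re = np.asarray(result.cov_re, dtype=float)
            # clip tiny negative eigenvalues from the boundary of the
            # parameter space
            eigval, eigvec = np.linalg.eigh((cov_re + cov_re.T) / 2)
            cov_re = (eigvec * np.maximum(eigval, 0.0)) @ eigvec.T
            self.params_[name] = LmmParams(
                intercept=float(result.fe_params.iloc[0]),
                slope=float(result.fe_params.iloc[1]),
                cov_re=cov_re,
                resid_var=float(result.scale))
        return self

    def forecast(self, visits: pd.DataFrame, endpoint: str, target_age: float) -> float:
        """Closed-form Gaussian MAP of the subject's line, extrapolated.

        With prior ``b ~ N(0, Psi)`` and observations
        ``y = X beta + X b + eps``, the MAP (= posterior mean) is
        ``Psi X' (X Psi X' + s2 I)^{-1} (y - X beta)``.
        """
        check_is_fitted(self, "params_")
        p = self.params_[endpoint]
        observed = visits.dropna(subset=[endpoint])
        if observed.empty:
            raise ValueError(f"endpoint {endpoint!r} never observed in the unblinded visits")
        t = observed["age"].to_numpy(dtype=float)
        y = observed[endpoint].to_numpy(dtype=float)
        Z = np.column_stack([np.ones_like(t), t])
        resid = y - (p.intercept + p.slope * t)
        V = Z @ p.cov_re @ Z.T + p.resid_var * np.eye(len(t))
        b = p.cov_re @ Z.T @ np.linalg.solve(V, resid)
        return float(p.intercept + b[0] + (p.slope + b[1]) * target_age)

    def map_posterior_mean(self, visits: pd.DataFrame, endpoint: str) -> np.ndarray:
        """The subject's posterior-mean random effects (intercept, slope)."""
        check_is_fitted(self, "params_")
        p = self.params_[endpoint]
        observed = visits.dropna(subset=[endpoint])
        t = observed["age"].to_numpy(dtype=float)
        y = observed[endpoint].to_numpy(dtype=float)
        Z = np.column_stack([np.ones_like(t), t])
        resid = y - (p.intercept + p.slope * t)
        V = Z @ p.cov_re @ Z.T + p.resid_var * np.eye(len(t))
        return p.cov_re @ Z.T @ np.linalg.solve(V, resid)


def lmm_fit(training_table: pd.DataFrame, endpoints: Sequence[str] | None = None,
            reml: bool = True) -> LinearMixedForecaster:
    """Fit the per-endpoint linear mixed baseline on native-scale data."""
    return LinearMixedForecaster(endpoints=endpoints, reml=reml).fit(training_table)


def lmm_forecast(model: LinearMixedForecaster, visits: pd.DataFrame,
                 endpoint: str, target_age: float) -> float:
    """MAP-personalized linear extrapolation to ``target_age``."""
    return model.forecast(visits, endpoint, target_age)
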