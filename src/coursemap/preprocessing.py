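"""Endpoint normalization and cross-cohort CSF harmonization.

The progression model works on a common (0, 1) pathology scale: 0 is the
most normal value and 1 the maximum pathological change, for every
endpoint.  Three normalization kinds cover the endpoint panel:

* ``theoretical-bounds`` — cognitive scales mapped linearly between their
  theoretical best and worst values (MMSE 30..0, ADAS-Cog13 0..85,
  CDR-SB 0..18);
* ``amyloid-cl`` — centiloid values clipped to [0, 100] and divided by 100;
* ``percentile-clip`` — MRI volumes, tau PET and harmonized CSF clipped at
  the 1st and 99th percentile of the training values and mapped linearly.

Endpoints that decrease with disease (hippocampal volume, CSF A-beta) are
flipped so that 1 is always pathological.  Every forward map stores the
native values sent to 0 and to 1, making denormalization a one-liner and
the round trip exact on the non-clipped range.

CSF biomarkers additionally need harmonization across cohorts that used
different immunoassays: per cohort and biomarker a linear mixed model with
per-subject random intercept regresses the measurement on age, APOE-e4
copies and CDR global, and the measurements are affinely rescaled so that
the fitted intercept is 0 and the total variance is 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .registry import EndpointRegistry, EndpointSpec, default_registry

NORM_KINDS = ("theoretical-bounds", "percentile-clip", "amyloid-cl")


class FitError(RuntimeError):
    """Raised when a normalization or harmonization fit is impossible."""


@dataclass(frozen=True)
class NormEntry:
    """Forward map of one endpoint: ``zero_point`` is the native value sent
    to 0 (most normal), ``one_point`` the native value sent to 1."""

    kind: str
    zero_point: float
    one_point: float

    def forward(self, value):
        n = (np.asarray(value, dtype=float) - self.zero_point) / (self.one_point - self.zero_point)
        return np.clip(n, 0.0, 1.0)

    def backward(self, norm):
        return self.zero_point + np.asarray(norm, dtype=float) * (self.one_point - self.zero_point)


def _theoretical_entry(spec: EndpointSpec) -> NormEntry:
    return NormEntry("theoretical-bounds", float(spec.native_best), float(spec.native_worst))


def normalize_cognitive(value, spec: EndpointSpec):
    """Map a cognitive score onto (0, 1) by its theoretical bounds.

    Best score maps to 0, theoretical worst to 1; scales where higher is
    better (MMSE) are flipped by construction.  Values outside the
    theoretical range are clipped with a warning.
    """
    entry = _theoretical_entry(spec)
    raw = (np.asarray(value, dtype=float) - entry.zero_point) / (entry.one_point - entry.zero_point)
    if np.any(raw < 0) or np.any(raw > 1):
        warnings.warn(f"{spec.name}: value outside theoretical bounds, clipped", stacklevel=2)
    return entry.forward(value)


def fit_percentile_clip(training_values, spec: EndpointSpec,
                        percentiles=(1.0, 99.0)) -> NormEntry:
    """Clip bounds at the stated centiles of the training values.

    Percentiles use linear interpolation between order statistics.  The
    orientation flag of the spec decides which bound maps to 0.
    """
    values = np.asarray(training_values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise FitError(f"{spec.name}: no training values to fit percentile bounds")
    if values.size < 100:
        warnings.warn(f"{spec.name}: only {values.size} training values for percentile bounds",
                      stacklevel=2)
    lo, hi = np.percentile(values, percentiles)
    if lo == hi:
        raise FitError(f"{spec.name}: degenerate percentile bounds ({lo})")
    if spec.higher_is_worse:
        return NormEntry("percentile-clip", float(lo), float(hi))
    return NormEntry("percentile-clip", float(hi), float(lo))


def normalize_amyloid_cl(value_cl):
    """Centiloids clipped to [0, 100] then divided by 100."""
    return NormEntry("amyloid-cl", 0.0, 100.0).forward(value_cl)


def centiloid_convert(suvr, tracer_slope: float, tracer_intercept: float):
    """Affine SUVR -> centiloid conversion with tracer-specific constants."""
    if tracer_slope == 0:
        raise ValueError("tracer slope must be non-zero")
    return tracer_slope * np.asarray(suvr, dtype=float) + tracer_intercept


def denormalize(value, entry_or_spec):
    """Inverse of the forward map on the non-clipped range."""
    if isinstance(entry_or_spec, EndpointSpec):
        entry_or_spec = _theoretical_entry(entry_or_spec)
    return entry_or_spec.backward(value)


class EndpointNormalizer(TransformerMixin, BaseEstimator):
    """Map the endpoint columns of a long-format table onto the (0, 1)
    pathology scale, with exact inverse transform.

    Parameters
    ----------
    registry : EndpointRegistry, optional
        Endpoint declarations; defaults to the standard nine-endpoint panel.
    clip_percentiles : tuple of float
        Centiles defining the data-driven clip bounds, default ``(1, 99)``.

    Percentile bounds are estimated on the data passed to :meth:`fit` only
    (the training split) and frozen; validation data reuse them.  Endpoints
    whose spec carries theoretical bounds use those instead, and amyloid
    PET always uses the fixed 0-100 centiloid clip.
    """

    def __init__(self, registry: EndpointRegistry | None = None,
                 clip_percentiles: tuple[float, float] = (1.0, 99.0)):
        self.registry = registry
        self.clip_percentiles = clip_percentiles

    def _registry(self) -> EndpointRegistry:
        return self.registry if self.registry is not None else default_registry()

    def fit(self, X: pd.DataFrame, y=None) -> "EndpointNormalizer":
        registry = self._registry()
        self.entries_ = {}
        for name, spec in registry.items():
            if name not in X.columns:
                continue
            values = pd.to_numeric(X[name], errors="coerce").to_numpy(dtype=float)
            if spec.modality == "cognitive" or spec.has_bounds:
                # bounds are declared best -> worst, so orientation is built in
                entry = _theoretical_entry(spec)
            elif spec.modality == "pet_amyloid":
                entry = NormEntry("amyloid-cl", 0.0, 100.0)
            elif not np.isfinite(values).any():
                warnings.warn(f"{name}: no data in the training table, endpoint skipped",
                              stacklevel=2)
                continue
            else:
                entry = fit_percentile_clip(values, spec, self.clip_percentiles)
            self.entries_[name] = entry
        if not self.entries_:
            raise FitError("no registry endpoint found among the table columns")
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "entries_")
        out = X.copy()
        for name, entry in self.entries_.items():
            if name in out.columns:
                mask = out[name].notna()
                out.loc[mask, name] = entry.forward(out.loc[mask, name].to_numpy())
        return out

    def inverse_transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "entries_")
        out = X.copy()
        for name, entry in self.entries_.items():
            if name in out.columns:
                mask = out[name].notna()
                out.loc[mask, name] = entry.backward(out.loc[mask, name].to_numpy())
        return out

    def normalize_value(self, endpoint: str, value):
        check_is_fitted(self, "entries_")
        return self.entries_[endpoint].forward(value)

    def denormalize_value(self, endpoint: str, value):
        check_is_fitted(self, "entries_")
        return self.entries_[endpoint].backward(value)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        check_is_fitted(self, "entries_")
        return {name: asdict(entry) for name, entry in self.entries_.items()}

    @classmethod
    def from_dict(cls, payload: Mapping, registry: EndpointRegistry | None = None
                  ) -> "EndpointNormalizer":
        obj = cls(registry=registry)
        obj.entries_ = {name: NormEntry(**d) for name, d in payload.items()}
        return obj


# ---------------------------------------------------------------------------
# CSF harmonization
# ---------------------------------------------------------------------------

@dataclass
class HarmonizationEntry:
    """Per cohort-biomarker harmonization: regression coefficients of the
    mixed model plus the affine standardization applied afterwards."""

    coefficients: dict[str, float]
    random_intercept_var: float
    shift: float   # fitted intercept, subtracted
    scale: float   # total (population) standard deviation, divided out

    def apply(self, values):
        return (np.asarray(values, dtype=float) - self.shift) / self.scale


class CsfHarmonizer(TransformerMixin, BaseEstimator):
    """Standardize CSF biomarkers within each cohort so that different
    immunoassays land on a common unitless scale.

    For each cohort and biomarker a linear mixed model with per-subject
    random intercept regresses the measurement on age, APOE-e4 copies and
    CDR global (all numeric; age centered at a fixed 75-year reference so
    the intercept is an interpretable reference value rather than an
    extrapolation to age zero).  The measurements are then affinely
    rescaled so the fitted intercept is 0 and the total variance is 1.
    """

    AGE_REFERENCE = 75.0

    def __init__(self, biomarkers: tuple[str, ...] = ("csf_abeta42", "csf_ptau181"),
                 min_rows: int = 10):
        self.biomarkers = biomarkers
        self.min_rows = min_rows

    def fit(self, X: pd.DataFrame, y=None) -> "CsfHarmonizer":
        import statsmodels.api as sm

        self.entries_ = {}
        for cohort, grp in X.groupby("cohort"):
            for bio in self.biomarkers:
                if bio not in grp.columns or grp[bio].notna().sum() == 0:
                    continue
                cols = [bio, "age", "apoe4_copies", "cdr_global"]
                complete = grp.dropna(subset=cols)
                if len(complete) < self.min_rows:
                    raise FitError(f"{cohort}/{bio}: {len(complete)} complete rows "
                                   f"(need >= {self.min_rows})")
                exog = complete[["age", "apoe4_copies", "cdr_global"]].astype(float)
                exog = sm.add_constant(exog.assign(age=exog["age"] - self.AGE_REFERENCE))
                if np.linalg.matrix_rank(exog.to_numpy()) < exog.shape[1]:
                    raise FitError(f"{cohort}/{bio}: singular design")
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    model = sm.MixedLM(complete[bio].astype(float), exog,
                                       groups=complete["subject_id"])
                    result = model.fit(reml=True)
                observed = grp[bio].dropna().to_numpy(dtype=float)
                scale = float(np.std(observed, ddof=0))
                if scale == 0:
                    raise FitError(f"{cohort}/{bio}: zero variance")
                self.entries_[(str(cohort), bio)] = HarmonizationEntry(
                    coefficients=dict(zip(exog.columns, map(float, result.fe_params))),
                    random_intercept_var=float(result.cov_re.iloc[0, 0]),
                    shift=float(result.fe_params.iloc[0]),
                    scale=scale,
                )
        if not self.entries_:
            raise FitError("no cohort-biomarker pair with data to harmonize")
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "entries_")
        out = X.copy()
        for (cohort, bio), entry in self.entries_.items():
            mask = (out["cohort"].astype(str) == cohort) & out[bio].notna()
            out.loc[mask, bio] = entry.apply(out.loc[mask, bio].to_numpy())
        return out

    def to_dict(self) -> dict:
        check_is_fitted(self, "entries_")
        return {f"{c}::{b}": asdict(e) for (c, b), e in self.entries_.items()}

    @classmethod
    def from_dict(cls, payload: Mapping) -> "CsfHarmonizer":
        obj = cls()
        obj.entries_ = {}
        for key, d in payload.items():
            cohort, bio = key.split("::")
            obj.entries_[(cohort, bio)] = HarmonizationEntry(**d)
        return obj


def harmonize_csf(df: pd.DataFrame,
                  biomarkers: tuple[str, ...] = ("csf_abeta42", "csf_ptau181"),
                  ) -> tuple[pd.DataFrame, CsfHarmonizer]:
    """Fit the harmonization on ``df`` and return (harmonized table, fit)."""
    harmonizer = CsfHarmonizer(biomarkers=biomarkers).fit(df)
    return harmonizer.transform(df), harmonizer
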