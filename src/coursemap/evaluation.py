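"""Blinded-forecast validation protocol.

The protocol mirrors a prospective use of the model: for each subject we
unblind one to three consecutive visits, forecast an endpoint at a later
(blinded) visit 1.4-6.6 years ahead, and compare with the observation.
Tasks are generated combinatorially over subjects, unblinding windows,
target visits and endpoints; analyses run on random subsets of disjoint
tasks (no two tasks of a subject share any visit) and absolute errors are
modelled with a covariate-adjusted linear mixed model whose intercept is
the adjusted mean absolute error for a reference participant and design.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

from .cohort import AtnThresholds, CohortTable, classify_atnc, education_class
from .registry import MODALITIES, default_registry

#: reference categorical levels of the adjusted-MAE model: an ADNI woman
#: with no APOE-e4 copy, middle education band, A+T+N+C~ stage, forecast
#: from two unblinded visits.
REFERENCE_LEVELS = {
    "cohort": "ADNI",
    "sex": "F",
    "apoe4": "0",
    "education": "middle",
    "stage": "A+T+N+C~",
    "n_unblinded": "2",
}


@dataclass(frozen=True)
class TaskConstraints:
    """Eligibility rules for prediction tasks."""

    min_horizon: float = 1.4
    max_horizon: float = 6.6
    age_range: tuple[float, float] = (50.0, 90.0)
    max_cdr: float = 2.0
    max_unblinded: int = 3


@dataclass(frozen=True)
class PredictionTask:
    """One blinded-forecast experiment."""

    subject_id: str
    unblinded: tuple[int, ...]      # consecutive visit indices
    target: int                     # blinded visit index, after all unblinded
    endpoint: str
    horizon: float                  # years from latest unblinded to target

    def __post_init__(self) -> None:
        idx = self.unblinded
        if len(idx) < 1 or any(b != a + 1 for a, b in zip(idx, idx[1:])):
            raise ValueError("unblinded visits must be consecutive indices")
        if self.target <= max(idx):
            raise ValueError("target must come after the unblinded visits")

    @property
    def visits_involved(self) -> tuple[int, ...]:
        return self.unblinded + (self.target,)


def make_cv_splits(pool: Sequence[str], seed: int = 0) -> list[list[str]]:
    """Ten training subsets from two independent 5-fold partitions.

    Each subset is the pool minus one fold, so every subject is left out
    exactly twice and appears in exactly eight training subsets.
    """
    pool = list(pool)
    if len(pool) < 10:
        raise ValueError("need at least 10 subjects to build 2x5 folds")
    child_seeds = np.random.SeedSequence(seed).generate_state(2)
    subsets = []
    for rs in child_seeds:
        kf = KFold(n_splits=5, shuffle=True, random_state=int(rs % (2 ** 31)))
        for _, test_idx in kf.split(pool):
            fold = {pool[i] for i in test_idx}
            subsets.append([sid for sid in pool if sid not in fold])
    return subsets


def generate_tasks(table: CohortTable, constraints: TaskConstraints | None = None,
                   endpoints: Sequence[str] | None = None) -> list[PredictionTask]:
    """Enumerate every admissible (subject, window, target, endpoint) task.

    A window of one to three consecutive visits is admissible when the
    subject is inside the age range and at CDR global <= 2 at the latest
    unblinded visit (visits without a CDR global score are skipped); a
    target is admissible when it falls inside the horizon window and the
    endpoint is observed there.
    """
    constraints = constraints if constraints is not None else TaskConstraints()
    endpoints = list(endpoints) if endpoints is not None else list(table.registry)
    tasks = []
    for subject in table.subjects:
        visits = subject.visits
        n = len(visits)
        for end in range(n):
            latest = visits[end]
            if not (constraints.age_range[0] <= latest.age <= constraints.age_range[1]):
                continue
            if latest.cdr_global is None or latest.cdr_global > constraints.max_cdr:
                continue
            for length in range(1, constraints.max_unblinded + 1):
                start = end - length + 1
                if start < 0:
                    continue
                window = tuple(range(start, end + 1))
                for target in range(end + 1, n):
                    horizon = visits[target].age - latest.age
                    if not (constraints.min_horizon <= horizon <= constraints.max_horizon):
                        continue
                    for name in endpoints:
                        if visits[target].observed(name):
                            tasks.append(PredictionTask(
                                subject_id=subject.subject_id, unblinded=window,
                                target=target, endpoint=name, horizon=horizon))
    return tasks


def sample_disjoint(tasks: Sequence[PredictionTask], seed: int = 0) -> list[PredictionTask]:
    """Random maximal subset of tasks sharing no visit within any subject."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(tasks))
    used: set[tuple[str, int]] = set()
    chosen = []
    for i in order:
        task = tasks[i]
        keys = [(task.subject_id, v) for v in task.visits_involved]
        if any(k in used for k in keys):
            continue
        used.update(keys)
        chosen.append(task)
    return chosen


def standardize_age(age: float) -> float:
    """Age at prediction centered on 75 years, normalized by 7.5 years."""
    return (age - 75.0) / 7.5


def standardize_years_to_prediction(years: float) -> float:
    """Horizon centered on three years, normalized by one year."""
    return (years - 3.0) / 1.0


def standardize_gap(gap_months: float) -> float:
    """Mean inter-visit gap centered on eight months, normalized by three."""
    return (gap_months - 8.0) / 3.0


def standardize_covariates(age: float, years_to_prediction: float,
                           gap_months: float) -> tuple[float, float, float]:
    return (standardize_age(age),
            standardize_years_to_prediction(years_to_prediction),
            standardize_gap(gap_months))


def evaluate(forecaster, tasks: Sequence[PredictionTask], table: CohortTable,
             thresholds: AtnThresholds | None = None) -> pd.DataFrame:
    """Run the forecaster on each task and assemble annotated error records.

    The error is the absolute difference between forecast and observation
    on the native scale.  Tasks on which the forecaster fails are excluded;
    their count is reported in ``DataFrame.attrs['n_failed']``.
    """
    thresholds = thresholds if thresholds is not None else AtnThresholds.default()
    registry = table.registry
    frame = table.to_frame()
    records = []
    n_failed = 0
    by_subject = {s.subject_id: s for s in table.subjects}
    grouped: dict[tuple[str, tuple[int, ...]], list[PredictionTask]] = {}
    for task in tasks:
        grouped.setdefault((task.subject_id, task.unblinded), []).append(task)

    for (sid, window), group in grouped.items():
        subject = by_subject[sid]
        sub_frame = frame[frame["subject_id"] == sid].sort_values("age")
        visits_df = sub_frame.iloc[list(window)]
        latest = subject.visits[window[-1]]
        ages = visits_df["age"].to_numpy(dtype=float)
        gap_months = float(np.diff(ages).mean() * 12.0) if len(ages) > 1 else 8.0
        stage = str(classify_atnc(subject, thresholds, upto_visit_index=window[-1]))
        miss = {}
        for modality in MODALITIES:
            names = [n for n in registry.by_modality(modality) if n in frame.columns]
            if not names:
                continue
            cells = visits_df[names].to_numpy(dtype=float)
            miss[f"miss_{modality}"] = float(np.isnan(cells).mean())
        for task in group:
            truth = subject.visits[task.target].measurements[task.endpoint]
            target_age = subject.visits[task.target].age
            try:
                pred = forecaster.forecast(visits_df, task.endpoint, target_age)
            except Exception:
                n_failed += 1
                continue
            records.append({
                "subject_id": sid, "endpoint": task.endpoint,
                "unblinded": task.unblinded, "target": task.target,
                "horizon": task.horizon,
                "abs_error": abs(pred - truth),
                "stage": stage, "cohort": subject.cohort_id,
                "apoe4": str(subject.apoe4_copies) if subject.apoe4_copies is not None
                         else "missing",
                "sex": subject.sex,
                "education": education_class(subject.education_years),
                "n_unblinded": str(len(window)),
                "std_age": standardize_age(latest.age),
                "std_years": standardize_years_to_prediction(task.horizon),
                "std_gap": standardize_gap(gap_months),
                **miss,
            })
    out = pd.DataFrame(records)
    out.attrs["n_failed"] = n_failed
    return out


@dataclass
class ErrorModelFit:
    """Covariate-adjusted absolute-error model.

    ``intercept`` is the adjusted MAE for the reference participant and
    design; ``coefficients`` the shift per covariate level / unit; ``ci``
    the empirical 95% interval per term over resamples (when resampled).
    """

    intercept: float
    coefficients: pd.Series
    ci: pd.DataFrame | None = None


_CATEGORICALS = ("stage", "cohort", "apoe4", "sex", "education", "n_unblinded")


def _build_design(records: pd.DataFrame) -> pd.DataFrame:
    cols = {}
    for name in _CATEGORICALS:
        values = records[name].astype(str)
        ref = REFERENCE_LEVELS.get(name)
        levels = sorted(values.unique())
        if ref not in levels:
            ref = values.mode().iloc[0]
        for level in levels:
            if level == ref:
                continue
            cols[f"{name}[{level}]"] = (values == level).astype(float)
    for name in records.columns:
        if name.startswith(("std_", "miss_")):
            cols[name] = records[name].astype(float)
    design = pd.DataFrame(cols, index=records.index)
    design.insert(0, "intercept", 1.0)
    return design


def fit_error_model(records: pd.DataFrame) -> ErrorModelFit:
    """Linear mixed model of absolute error with per-subject random intercept.

    Categorical covariates are coded against the reference participant
    levels; aliased (rank-deficient) columns are dropped with a warning.
    """
    import statsmodels.api as sm

    if records["subject_id"].nunique() < 2:
        raise ValueError("need records from at least two subjects")
    design = _build_design(records)
    # drop aliased columns
    q, r = np.linalg.qr(design.to_numpy())
    keep = np.abs(np.diag(r)) > 1e-8 * max(1.0, np.abs(np.diag(r)).max())
    if not keep.all():
        dropped = list(design.columns[~keep])
        warnings.warn(f"dropping aliased design columns: {dropped}", stacklevel=2)
        design = design.loc[:, keep]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(records["abs_error"].astype(float), design,
                           groups=records["subject_id"])
        result = model.fit()
    params = result.fe_params
    return ErrorModelFit(intercept=float(params["intercept"]),
                         coefficients=params.drop("intercept"))


def resample_summary(records: pd.DataFrame, reps: int = 100, seed: int = 0
                     ) -> ErrorModelFit:
    """Repeat the adjusted-error fit over disjoint-task resamples.

    Each repetition keeps one record per (subject, visit-set) conflict
    group — the disjoint-task rule — refits the mixed model, and the
    summary reports the mean and empirical 2.5-97.5 percentile interval
    of the intercept and each coefficient.
    """
    seeds = np.random.SeedSequence(seed).generate_state(reps)
    fits = []
    for rs in seeds:
        sub = _disjoint_records(records, int(rs % (2 ** 31)))
        fits.append(fit_error_model(sub))
    table = pd.DataFrame([
        pd.concat([pd.Series({"intercept": f.intercept}), f.coefficients])
        for f in fits])
    mean = table.mean()
    ci = pd.DataFrame({"low": table.quantile(0.025), "high": table.quantile(0.975)})
    return ErrorModelFit(intercept=float(mean["intercept"]),
                         coefficients=mean.drop("intercept"), ci=ci)


def _disjoint_records(records: pd.DataFrame, seed: int) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(records))
    used: set[tuple[str, int]] = set()
    rows = []
    for i in order:
        row = records.iloc[i]
        keys = [(row["subject_id"], v) for v in (*row["unblinded"], row["target"])]
        if any(k in used for k in keys):
            continue
        used.update(keys)
        rows.append(i)
    return records.iloc[sorted(rows)]


class CourseMapForecaster:
    """Adapter giving a fitted :class:`~coursemap.model.CourseMap` the
    uniform ``forecast(visits, endpoint, target_age)`` signature, with a
    cache of the last personalization so that tasks sharing an unblinding
    window personalize once."""

    def __init__(self, model):
        self.model = model
        self._key = None
        self._effects = None

    def forecast(self, visits: pd.DataFrame, endpoint: str, target_age: float) -> float:
        key = (tuple(visits["age"].round(9)),
               tuple(visits.index))
        if key != self._key:
            self._effects = self.model.personalize(visits)
            self._key = key
        value = self.model.forecast(self._effects, [target_age], [endpoint])
        return float(value.iloc[0, 0])


class ExternalScoreForecaster:
    """Comparator slot for externally computed forecasts, e.g. a recurrent
    network run elsewhere: a table with columns subject_id, endpoint,
    target_age, value is looked up instead of computing anything."""

    def __init__(self, scores: pd.DataFrame, subject_column: str = "subject_id"):
        self._lookup = {
            (str(r[subject_column]), str(r["endpoint"]), round(float(r["target_age"]), 3)):
                float(r["value"])
            for _, r in scores.iterrows()}

    def forecast(self, visits: pd.DataFrame, endpoint: str, target_age: float) -> float:
        sid = str(visits["subject_id"].iloc[0])
        key = (sid, endpoint, round(float(target_age), 3))
        if key not in self._lookup:
            raise KeyError(f"no external forecast for {key}")
        return self._lookup[key]
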