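"""Clinical-trial simulation and prognostic enrichment.

A trial design fixes inclusion criteria (age window, CDR global, MMSE
floor, biomarker positivity, APOE rule), a primary outcome and a duration
with tolerance.  From observational data we extract all (baseline,
follow-up) visit pairs satisfying the design; the outcome is the oriented
annual rate of change of the primary endpoint (larger = clinically
worse).  Fast progressors are the half of the population above the median
outcome; a prognostic score — the outcome forecast from baseline data
only — tries to identify them, and a ROC analysis with half-sample
resampling quantifies how well.  The enrichment comparator selects
APOE-e4 carriers instead, and a logistic selection-bias regression checks
which covariates the score-based selection favours.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .cohort import AtnThresholds, CohortTable, SubjectRecord, classify_atnc
from .registry import EndpointSpec, default_registry


@dataclass(frozen=True)
class TrialDesign:
    """Inclusion criteria, outcome and timing of one simulated trial."""

    name: str
    description: str
    age_range: tuple[float, float]
    cdr_allowed: tuple[float, ...]
    outcome: str
    duration_years: float
    tolerance_years: float
    mmse_min: float | None = None
    biomarker: str = "none"                    # none | amyloid | ptau
    apoe_rule: str | None = None               # None | carrier | risk_factor
    cohort_filter: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.age_range[0] >= self.age_range[1]:
            raise ValueError("age window must satisfy lo < hi")
        if self.duration_years <= 0 or self.tolerance_years < 0:
            raise ValueError("duration must be positive and tolerance >= 0")
        if self.biomarker not in ("none", "amyloid", "ptau"):
            raise ValueError(f"unknown biomarker requirement {self.biomarker!r}")


def builtin_trial_designs() -> list[TrialDesign]:
    """The six simulated phase-III-style designs.

    They span the AD continuum from cognitively normal individuals at
    genetic risk through preclinical and early AD to MCI/mild AD, with
    durations of 1.5 to 4.5 years and cognitive primary outcomes.
    """
    return [
        TrialDesign(
            name="at_risk_onset",
            description="Participants at risk of AD onset",
            age_range=(59.9, 76.1), cdr_allowed=(0.0,), mmse_min=24.0,
            apoe_rule="risk_factor", outcome="mmse",
            duration_years=4.0, tolerance_years=1.0),
        TrialDesign(
            name="preclinical_amyloid",
            description="Preclinical AD with high brain amyloid levels",
            age_range=(54.9, 81.1), cdr_allowed=(0.0,), mmse_min=27.0,
            biomarker="amyloid", outcome="adas13",
            duration_years=4.0, tolerance_years=1.0),
        TrialDesign(
            name="early_ad_amyloid_mmse",
            description="Early AD with high brain amyloid levels (MMSE outcome)",
            age_range=(49.9, 86.1), cdr_allowed=(0.5,), mmse_min=24.0,
            biomarker="amyloid", outcome="mmse",
            duration_years=1.5, tolerance_years=0.5),
        TrialDesign(
            name="early_ad_amyloid_cdrsb",
            description="Early AD with high brain amyloid levels (CDR-SB outcome)",
            age_range=(49.9, 86.1), cdr_allowed=(0.5,), mmse_min=24.0,
            biomarker="amyloid", outcome="cdrsb",
            duration_years=1.5, tolerance_years=0.5),
        TrialDesign(
            name="early_ad_tau",
            description="Early AD with high brain tau levels",
            age_range=(54.9, 81.1), cdr_allowed=(0.5,),
            biomarker="ptau", outcome="adas13",
            duration_years=4.5, tolerance_years=0.5),
        TrialDesign(
            name="mci_mild_ad",
            description="MCI probably due to AD or mild AD",
            age_range=(54.9, 86.1), cdr_allowed=(0.5, 1.0),
            cohort_filter=("ADNI", "AIBL", "PHARMACOG", "J-ADNI"),
            outcome="mmse", duration_years=3.0, tolerance_years=0.75),
    ]


@dataclass
class EligiblePair:
    """One (baseline, follow-up) visit pair entering a simulated trial."""

    subject_id: str
    baseline_index: int
    followup_index: int
    baseline_age: float
    followup_age: float
    elapsed_years: float
    baseline_value: float
    followup_value: float
    outcome: float                      # oriented annual rate of change
    label_fast: bool | None = None
    score: float | None = None          # predicted oriented outcome


def annual_rate(y_baseline: float, y_followup: float, elapsed_years: float,
                spec: EndpointSpec) -> float:
    """Oriented annual rate of change: positive = worsening per year."""
    if elapsed_years <= 0:
        raise ValueError("elapsed time must be positive")
    rate = (y_followup - y_baseline) / elapsed_years
    return rate if spec.higher_is_worse else -rate


def _meets_criteria(subject: SubjectRecord, visit_index: int, design: TrialDesign,
                    thresholds: AtnThresholds) -> bool:
    visit = subject.visits[visit_index]
    if not (design.age_range[0] <= visit.age <= design.age_range[1]):
        return False
    if visit.cdr_global is None or visit.cdr_global not in design.cdr_allowed:
        return False
    if design.mmse_min is not None:
        if not visit.observed("mmse") or visit.measurements["mmse"] < design.mmse_min:
            return False
    if design.cohort_filter is not None and subject.cohort_id not in design.cohort_filter:
        return False
    profile = None
    if design.biomarker != "none" or design.apoe_rule == "risk_factor":
        profile = classify_atnc(subject, thresholds, upto_visit_index=visit_index)
    if design.biomarker == "amyloid" and profile.A != "+":
        return False
    if design.biomarker == "ptau" and profile.T != "+":
        return False
    if design.apoe_rule == "carrier":
        if subject.apoe4_copies is None or subject.apoe4_copies < 1:
            return False
    elif design.apoe_rule == "risk_factor":
        # homozygous APOE-e4, or heterozygous with confirmed amyloid
        copies = subject.apoe4_copies
        if copies is None or copies == 0:
            return False
        if copies == 1 and profile.A != "+":
            return False
    return True


def find_eligible_pairs(table: CohortTable, design: TrialDesign,
                        thresholds: AtnThresholds | None = None) -> list[EligiblePair]:
    """All visit pairs meeting the design: outcome observed at both visits,
    criteria met at baseline, elapsed time within duration +/- tolerance.
    Intermediate visits are ignored."""
    thresholds = thresholds if thresholds is not None else AtnThresholds.default()
    spec = table.registry[design.outcome]
    pairs = []
    for subject in table.subjects:
        visits = subject.visits
        for i in range(len(visits)):
            if not visits[i].observed(design.outcome):
                continue
            if not _meets_criteria(subject, i, design, thresholds):
                continue
            for j in range(i + 1, len(visits)):
                if not visits[j].observed(design.outcome):
                    continue
                elapsed = visits[j].age - visits[i].age
                if abs(elapsed - design.duration_years) > design.tolerance_years:
                    continue
                y0 = visits[i].measurements[design.outcome]
                y1 = visits[j].measurements[design.outcome]
                pairs.append(EligiblePair(
                    subject_id=subject.subject_id, baseline_index=i, followup_index=j,
                    baseline_age=visits[i].age, followup_age=visits[j].age,
                    elapsed_years=elapsed, baseline_value=y0, followup_value=y1,
                    outcome=annual_rate(y0, y1, elapsed, spec)))
    return pairs


def label_fast(pairs: Sequence[EligiblePair]) -> list[EligiblePair]:
    """Median split of the oriented outcome; ties go to the slow group."""
    if len(pairs) < 2:
        raise ValueError("need at least two pairs for a median split")
    outcomes = np.array([p.outcome for p in pairs])
    threshold = float(np.median(outcomes))
    return [replace_pair(p, label_fast=p.outcome > threshold) for p in pairs]


def replace_pair(pair: EligiblePair, **changes) -> EligiblePair:
    out = EligiblePair(**{**pair.__dict__})
    for key, value in changes.items():
        setattr(out, key, value)
    return out


def prognostic_scores(forecaster, pairs: Sequence[EligiblePair], table: CohortTable,
                      outcome: str) -> list[EligiblePair]:
    """Predicted oriented annual rate from baseline data only.

    The forecaster is personalized on the single baseline visit and asked
    for the outcome endpoint at the follow-up age; the score is the
    oriented annual rate between the observed baseline value and that
    forecast.  No follow-up measurement enters the computation.  Pairs on
    which the forecaster fails are dropped (count in the log).
    """
    spec = table.registry[outcome]
    frame = table.to_frame()
    scored = []
    n_failed = 0
    for pair in pairs:
        sub = frame[frame["subject_id"] == pair.subject_id].sort_values("age")
        baseline_row = sub.iloc[[pair.baseline_index]]
        try:
            predicted = forecaster.forecast(baseline_row, outcome, pair.followup_age)
        except Exception:
            n_failed += 1
            continue
        score = annual_rate(pair.baseline_value, float(predicted),
                            pair.elapsed_years, spec)
        scored.append(replace_pair(pair, score=score))
    if n_failed:
        warnings.warn(f"prognostic scoring failed for {n_failed} pair(s); dropped",
                      stacklevel=2)
    return scored


# ---------------------------------------------------------------------------
# ROC analysis
# ---------------------------------------------------------------------------

@dataclass
class RocResult:
    """Threshold sweep with AUC, operating point and optional resampling
    confidence intervals / envelope bands."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    operating: dict = field(default_factory=dict)
    apoe: dict | None = None
    ci: dict | None = None
    envelope: dict | None = None


def roc(scores: Sequence[float], labels: Sequence[bool]) -> RocResult:
    """Full-threshold ROC with trapezoidal AUC."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or (~labels).all():
        raise ValueError("AUC undefined: only one class present")
    fpr, tpr, thr = _sk_roc_curve(labels.astype(int), scores)
    result = RocResult(thresholds=thr, sensitivity=tpr, specificity=1.0 - fpr,
                       auc=float(_trapezoid_auc(fpr, tpr)))
    thr_op = operating_point(scores)
    sens, spec = _point_at_threshold(scores, labels, thr_op)
    result.operating = {"threshold": thr_op, "sensitivity": sens, "specificity": spec}
    return result


def operating_point(scores: Sequence[float]) -> float:
    """Threshold splitting the screened population into equal halves."""
    return float(np.median(np.asarray(scores, dtype=float)))


def _point_at_threshold(scores, labels, threshold):
    selected = np.asarray(scores) > threshold
    labels = np.asarray(labels, dtype=bool)
    sens = float(selected[labels].mean()) if labels.any() else np.nan
    spec = float((~selected)[~labels].mean()) if (~labels).any() else np.nan
    return sens, spec


def apoe_point(pairs: Sequence[EligiblePair], table: CohortTable
               ) -> tuple[float, float]:
    """(sensitivity, specificity) when APOE-e4 carriers are selected."""
    labels = np.array([bool(p.label_fast) for p in pairs])
    carrier = np.array([
        (table.get(p.subject_id).apoe4_copies or 0) >= 1 for p in pairs])
    sens = float(carrier[labels].mean()) if labels.any() else np.nan
    spec = float((~carrier)[~labels].mean()) if (~labels).any() else np.nan
    return sens, spec


def _half_sample_no_visit_reuse(pairs: Sequence[EligiblePair], rng) -> list[EligiblePair]:
    """Half the pairs, never using any visit of a subject twice in the run."""
    order = rng.permutation(len(pairs))
    target = len(pairs) // 2
    used: set[tuple[str, int]] = set()
    out = []
    for i in order:
        p = pairs[i]
        keys = [(p.subject_id, p.baseline_index), (p.subject_id, p.followup_index)]
        if any(k in used for k in keys):
            continue
        used.update(keys)
        out.append(p)
        if len(out) == target:
            break
    return out


def resample_enrichment(pairs: Sequence[EligiblePair], reps: int = 100, seed: int = 0,
                        table: CohortTable | None = None,
                        grid_size: int = 101) -> RocResult:
    """ROC of scored pairs with half-sample resampling envelopes.

    Each repetition draws half the eligible pairs at random without visit
    reuse, recomputes the fast/slow labels (median of the resample), the
    ROC and the operating point.  The summary carries 2.5-97.5 percentile
    intervals of AUC and operating-point coordinates, and an envelope band
    of sensitivity and specificity along a fixed threshold grid.
    """
    pairs = [p for p in pairs if p.score is not None]
    scores_all = np.array([p.score for p in pairs])
    full = roc([p.score for p in label_fast(pairs)],
               [p.label_fast for p in label_fast(pairs)])
    if table is not None:
        full.apoe = dict(zip(("sensitivity", "specificity"),
                             apoe_point(label_fast(pairs), table)))
    grid = np.quantile(scores_all, np.linspace(0.0, 1.0, grid_size))
    rng = np.random.default_rng(seed)
    aucs, op_sens, op_spec = [], [], []
    sens_grid = np.empty((reps, grid_size))
    spec_grid = np.empty((reps, grid_size))
    for r in range(reps):
        half = label_fast(_half_sample_no_visit_reuse(pairs, rng))
        s = np.array([p.score for p in half])
        y = np.array([p.label_fast for p in half], dtype=bool)
        rr = roc(s, y)
        aucs.append(rr.auc)
        op_sens.append(rr.operating["sensitivity"])
        op_spec.append(rr.operating["specificity"])
        for g, thr in enumerate(grid):
            se, sp = _point_at_threshold(s, y, thr)
            sens_grid[r, g] = se
            spec_grid[r, g] = sp
    pct = lambda a, q: float(np.percentile(a, q))
    full.ci = {
        "auc": (pct(aucs, 2.5), pct(aucs, 97.5)),
        "auc_mean": float(np.mean(aucs)),
        "auc_sd": float(np.std(aucs, ddof=1)),
        "operating_sensitivity": (pct(op_sens, 2.5), pct(op_sens, 97.5)),
        "operating_specificity": (pct(op_spec, 2.5), pct(op_spec, 97.5)),
    }
    full.envelope = {
        "thresholds": grid,
        "sensitivity_low": np.percentile(sens_grid, 2.5, axis=0),
        "sensitivity_high": np.percentile(sens_grid, 97.5, axis=0),
        "specificity_low": np.percentile(spec_grid, 2.5, axis=0),
        "specificity_high": np.percentile(spec_grid, 97.5, axis=0),
    }
    return full


# ---------------------------------------------------------------------------
# selection-bias regression
# ---------------------------------------------------------------------------

def build_selection_frame(pairs: Sequence[EligiblePair], table: CohortTable,
                          selected: Sequence[bool]) -> pd.DataFrame:
    """Assemble covariates for the selection-bias regression: population
    covariates, cohort, baseline modality missingness and the true
    fast-progression indicator."""
    registry = table.registry
    frame = table.to_frame()
    rows = []
    for pair, sel in zip(pairs, selected):
        subject = table.get(pair.subject_id)
        sub = frame[frame["subject_id"] == pair.subject_id].sort_values("age")
        base = sub.iloc[pair.baseline_index]
        row = {
            "selected": bool(sel),
            "age": pair.baseline_age,
            "sex_male": 1.0 if subject.sex == "M" else 0.0,
            "education_years": subject.education_years,
            "apoe4_copies": subject.apoe4_copies,
            "cohort": subject.cohort_id,
            "true_fast": bool(pair.label_fast),
        }
        for modality in ("mri", "csf", "pet_amyloid", "pet_tau"):
            names = [n for n in registry.by_modality(modality) if n in frame.columns]
            if names:
                row[f"missing_{modality}"] = float(
                    np.isnan(base[names].to_numpy(dtype=float)).all())
        rows.append(row)
    return pd.DataFrame(rows)


def selection_bias(selection_frame: pd.DataFrame) -> pd.DataFrame:
    """Logistic regression of selection status on the stated covariates.

    Returns one row per coefficient with estimate, standard error and an
    ``estimable`` flag (False under separation / failed convergence).
    """
    import statsmodels.api as sm

    df = selection_frame.dropna(subset=[c for c in selection_frame.columns
                                        if c not in ("cohort",)]).copy()
    if df["selected"].nunique() < 2:
        raise ValueError("need both selected and unselected pairs")
    design = pd.DataFrame({"const": 1.0}, index=df.index)
    for col in ("age", "sex_male", "education_years", "apoe4_copies"):
        design[col] = df[col].astype(float)
    cohorts = sorted(df["cohort"].astype(str).unique())
    for level in cohorts[1:]:
        design[f"cohort[{level}]"] = (df["cohort"].astype(str) == level).astype(float)
    for col in df.columns:
        if col.startswith("missing_") and df[col].nunique() > 1:
            design[col] = df[col].astype(float)
    design["true_fast"] = df["true_fast"].astype(float)
    # drop constant columns (beyond the intercept)
    for col in list(design.columns[1:]):
        if design[col].nunique() < 2:
            design = design.drop(columns=col)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = sm.Logit(df["selected"].astype(float), design).fit(disp=0)
        coef, se = result.params, result.bse
        ok = np.isfinite(se) & (np.abs(coef) < 20)
    except Exception:
        coef = pd.Series(np.nan, index=design.columns)
        se = pd.Series(np.nan, index=design.columns)
        ok = pd.Series(False, index=design.columns)
    return pd.DataFrame({"coef": coef, "se": se, "estimable": ok})


def pairs_to_frame(pairs: Sequence[EligiblePair]) -> pd.DataFrame:
    """Flat table of pairs (for CSV export)."""
    return pd.DataFrame([p.__dict__ for p in pairs])
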