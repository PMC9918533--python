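"""Longitudinal multi-cohort data model and staging.

A cohort is a collection of subjects, each with visits sorted by age and
partially missing endpoint measurements.  File I/O uses a long-format CSV
(one row per visit).  This module also implements the follow-up filter
(subjects need a minimum observation span), education banding, and
A/T/N/C staging from worst-to-date biomarker values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .registry import EndpointRegistry, default_registry

#: columns a cohort CSV must provide besides the endpoint columns
REQUIRED_COLUMNS = ("subject_id", "cohort", "sex", "education_years",
                    "apoe4_copies", "age", "cdr_global", "diagnosis")

VALID_CDR_GLOBAL = (0.0, 0.5, 1.0, 2.0, 3.0)


class FormatError(ValueError):
    """Raised when a cohort file violates the expected layout."""


class ConfigError(ValueError):
    """Raised for invalid threshold / configuration inputs."""


@dataclass
class VisitRecord:
    """One subject-visit: age, endpoint measurements and clinical status."""

    age: float
    measurements: dict[str, float] = field(default_factory=dict)
    cdr_global: float | None = None
    diagnosis: str | None = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.age) and self.age > 0):
            raise ValueError(f"visit age must be finite and positive, got {self.age}")
        for key, value in self.measurements.items():
            if value is not None and not math.isfinite(value):
                raise ValueError(f"non-finite measurement {key}={value}")

    def observed(self, endpoint: str) -> bool:
        return self.measurements.get(endpoint) is not None


@dataclass
class SubjectRecord:
    """A subject with visits strictly increasing in age."""

    subject_id: str
    cohort_id: str
    sex: str = "F"
    education_years: int | None = None
    apoe4_copies: int | None = None
    visits: list[VisitRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ages = [v.age for v in self.visits]
        if any(b <= a for a, b in zip(ages, ages[1:])):
            raise ValueError(f"subject {self.subject_id}: visit ages must strictly increase")
        if self.apoe4_copies is not None and self.apoe4_copies not in (0, 1, 2):
            raise ValueError(f"subject {self.subject_id}: apoe4_copies must be 0, 1 or 2")

    @property
    def followup_years(self) -> float:
        if len(self.visits) < 2:
            return 0.0
        return self.visits[-1].age - self.visits[0].age


@dataclass
class CohortTable:
    """Collection of subjects plus the endpoint registry they refer to."""

    subjects: list[SubjectRecord]
    registry: EndpointRegistry

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for s in self.subjects:
            if s.subject_id in seen:
                raise ValueError(f"duplicate subject_id {s.subject_id!r}")
            seen.add(s.subject_id)
            for v in s.visits:
                unknown = set(v.measurements) - set(self.registry)
                if unknown:
                    raise ValueError(f"measurements not in registry: {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self):
        return iter(self.subjects)

    def get(self, subject_id: str) -> SubjectRecord:
        for s in self.subjects:
            if s.subject_id == subject_id:
                return s
        raise KeyError(subject_id)

    def to_frame(self) -> pd.DataFrame:
        """Long format: one row per visit, endpoint columns, NaN = missing."""
        rows = []
        for s in self.subjects:
            for v in s.visits:
                row = {
                    "subject_id": s.subject_id,
                    "cohort": s.cohort_id,
                    "sex": s.sex,
                    "education_years": s.education_years,
                    "apoe4_copies": s.apoe4_copies,
                    "age": v.age,
                    "cdr_global": v.cdr_global,
                    "diagnosis": v.diagnosis,
                }
                for name in self.registry:
                    row[name] = v.measurements.get(name)
                rows.append(row)
        columns = list(REQUIRED_COLUMNS) + list(self.registry)
        return pd.DataFrame(rows, columns=columns)


def read_cohort_long(path: str | Path, registry: EndpointRegistry | None = None) -> CohortTable:
    """Read a long-format cohort CSV into a :class:`CohortTable`.

    Empty cells are missing values.  Visits are grouped by subject and
    sorted by age; duplicate ages within a subject are rejected.
    """
    registry = registry if registry is not None else default_registry()
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"cohort file lacks required column(s): {missing}")
    ages = pd.to_numeric(df["age"], errors="coerce")
    bad = df.index[ages.isna() & df["age"].notna()]
    if len(bad):
        raise FormatError(f"non-numeric age in row {int(bad[0]) + 2} of {path}")
    if ages.isna().any():
        raise FormatError(f"missing age in row {int(df.index[ages.isna()][0]) + 2} of {path}")
    df = df.assign(age=ages)
    return cohort_from_frame(df, registry)


def cohort_from_frame(df: pd.DataFrame, registry: EndpointRegistry | None = None) -> CohortTable:
    """Build a :class:`CohortTable` from a long-format DataFrame."""
    registry = registry if registry is not None else default_registry()
    endpoint_cols = [c for c in df.columns if c in registry]
    subjects = []
    for sid, grp in df.groupby("subject_id", sort=True):
        grp = grp.sort_values("age")
        if grp["age"].duplicated().any():
            raise FormatError(f"subject {sid}: duplicate visit ages")
        first = grp.iloc[0]
        visits = []
        for _, row in grp.iterrows():
            meas = {c: float(row[c]) for c in endpoint_cols if pd.notna(row[c])}
            cdr = float(row["cdr_global"]) if pd.notna(row.get("cdr_global")) else None
            diag = str(row["diagnosis"]) if pd.notna(row.get("diagnosis")) else None
            visits.append(VisitRecord(age=float(row["age"]), measurements=meas,
                                      cdr_global=cdr, diagnosis=diag))
        edu = int(first["education_years"]) if pd.notna(first.get("education_years")) else None
        apoe = int(first["apoe4_copies"]) if pd.notna(first.get("apoe4_copies")) else None
        subjects.append(SubjectRecord(
            subject_id=str(sid), cohort_id=str(first.get("cohort", "")),
            sex=str(first.get("sex", "F")), education_years=edu,
            apoe4_copies=apoe, visits=visits))
    return CohortTable(subjects=subjects, registry=registry)


def write_cohort_long(table: CohortTable, path: str | Path) -> None:
    """Write the long-format CSV (empty cell = missing)."""
    table.to_frame().to_csv(path, index=False)


def filter_followup(table: CohortTable, min_years: float = 1.0) -> CohortTable:
    """Keep subjects whose last-minus-first visit age spans >= ``min_years``.

    Subjects below the threshold (including single-visit subjects) are
    removed whole.  Idempotent and order-preserving.
    """
    if min_years < 0:
        raise ValueError("min_years must be >= 0")
    kept = [s for s in table.subjects if s.followup_years >= min_years]
    return CohortTable(subjects=kept, registry=table.registry)


def education_class(years: int | float | None) -> str:
    """Band education years: <=9 low, 10-15 middle, >=16 high."""
    if years is None or (isinstance(years, float) and math.isnan(years)):
        return "missing"
    if years < 0:
        raise ValueError("education years cannot be negative")
    if years <= 9:
        return "low"
    if years < 16:
        return "middle"
    return "high"


# ---------------------------------------------------------------------------
# A/T/N/C staging
# ---------------------------------------------------------------------------

#: which registry endpoints inform each biomarker axis
AXIS_BIOMARKERS = {
    "A": ("csf_abeta42", "amyloid_pet_cl"),
    "T": ("csf_ptau181", "tau_pet_suvr"),
    "N": ("hippocampus_icv",),
}


@dataclass(frozen=True)
class BiomarkerCutoff:
    """Pathological cut-off for one biomarker: crossed when the value is
    strictly beyond ``cutoff`` in the stated ``direction``."""

    cutoff: float
    direction: str  # "above" or "below"

    def crossed(self, value: float) -> bool:
        if self.direction == "above":
            return value > self.cutoff
        if self.direction == "below":
            return value < self.cutoff
        raise ConfigError(f"direction must be 'above' or 'below', got {self.direction!r}")


@dataclass
class AtnThresholds:
    """Cut-offs per axis biomarker.  The exact published values live in a
    configuration file; these defaults are explicit, documented stand-ins
    chosen from common practice (amyloid PET ~30 CL, CSF on the harmonized
    zero-mean scale, hippocampal volume ~0.40 % ICV)."""

    cutoffs: dict[str, dict[str, BiomarkerCutoff]]

    def __post_init__(self) -> None:
        registry = default_registry()
        for axis, marks in self.cutoffs.items():
            if axis not in AXIS_BIOMARKERS:
                raise ConfigError(f"unknown A/T/N axis {axis!r}")
            for name in marks:
                if name not in registry:
                    raise ConfigError(f"unknown biomarker {name!r} in thresholds")

    @classmethod
    def default(cls) -> "AtnThresholds":
        return cls(cutoffs={
            "A": {"csf_abeta42": BiomarkerCutoff(-0.25, "below"),
                  "amyloid_pet_cl": BiomarkerCutoff(30.0, "above")},
            "T": {"csf_ptau181": BiomarkerCutoff(0.25, "above"),
                  "tau_pet_suvr": BiomarkerCutoff(1.30, "above")},
            "N": {"hippocampus_icv": BiomarkerCutoff(0.40, "below")},
        })

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AtnThresholds":
        raw = yaml.safe_load(Path(path).read_text())
        cutoffs = {
            axis: {name: BiomarkerCutoff(float(d["cutoff"]), str(d["direction"]))
                   for name, d in marks.items()}
            for axis, marks in raw.items()
        }
        return cls(cutoffs=cutoffs)

    def to_yaml(self, path: str | Path) -> None:
        raw = {axis: {name: {"cutoff": c.cutoff, "direction": c.direction}
                      for name, c in marks.items()}
               for axis, marks in self.cutoffs.items()}
        Path(path).write_text(yaml.safe_dump(raw))


@dataclass(frozen=True)
class AtncProfile:
    """A/T/N each one of '+', '-', '*'; C one of '+', '~', '-', '*'.
    '*' marks an axis never measured up to the query visit."""

    A: str
    T: str
    N: str
    C: str

    def __str__(self) -> str:
        return f"A{self.A}T{self.T}N{self.N}C{self.C}"


def classify_atnc(subject: SubjectRecord, thresholds: AtnThresholds | None = None,
                  upto_visit_index: int | None = None) -> AtncProfile:
    """Stage a subject from the worst biomarker levels observed to date.

    Each of A, T, N is '+' if any measurement up to and including the query
    visit crosses its pathological cut-off, '-' if measured and never
    crossed, '*' if never measured.  C derives from the worst CDR global
    score to date: 0 -> '-', 0.5 -> '~', >=1 -> '+', never recorded -> '*'.
    The resulting statuses are monotone non-reverting across visits.
    """
    thresholds = thresholds if thresholds is not None else AtnThresholds.default()
    if upto_visit_index is None:
        upto_visit_index = len(subject.visits) - 1
    if not 0 <= upto_visit_index < len(subject.visits):
        raise IndexError(f"visit index {upto_visit_index} out of range")
    visits = subject.visits[: upto_visit_index + 1]

    status = {}
    for axis in ("A", "T", "N"):
        marks = thresholds.cutoffs.get(axis, {})
        measured = crossed = False
        for v in visits:
            for name, cut in marks.items():
                if v.observed(name):
                    measured = True
                    if cut.crossed(v.measurements[name]):
                        crossed = True
        status[axis] = "+" if crossed else ("-" if measured else "*")

    cdrs = [v.cdr_global for v in visits if v.cdr_global is not None]
    if not cdrs:
        c = "*"
    else:
        worst = max(cdrs)
        c = "-" if worst == 0 else ("~" if worst == 0.5 else "+")
    return AtncProfile(A=status["A"], T=status["T"], N=status["N"], C=c)
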