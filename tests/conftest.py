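"""Shared fixtures: hand-built micro-cohorts and seeded simulations."""

import numpy as np
import pandas as pd
import pytest

from coursemap.cohort import CohortTable, SubjectRecord, VisitRecord
from coursemap.model import CourseMap
from coursemap.registry import default_registry
from coursemap.simulate import (CohortSpec, SimConfig, simulate_cohorts,
                                simulation_normalizer)

NO_MISSING = {m: 0.0 for m in ("cognitive", "mri", "csf", "pet_amyloid", "pet_tau")}


@pytest.fixture(scope="session")
def registry():
    return default_registry()


def make_subject(sid, ages, cohort="ADNI", sex="F", education=12, apoe=0,
                 cdr=None, **measurements):
    """Build a subject whose visits carry the given per-endpoint value lists."""
    visits = []
    for i, age in enumerate(ages):
        meas = {}
        for name, values in measurements.items():
            if values[i] is not None:
                meas[name] = float(values[i])
        cdr_i = cdr[i] if cdr is not None else 0.0
        visits.append(VisitRecord(age=float(age), measurements=meas, cdr_global=cdr_i))
    return SubjectRecord(subject_id=sid, cohort_id=cohort, sex=sex,
                         education_years=education, apoe4_copies=apoe, visits=visits)


@pytest.fixture
def tiny_table(registry):
    """Three hand-built subjects used for enumeration and I/O tests."""
    subjects = [
        make_subject("s1", [70.0, 70.5, 71.0, 74.0],
                     mmse=[29, 28, 28, 25], adas13=[10, 11, 12, 20],
                     cdr=[0.0, 0.0, 0.5, 0.5]),
        make_subject("s2", [65.0, 66.4], mmse=[30, 30], cdr=[0.0, 0.0]),
        make_subject("s3", [80.0], mmse=[22], cdr=[1.0]),
    ]
    return CohortTable(subjects=subjects, registry=registry)


SIM_ENDPOINTS = ("mmse", "adas13", "cdrsb", "hippocampus_icv",
                 "csf_abeta42", "amyloid_pet_cl")


@pytest.fixture(scope="session")
def sim_cohort():
    """Moderately sized simulated cohort with realistic missingness."""
    cfg = SimConfig(
        cohorts=(CohortSpec("ADNI", 70), CohortSpec("AIBL", 50, csf_shift=0.6,
                                                    csf_scale=1.4)),
        endpoints=SIM_ENDPOINTS,
        missingness={"cognitive": 0.05, "mri": 0.4, "csf": 0.5,
                     "pet_amyloid": 0.5, "pet_tau": 0.9},
        seed=11)
    return simulate_cohorts(cfg)


@pytest.fixture(scope="session")
def dense_cohort():
    """Fully observed simulated cohort (for calibration/personalization)."""
    cfg = SimConfig(cohorts=(CohortSpec("SIM", 120),), endpoints=SIM_ENDPOINTS[:4],
                    visit_count_mean=6.0, visit_count_sd=0.5,
                    visit_count_range=(5, 7), missingness=NO_MISSING, seed=5)
    return simulate_cohorts(cfg)


@pytest.fixture(scope="session")
def fitted_model(dense_cohort):
    table, truth = dense_cohort
    endpoints = list(truth.params.endpoints)
    model = CourseMap(n_sources=2, normalizer=simulation_normalizer(endpoints),
                      endpoints=endpoints, max_outer=25)
    return model.fit(table.to_frame())


@pytest.fixture(scope="session")
def truth_model(dense_cohort):
    """A CourseMap carrying the exact generator parameters (no fitting)."""
    table, truth = dense_cohort
    endpoints = list(truth.params.endpoints)
    model = CourseMap(n_sources=truth.params.n_sources,
                      normalizer=simulation_normalizer(endpoints),
                      endpoints=endpoints)
    model.params_ = truth.params
    model.endpoints_ = endpoints
    model.effects_ = {}
    model.history_ = []
    model.n_iter_ = 0
    model.converged_ = True
    return model
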