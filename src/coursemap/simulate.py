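"""Seeded generator of multi-cohort longitudinal data with known truth.

The generator draws subjects from the same generative family as the
progression model: per-subject log-acceleration, time shift and
presentation sources act on population logistic curves, observations add
independent Gaussian noise on the (0, 1) scale, and modality-wise
missingness masks emulate the very uneven availability of cognition
(nearly complete), MRI (about half), CSF and PET (largely missing) seen
in real multi-cohort AD studies.  Cohorts can differ in size, baseline
age distribution and CSF assay (an affine offset on the native CSF
scale), which is what the harmonization step is meant to undo.

Everything is deterministic given the seed, and the ground truth
(population parameters, individual effects, noiseless trajectories) is
returned alongside the table so that parameter recovery, forecast error
and trial labelling can all be checked against the latent truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .cohort import CohortTable, SubjectRecord, VisitRecord, cohort_from_frame
from .model import IndividualEffects, PopulationParams, individual_curve
from .preprocessing import EndpointNormalizer, NormEntry
from .registry import EndpointRegistry, default_registry

DEFAULT_ENDPOINTS = ("mmse", "adas13", "cdrsb", "hippocampus_icv", "ventricles_icv",
                     "csf_abeta42", "csf_ptau181", "amyloid_pet_cl", "tau_pet_suvr")

#: native value at normalized 0 (most normal) and at normalized 1, for the
#: endpoints whose native scale is not a theoretical cognitive range.
NATIVE_MAPS: dict[str, tuple[float, float]] = {
    "hippocampus_icv": (0.58, 0.25),
    "ventricles_icv": (1.0, 8.0),
    "csf_abeta42": (1.5, -2.0),
    "csf_ptau181": (-1.2, 4.0),
    "amyloid_pet_cl": (0.0, 100.0),
    "tau_pet_suvr": (1.15, 3.5),
}

#: (inflexion delay vs t0 in years, logistic rate per year) per endpoint:
#: amyloid changes earliest, then tau and neurodegeneration, cognition last.
DEFAULT_TIMING: dict[str, tuple[float, float]] = {
    "amyloid_pet_cl": (-12.0, 0.18),
    "csf_abeta42": (-10.0, 0.15),
    "csf_ptau181": (-6.0, 0.12),
    "tau_pet_suvr": (-3.0, 0.15),
    "hippocampus_icv": (0.0, 0.12),
    "ventricles_icv": (1.5, 0.10),
    "adas13": (3.0, 0.20),
    "mmse": (5.0, 0.22),
    "cdrsb": (7.0, 0.25),
}

#: modality-wise missingness (probability a modality is absent at a visit)
DEFAULT_MISSINGNESS: dict[str, float] = {
    "cognitive": 0.04,
    "mri": 0.55,
    "csf": 0.75,
    "pet_amyloid": 0.70,
    "pet_tau": 0.90,
}

#: empirical APOE-e4 copy frequencies (0 / 1 / 2 copies) of a large
#: North-American memory-clinic cohort
DEFAULT_APOE_PROBS = (0.555, 0.356, 0.087)


@dataclass(frozen=True)
class CohortSpec:
    """One simulated cohort: size, baseline ages and CSF assay offsets."""

    name: str
    n_subjects: int
    age_mean: float = 73.3
    age_sd: float = 7.0
    csf_shift: float = 0.0
    csf_scale: float = 1.0


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of the simulated multi-cohort dataset."""

    cohorts: tuple[CohortSpec, ...] = (CohortSpec("ADNI-SIM", 300),)
    endpoints: tuple[str, ...] = DEFAULT_ENDPOINTS
    n_sources: int = 2
    age_bounds: tuple[float, float] = (50.0, 92.0)
    visit_count_mean: float = 6.0
    visit_count_sd: float = 2.0
    visit_count_range: tuple[int, int] = (2, 9)
    gap_mean_years: float = 0.8
    gap_sd_years: float = 0.25
    gap_range_years: tuple[float, float] = (0.5, 1.5)
    sigma_xi: float = 0.3
    sigma_tau: float = 5.0
    source_scale: float = 1.0
    noise_sd: float = 0.05
    missingness: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_MISSINGNESS))
    subject_level_missingness: bool = False
    apoe_probs: tuple[float, float, float] = DEFAULT_APOE_PROBS
    female_frac: float = 0.53
    education_probs: tuple[float, float, float] = (0.15, 0.45, 0.40)
    cdr_bands: tuple[float, float, float, float] = (0.25, 4.0, 9.0, 15.0)
    clip_observations: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for probs in (self.apoe_probs, self.education_probs):
            # empirical frequencies may carry rounding; renormalized at draw time
            if abs(sum(probs) - 1.0) > 0.02:
                raise ValueError("probabilities must sum to 1")
        if min(self.sigma_xi, self.sigma_tau, self.source_scale, self.noise_sd) < 0:
            raise ValueError("scales must be >= 0")
        if self.visit_count_range[0] < 1:
            raise ValueError("subjects need at least one visit")


@dataclass
class GroundTruth:
    """Latent state behind a simulated table."""

    params: PopulationParams
    effects: dict[str, IndividualEffects]
    latent: pd.DataFrame          # noiseless normalized values, long format
    config: SimConfig

    def latent_value(self, subject_id: str, endpoint: str, age: float) -> float:
        """Noiseless normalized value of the subject's curve at ``age``."""
        k = self.params.endpoints.index(endpoint)
        return float(individual_curve(age, self.params, self.effects[subject_id], k))

    def latent_native_rate(self, subject_id: str, endpoint: str,
                           age0: float, age1: float) -> float:
        """Oriented native-scale annual rate of the noiseless curve."""
        from .trial import annual_rate  # local import to avoid a cycle
        entry = simulation_normalizer([endpoint]).entries_[endpoint]
        y0 = entry.backward(self.latent_value(subject_id, endpoint, age0))
        y1 = entry.backward(self.latent_value(subject_id, endpoint, age1))
        spec = default_registry()[endpoint]
        return annual_rate(float(y0), float(y1), age1 - age0, spec)


def default_population_params(endpoints: Sequence[str] = DEFAULT_ENDPOINTS,
                              n_sources: int = 2, noise_sd: float = 0.05,
                              sigma_xi: float = 0.3, sigma_tau: float = 5.0,
                              seed: int = 0, t0: float = 78.0) -> PopulationParams:
    """Population curves with the canonical biomarker ordering (amyloid
    first, cognition last) and identifiability constraints satisfied."""
    endpoints = list(endpoints)
    K = len(endpoints)
    delta = np.array([DEFAULT_TIMING.get(e, (0.0, 0.15))[0] for e in endpoints])
    rates = np.array([DEFAULT_TIMING.get(e, (0.0, 0.15))[1] for e in endpoints])
    delta = delta - delta.mean()
    rng = np.random.default_rng(seed)
    A = 0.5 * rng.standard_normal((K, n_sources))
    if n_sources:
        A -= np.outer(rates, rates @ A) / (rates @ rates)
    return PopulationParams(t0=t0, delta=delta, rates=rates, mixing=A,
                            sigma_xi=sigma_xi, sigma_tau=sigma_tau,
                            sigma_noise=np.full(K, noise_sd),
                            endpoints=endpoints)


def simulation_normalizer(endpoints: Sequence[str]) -> EndpointNormalizer:
    """The exact normalization used by the generator (affine per endpoint),
    packaged as a fitted :class:`EndpointNormalizer`.  With it, normalizing
    simulated native data recovers the latent (0, 1) values exactly."""
    registry = default_registry()
    entries = {}
    for name in endpoints:
        spec = registry[name]
        if spec.modality == "cognitive":
            entries[name] = NormEntry("theoretical-bounds",
                                      float(spec.native_best), float(spec.native_worst))
        else:
            zero, one = NATIVE_MAPS[name]
            entries[name] = NormEntry("theoretical-bounds", zero, one)
    return EndpointNormalizer.from_dict({k: {"kind": e.kind, "zero_point": e.zero_point,
                                             "one_point": e.one_point}
                                         for k, e in entries.items()})


def _truncated_normal(rng, mean, sd, lo, hi):
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return x
    return float(np.clip(mean, lo, hi))


def cdr_from_cdrsb(native_cdrsb: float, bands: tuple[float, float, float, float]) -> float:
    """CDR global band from the (latent) CDR sum-of-boxes value."""
    b0, b1, b2, b3 = bands
    if native_cdrsb <= b0:
        return 0.0
    if native_cdrsb <= b1:
        return 0.5
    if native_cdrsb <= b2:
        return 1.0
    if native_cdrsb <= b3:
        return 2.0
    return 3.0


_DIAGNOSIS = {0.0: "CU", 0.5: "MCI"}


def simulate_cohorts(config: SimConfig,
                     params: PopulationParams | None = None
                     ) -> tuple[CohortTable, GroundTruth]:
    """Draw a multi-cohort longitudinal table plus its ground truth."""
    endpoints = list(config.endpoints)
    registry = default_registry()
    if params is None:
        params = default_population_params(
            endpoints, n_sources=config.n_sources, noise_sd=config.noise_sd,
            sigma_xi=config.sigma_xi, sigma_tau=config.sigma_tau, seed=config.seed)
    norm = simulation_normalizer(endpoints)
    K = len(endpoints)
    q = params.n_sources
    rng = np.random.default_rng(config.seed)
    modality_of = {name: registry[name].modality for name in endpoints}

    rows, latent_rows = [], []
    effects: dict[str, IndividualEffects] = {}
    for cohort in config.cohorts:
        for i in range(cohort.n_subjects):
            sid = f"{cohort.name}-{i:04d}"
            sex = "F" if rng.random() < config.female_frac else "M"
            edu_probs = np.asarray(config.education_probs) / np.sum(config.education_probs)
            edu_band = rng.choice(3, p=edu_probs)
            education = int(rng.integers(*((6, 10), (10, 16), (16, 21))[edu_band]))
            apoe_probs = np.asarray(config.apoe_probs) / np.sum(config.apoe_probs)
            apoe = int(rng.choice(3, p=apoe_probs))
            xi = rng.normal(0.0, config.sigma_xi)
            tau = rng.normal(0.0, config.sigma_tau)
            s = rng.normal(0.0, config.source_scale, size=q)
            eff = IndividualEffects(xi, tau, s, params.mixing @ s if q else np.zeros(K))
            effects[sid] = eff

            age0 = _truncated_normal(rng, cohort.age_mean, cohort.age_sd,
                                     *config.age_bounds)
            n_visits = int(np.clip(round(rng.normal(config.visit_count_mean,
                                                    config.visit_count_sd)),
                                   *config.visit_count_range))
            gaps = np.clip(rng.normal(config.gap_mean_years, config.gap_sd_years,
                                      size=max(n_visits - 1, 0)),
                           *config.gap_range_years)
            ages = age0 + np.concatenate([[0.0], np.cumsum(gaps)])

            if config.subject_level_missingness:
                absent = {m: rng.random() < r for m, r in config.missingness.items()}

            for age in ages:
                clean = np.array([individual_curve(age, params, eff, k)
                                  for k in range(K)])
                noisy = clean + rng.normal(0.0, params.sigma_noise)
                if config.clip_observations:
                    noisy = np.clip(noisy, 0.0, 1.0)
                latent_row = {"subject_id": sid, "age": float(age)}
                row = {"subject_id": sid, "cohort": cohort.name, "sex": sex,
                       "education_years": education, "apoe4_copies": apoe,
                       "age": float(age)}
                for k, name in enumerate(endpoints):
                    latent_row[name] = float(clean[k])
                    mod = modality_of[name]
                    if config.subject_level_missingness:
                        drop = absent.get(mod, False)
                    else:
                        drop = rng.random() < config.missingness.get(mod, 0.0)
                    if drop:
                        row[name] = np.nan
                        continue
                    value = float(norm.entries_[name].backward(noisy[k]))
                    if mod == "csf":
                        value = cohort.csf_scale * value + cohort.csf_shift
                    row[name] = value
                if "cdrsb" in endpoints:
                    native_sb = float(norm.entries_["cdrsb"].backward(
                        latent_row["cdrsb"]))
                    cdr = cdr_from_cdrsb(native_sb, config.cdr_bands)
                    row["cdr_global"] = cdr
                    row["diagnosis"] = _DIAGNOSIS.get(cdr, "Dementia")
                else:
                    row["cdr_global"] = np.nan
                    row["diagnosis"] = None
                rows.append(row)
                latent_rows.append(latent_row)

    df = pd.DataFrame(rows)
    for col in ("cdr_global", "diagnosis"):
        if col not in df.columns:
            df[col] = np.nan
    table = cohort_from_frame(df, registry)
    truth = GroundTruth(params=params, effects=effects,
                        latent=pd.DataFrame(latent_rows), config=config)
    return table, truth


def derive_clinical(table: CohortTable, ground_truth: GroundTruth,
                    bands: tuple[float, float, float, float] | None = None
                    ) -> CohortTable:
    """Recompute CDR global and diagnosis from the latent CDR-SB curves.

    The generator already labels visits this way; this re-derivation lets a
    caller change the bands after the fact.
    """
    if "cdrsb" not in ground_truth.params.endpoints:
        raise ValueError("latent CDR-SB trajectories are required")
    bands = bands if bands is not None else ground_truth.config.cdr_bands
    entry = simulation_normalizer(["cdrsb"]).entries_["cdrsb"]
    subjects = []
    for s in table.subjects:
        visits = []
        for v in s.visits:
            latent = ground_truth.latent_value(s.subject_id, "cdrsb", v.age)
            cdr = cdr_from_cdrsb(float(entry.backward(latent)), bands)
            visits.append(VisitRecord(age=v.age, measurements=dict(v.measurements),
                                      cdr_global=cdr,
                                      diagnosis=_DIAGNOSIS.get(cdr, "Dementia")))
        subjects.append(SubjectRecord(subject_id=s.subject_id, cohort_id=s.cohort_id,
                                      sex=s.sex, education_years=s.education_years,
                                      apoe4_copies=s.apoe4_copies, visits=visits))
    return CohortTable(subjects=subjects, registry=table.registry)


def trial_suite(config: SimConfig, design, target_pairs: int = 200,
                thresholds=None, max_batches: int = 25):
    """Generate a cohort guaranteed to contain eligible visit pairs.

    Simulates batches under ``config`` (with shifted seeds), keeps only
    subjects that contribute at least one eligible (baseline, follow-up)
    pair for ``design``, and accumulates until ``target_pairs`` pairs are
    available.  Returns ``(table, truth, pairs)``.
    """
    from .trial import find_eligible_pairs

    kept_subjects: list[SubjectRecord] = []
    effects: dict[str, IndividualEffects] = {}
    latent_frames = []
    params = None
    n_pairs = 0
    for batch in range(max_batches):
        cohorts = tuple(replace(c, name=f"{c.name}.b{batch}") for c in config.cohorts)
        batch_cfg = replace(config, cohorts=cohorts, seed=config.seed + 1000 * batch)
        table, truth = simulate_cohorts(batch_cfg, params=params)
        params = truth.params
        pairs = find_eligible_pairs(table, design, thresholds=thresholds)
        contributing = {p.subject_id for p in pairs}
        for s in table.subjects:
            if s.subject_id in contributing:
                kept_subjects.append(s)
                effects[s.subject_id] = truth.effects[s.subject_id]
        latent_frames.append(truth.latent[truth.latent["subject_id"].isin(contributing)])
        n_pairs += len(pairs)
        if n_pairs >= target_pairs:
            break
    else:
        raise RuntimeError(
            f"only {n_pairs} eligible pairs found after {max_batches} batches "
            f"(target {target_pairs}); design {design.name!r} may be unreachable "
            f"under this configuration")
    registry = default_registry()
    merged = CohortTable(subjects=kept_subjects, registry=registry)
    truth_all = GroundTruth(params=params, effects=effects,
                            latent=pd.concat(latent_frames, ignore_index=True),
                            config=config)
    pairs = find_eligible_pairs(merged, design, thresholds=thresholds)
    return merged, truth_all, pairs
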