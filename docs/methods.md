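# Methods

## Model

Every endpoint is first mapped to a common (0, 1) pathology scale with 0
the most normal value and 1 the maximal pathological change. Cognitive
scales use their theoretical bounds (MMSE 30→0 maps to 0→1, ADAS-Cog13
0→85, CDR-SB 0→18); amyloid PET is clipped to [0, 100] centiloids and
divided by 100; MRI volumes, tau PET and harmonized CSF are clipped at
the 1st and 99th percentile of the *training* values (linear
interpolation between order statistics) and mapped linearly, with
endpoints that decrease with disease (hippocampal volume, CSF Aβ1–42)
flipped. Clip bounds are estimated on the training split only and frozen
into the fitted model, so validation data cannot leak into the
normalization. Each forward map stores the two native anchor values sent
to 0 and to 1; denormalization is the exact affine inverse on the
non-clipped range.

On that scale, endpoint k follows a population logistic curve with rate
a_k (per year, on the logit scale) and inflexion delay δ_k (years)
around a reference age t0. Subject i reparametrizes time through an
acceleration factor exp(ξ_i) and a time shift τ_i, and shifts the
relative severity of endpoints through a low-rank space shift
w_i = A s_i:

    ψ_i(t) = t0 + exp(ξ_i) (t − t0 − τ_i)
    y_ik(t) = sigmoid( a_k (ψ_i(t) − t0 − δ_k) + w_ik ) + ε,  ε ~ N(0, σ_k²)

This is the minimal parametrization that keeps the ingredients of
disease course mapping — per-endpoint rates and inflexion ages, an
individual time-warp, and a presentation shift — while remaining
identifiable at desk scale. Identifiability conventions: mean(δ) = 0
(t0 is the average inflexion age), the columns of A are orthogonal to
the rate vector (a_1..a_K) so that presentation cannot mimic a time
shift, sources have unit variance (their scale lives in the columns of
A), and ξ and τ are zero-mean. Missing entries drop out of the
likelihood; no imputation happens anywhere.

### Calibration

Calibration alternates two steps until the penalized objective changes
by less than `tol` (default 1e-6 relative) or `max_outer` iterations:

1. joint L-BFGS over all fixed effects and all individual effects with
   analytic gradients, rates parametrized on the log scale, δ centered
   by reparametrization;
2. closed-form variance updates: σ_k² from residuals; σ_ξ² and σ_τ² as
   Laplace-corrected second moments (MAP² plus the Gauss–Newton
   posterior variance of each subject's effects). The correction matters
   because subjects observed on the flat tails of their curves carry
   little information about τ, and their shrunken MAP estimates would
   otherwise bias the heterogeneity scales downwards.

After every outer iteration the representation is re-canonicalized
without changing predictions: τ and ξ are recentered (absorbed into t0
and the rates/delays), the component of A parallel to the rates is
absorbed into per-subject time shifts, and source variances are rescaled
into A.

Initialization is deterministic and data-driven: t0 is the mean observed
age; a_k and δ_k come from a pooled linear regression of the logit of
the (clipped) normalized values on age; a first stage fits the model
without space shifts, then A and s are initialized from the leading
principal directions of the per-subject logit-scale residuals and the
full model is fitted. Noise floors (σ_k ≥ 1e-3, σ_ξ ≥ 1e-3, σ_τ ≥ 1e-2)
keep degenerate simulations (zero heterogeneity) numerically safe while
still recovering variances near zero.

### Personalization and forecasting

An unseen subject's (ξ, τ, s) is the MAP estimate under the learnt
prior, computed by L-BFGS with analytic gradients from any subset of
visits with at least one observed measurement. Forecasts evaluate the
personalized curves at the requested ages and denormalize; they are
monotone in age per endpoint and bounded by the native scale by
construction. Model files are single JSON documents (parameters,
normalization anchors, configuration, diagnostics); Python's JSON float
round trip is exact, so a saved and reloaded model forecasts
bit-identically.

## Harmonization

CSF biomarkers measured with different immunoassays are harmonized per
cohort: a linear mixed model with per-subject random intercept regresses
the biomarker on age, APOE-ε4 copies and CDR global (all numeric — the
minimal, invertible coding), and the measurements are affinely rescaled
so the fitted intercept is 0 and the empirical variance is 1. Age is
centered at a fixed 75-year reference inside the regression; otherwise
the "intercept" would be an extrapolation to age zero and its estimation
error (slope error × 72 years) would dominate the cross-cohort
alignment. "Total variance is 1" is the population variance of the
transformed measurements within the cohort, which makes the property
directly testable.

## Validation protocol

Forecast tasks are generated combinatorially: every window of 1–3
consecutive visits of a subject, provided the subject is 50–90 years old
and at CDR global ≤ 2 at the latest unblinded visit (visits without a
CDR score are skipped), combined with every later visit 1.4–6.6 years
ahead at which the endpoint is observed. Error analyses run on random
maximal subsets of *disjoint* tasks — tasks of one subject sharing no
visit, unblinded or target; visits are subject-scoped so tasks of
different subjects never conflict. Absolute errors on the native scale
are modelled with a linear mixed model (random intercept per subject)
on the A/T/N/C stage, cohort, APOE copies, sex, education band and
window size, plus standardized age ((age−75)/7.5), horizon
((years−3)/1) and mean inter-visit gap ((months−8)/3) and per-modality
missingness fractions; for single-visit windows the gap covariate is set
to the 8-month reference. The intercept is the adjusted MAE of the
reference profile (ADNI cohort, female, 0 ε4 copies, middle education,
A+T+N+C~ stage, two unblinded visits); empirical 95% intervals are the
2.5–97.5 percentiles over 100 disjoint-task resamples. Rank-deficient
design columns are dropped with a warning.

Cross-validation splits are two independent shuffled 5-fold partitions
of the training pool: ten training subsets, every subject left out
exactly twice; forecasts from multiple model instances are combined by
arithmetic averaging.

## Trial simulation and power

A design fixes an age window, allowed CDR global values, an optional
MMSE floor, a biomarker requirement (amyloid or p-tau positivity,
evaluated worst-visit-to-date from CSF *or* PET with the same threshold
configuration as A/T/N/C staging), an optional APOE rule, a primary
outcome and a duration with tolerance. All (baseline, follow-up) visit
pairs with the outcome observed at both ends, criteria met at baseline
and elapsed time within duration ± tolerance are eligible; intermediate
visits are ignored and the tolerance bounds are inclusive. The outcome
is the oriented annual rate of change (sign-flipped where higher native
values are better, so larger always means worse). Fast progressors are
the half above the median outcome, ties to the slow group. The
prognostic score personalizes the model on the single baseline visit and
converts the forecast at the follow-up age into an oriented annual rate;
no follow-up measurement enters it. ROC curves sweep all thresholds
(trapezoidal AUC); the operating point is the median score, splitting
the screened population into equal halves within one. Confidence
intervals and envelope bands come from 100 half-sample resamples in
which no visit of a subject is used twice; when within-subject pair
conflicts make the exact half unreachable, the run uses the largest
conflict-free draw. The headline (non-resampled) analysis uses all
eligible pairs. A logistic regression of selection status on age, sex,
education, APOE copies, cohort, missing baseline modalities and the true
fast label quantifies selection bias; separated or non-converged
coefficients are flagged non-estimable.

The hypothetical treatment multiplies a worsening participant's oriented
rate by (1 − effect) and leaves improving participants untouched. The
default power contrast is deterministic — control and treated arms are
the untreated and treated transforms of the same selected outcomes —
which removes allocation noise; a seeded random 1:1 allocation mode is
available. Cohen's d uses the pooled (n−1-weighted) standard deviation,
and the two-arm sample size is the asymptotic normal-quantile formula
n/arm = ⌈2 (z_{1−α/2} + z_power)² / d²⌉ at α = 0.05 two-sided and 80%
power, per-arm ceiling, total = 2 × per-arm. An independent Monte-Carlo
t-test simulation validates the formula; at large effects (d = 1) the
asymptotic size of 16 per arm yields a true power slightly above 78%,
the known small-sample cost of the normal approximation.

## Synthetic data

The generator draws from exactly the model family above, so calibration
and personalization can be checked against ground truth. Defaults
describe a memory-clinic-style study: baseline ages 73.3 ± 7.0 years
(truncated to 50–92), 6 ± 2 visits (2–9) at 0.8 ± 0.25-year gaps
(0.5–1.5), APOE-ε4 copy frequencies 55.5/35.6/8.7%, 53% women, education
bands 15/45/40% (low/middle/high), σ_ξ = 0.3, σ_τ = 5 years, unit
sources, observation noise 0.05 on the (0, 1) scale. Inflexion delays
follow the canonical biomarker cascade with multi-year separations —
amyloid PET earliest (−12 y from the mean), then CSF Aβ, p-tau, tau PET,
hippocampal volume, ventricles, ADAS-Cog13, MMSE, and CDR-SB last
(+7 y) — and rates 0.10–0.25 per year. Missingness is modality-wise MCAR
by default (cognition 4%, MRI 55%, CSF 75%, amyloid PET 70%, tau PET
90%, mirroring typical availability), with an optional subject-level
"modality never acquired" mode. CDR global and diagnosis derive from the
latent CDR-SB curve through configurable bands (0 / 0.5 / 1 / 2 / 3 at
0.25, 4, 9, 15 points). Cohorts can differ in size, age distribution and
CSF assay (affine distortion on the native scale). Observations are not
clipped to the native bounds by default, keeping the noise model exactly
Gaussian (a `clip_observations` flag restores hard bounds); real scales
are bounded and pile up at their ends, which this generator therefore
does not emulate. Other real-data features outside the generator:
informative (non-MCAR) missingness, dropout correlated with progression,
measurement error that grows with severity, site effects, and model
misspecification — passing tests show correctness of the pipeline under
the model's own assumptions, not robustness to these.

The `trial_suite` helper accumulates simulation batches and keeps only
subjects contributing at least one eligible pair until a requested pair
count is reached, so design-specific tests need not oversample.

## Problem sizes

The test suite calibrates on cohorts of 80–300 subjects with 3–6
endpoints; the recovery check uses 300 subjects, six endpoints, six
visits and noise 0.05, recovering t0 within ±1.5 years, the exact rank
order of the inflexion delays, rates within 15% and σ_τ within 25%.
The forecaster comparison trains on 200 subjects and evaluates ≥ 200
disjoint three-year tasks on an independent 260-subject cohort. The
acceptance script uses the same sizes plus a 300-subject validation
cohort for the trial simulation (~1,000 eligible pairs) and 10,000
Monte-Carlo replicates for the power check; it completes in well under a
minute on one CPU.

## Limitations

The exact parametrization, constraint set and estimation algorithm of
the published disease-course-mapping software differ in detail; this
package implements the structure described above and defines correctness
by parameter recovery and protocol invariants, not by equality with any
particular implementation. A/T/N/C thresholds, centiloid conversion
constants and harmonization equations are configuration with documented
defaults, not published constants. The alternating optimizer finds a
local optimum; the deterministic initialization makes runs reproducible
but a pathological dataset could still require restarts. Recurrent-
network comparators are not reimplemented; external per-task forecasts
and per-pair scores plug into the same harness through CSV.
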