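"""Hypothetical-treatment model, effect size and trial sample size.

The treatment multiplies a participant's oriented annual rate of change
by (1 - effect) when the participant worsens, and does nothing when they
improve.  Effect size is Cohen's d between control and treated outcome
distributions, and the two-arm sample size comes from the asymptotic
(normal-quantile) two-sample t-test formula

    n_per_arm = ceil( 2 (z_{1-alpha/2} + z_power)^2 / d^2 ).

Enrichment is assessed by computing the sample size for all eligible
participants and for the subgroup predicted to progress fast; the
reduction is 1 - n_enriched / n_all.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class PowerResult:
    """Sample-size computation for one treatment effect and population."""

    effect: float
    condition: str                 # "all-eligible" or "predicted-fast"
    cohens_d: float
    n_per_arm: int
    n_total: int
    reduction_pct: float | None = None   # vs the all-eligible condition

    def __post_init__(self) -> None:
        if self.n_per_arm < 2:
            raise ValueError("sample size per arm must be >= 2")
        if self.n_total != 2 * self.n_per_arm:
            raise ValueError("two-arm total must be twice the per-arm size")


def apply_treatment(oriented_rate, effect: float):
    """Treated rate: worsening slows by ``effect``; improvement unchanged."""
    if not 0.0 <= effect < 1.0:
        raise ValueError("treatment effect must be in [0, 1)")
    rate = np.asarray(oriented_rate, dtype=float)
    treated = np.where(rate > 0, (1.0 - effect) * rate, rate)
    return float(treated) if np.isscalar(oriented_rate) else treated


def cohens_d(sample_a: Sequence[float], sample_b: Sequence[float]) -> float:
    """Difference of means over the pooled (n-1 weighted) standard deviation."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least two values")
    pooled_var = (((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1))
                  / (a.size + b.size - 2))
    if pooled_var == 0:
        raise ValueError("zero pooled variance: effect size undefined")
    return float((a.mean() - b.mean()) / math.sqrt(pooled_var))


def sample_size(d: float, alpha: float = 0.05, power: float = 0.80) -> tuple[int, int]:
    """(n per arm, two-arm total) from the asymptotic t-test formula."""
    if d == 0:
        raise ValueError("sample size diverges at zero effect size")
    z_alpha = stats.norm.ppf(1.0 - alpha / 2.0)
    z_power = stats.norm.ppf(power)
    n_arm = math.ceil(2.0 * (z_alpha + z_power) ** 2 / d ** 2)
    n_arm = max(n_arm, 2)
    return n_arm, 2 * n_arm


def treatment_contrast(outcomes: Sequence[float], effect: float,
                       allocation_seed: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Control and treated outcome samples for one population.

    Default (deterministic) mode contrasts the untreated outcomes with the
    treated transform of the same outcomes.  With ``allocation_seed`` the
    population is instead randomly split 1:1 into a control and a treated
    arm (unblinded allocation), which adds allocation noise.
    """
    outcomes = np.asarray(outcomes, dtype=float)
    if allocation_seed is None:
        return outcomes.copy(), apply_treatment(outcomes, effect)
    rng = np.random.default_rng(allocation_seed)
    order = rng.permutation(outcomes.size)
    half = outcomes.size // 2
    control = outcomes[order[:half]]
    treated = apply_treatment(outcomes[order[half:]], effect)
    return control, treated


def enrichment_comparison(outcomes: Sequence[float], selected: Sequence[bool],
                          effects: Sequence[float] = (0.20, 0.25, 0.30),
                          alpha: float = 0.05, power: float = 0.80,
                          allocation_seed: int | None = None) -> list[PowerResult]:
    """Sample sizes with and without prognostic enrichment.

    ``outcomes`` are the oriented annual rates of all eligible pairs and
    ``selected`` flags the predicted-fast subgroup (operating-point
    selection).  For each effect, Cohen's d and the two-arm sample size
    are computed for both populations, plus the enrichment reduction.
    """
    outcomes = np.asarray(outcomes, dtype=float)
    selected = np.asarray(selected, dtype=bool)
    if not selected.any():
        raise ValueError("the enriched group is empty")
    results = []
    for effect in effects:
        per_condition = {}
        for condition, values in (("all-eligible", outcomes),
                                  ("predicted-fast", outcomes[selected])):
            control, treated = treatment_contrast(values, effect, allocation_seed)
            d = cohens_d(control, treated)
            n_arm, n_total = sample_size(abs(d), alpha=alpha, power=power)
            per_condition[condition] = (d, n_arm, n_total)
        d_all, arm_all, tot_all = per_condition["all-eligible"]
        d_en, arm_en, tot_en = per_condition["predicted-fast"]
        results.append(PowerResult(effect=effect, condition="all-eligible",
                                   cohens_d=d_all, n_per_arm=arm_all, n_total=tot_all))
        results.append(PowerResult(effect=effect, condition="predicted-fast",
                                   cohens_d=d_en, n_per_arm=arm_en, n_total=tot_en,
                                   reduction_pct=100.0 * (1.0 - tot_en / tot_all)))
    return results


def monte_carlo_power(d: float, n_per_arm: int, reps: int = 10000,
                      alpha: float = 0.05, seed: int = 0) -> float:
    """Empirical power of the two-sample t-test at the given size.

    Independent simulation used to validate the asymptotic formula: draws
    ``reps`` pairs of normal samples separated by ``d`` standard
    deviations and counts two-sided rejections.
    """
    rng = np.random.default_rng(seed)
    a = rng.standard_normal((reps, n_per_arm)) + d
    b = rng.standard_normal((reps, n_per_arm))
    t, p = stats.ttest_ind(a, b, axis=1)
    return float((p < alpha).mean())
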