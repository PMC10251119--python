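"""Lineage-level outcome metrics.

Under neutral expectations every founder lineage should end with the same
biomass, ``X_E = X_t / N``.  Realised lineage biomass ``X_i`` is compared to
that expectation and classified as *languishing* (``X_i < 0.3 X_E``),
*thriving* (``X_i > 0.9 X_E``) or *barely surviving* (the closed interval in
between).  The thriving cut sits below ``X_E`` itself so that a lineage doing
well next to a single massively dominant competitor still counts as thriving.

The drift-fairness check treats the per-site biggest-loser counts like a test
of m dice for fairness: a chi-square goodness-of-fit test against the uniform
expectation, judged at a Bonferroni-corrected level alpha = 0.05 / m.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "LANGUISHING",
    "THRIVING",
    "BARELY_SURVIVING",
    "ClassificationThresholds",
    "FairnessResult",
    "expected_abundance",
    "classify",
    "fairness_test",
    "BONFERRONI_M_CROWDING",
]

LANGUISHING = "languishing"
THRIVING = "thriving"
BARELY_SURVIVING = "barely_surviving"

#: number of crowding conditions (3 spacings x 3 population sizes), the
#: Bonferroni divisor for the fairness tests
BONFERRONI_M_CROWDING = 9


@dataclass(frozen=True)
class ClassificationThresholds:
    """Survival-class cut points as multiples of the expected abundance."""

    languish_below: float = 0.3
    thrive_above: float = 0.9

    def __post_init__(self):
        if not (0 < self.languish_below < self.thrive_above):
            raise ValueError(
                "thresholds must satisfy 0 < languish_below < thrive_above"
            )


DEFAULT_THRESHOLDS = ClassificationThresholds()


def expected_abundance(X_t: float, N: int) -> float:
    """Neutral per-lineage expectation ``X_E = X_t / N``."""
    if N < 1:
        raise ValueError(f"lineage count N must be >= 1, got {N}")
    if X_t < 0:
        raise ValueError(f"total biomass must be >= 0, got {X_t}")
    return X_t / N


def classify(X_i: float, X_E: float,
             thresholds: ClassificationThresholds = DEFAULT_THRESHOLDS) -> str:
    """Three-way survival classification of one lineage.

    The middle class is the closed interval
    ``languish_below * X_E <= X_i <= thrive_above * X_E``; both comparisons
    at the thriving boundary are therefore non-strict on the barely-surviving
    side.
    """
    if X_i < 0:
        raise ValueError(f"lineage biomass must be >= 0, got {X_i}")
    if X_E <= 0:
        raise ValueError(f"expected abundance must be > 0, got {X_E}")
    if X_i < thresholds.languish_below * X_E:
        return LANGUISHING
    if X_i > thresholds.thrive_above * X_E:
        return THRIVING
    return BARELY_SURVIVING


@dataclass(frozen=True)
class FairnessResult:
    statistic: float
    pvalue: float
    alpha: float
    significant: bool
    dof: int
    method: str


def fairness_test(counts, n_conditions: int = BONFERRONI_M_CROWDING,
                  monte_carlo: int = 0, seed: int = 0) -> FairnessResult:
    """Chi-square test of biggest-loser counts against uniform expectation.

    Parameters
    ----------
    counts
        Number of runs in which each initial site was the biggest loser.
    n_conditions
        Bonferroni divisor m; significance is judged at ``alpha = 0.05 / m``.
    monte_carlo
        If > 0, the p-value is computed by multinomial simulation with this
        many replicates instead of the asymptotic chi-square distribution
        (useful for reduced-replicate desk runs with small expected counts).
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 1 or counts.size < 2:
        raise ValueError("counts must be a 1-D vector with >= 2 sites")
    if np.any(counts < 0):
        raise ValueError("counts must be nonnegative")
    n_runs = counts.sum()
    if n_runs == 0:
        raise ValueError("all-zero count table")
    if n_conditions < 1:
        raise ValueError("n_conditions (Bonferroni m) must be >= 1")
    k = counts.size
    expected = n_runs / k
    statistic = float(np.sum((counts - expected) ** 2 / expected))
    dof = k - 1
    if monte_carlo > 0:
        rng = np.random.default_rng(seed)
        sims = rng.multinomial(int(round(n_runs)), np.full(k, 1.0 / k),
                               size=monte_carlo)
        sim_stats = np.sum((sims - expected) ** 2 / expected, axis=1)
        pvalue = float((1 + np.sum(sim_stats >= statistic - 1e-12)) / (monte_carlo + 1))
        method = f"monte-carlo({monte_carlo})"
    else:
        pvalue = float(stats.chi2.sf(statistic, dof))
        method = "asymptotic"
    alpha = 0.05 / n_conditions
    return FairnessResult(
        statistic=statistic, pvalue=pvalue, alpha=alpha,
        significant=pvalue < alpha, dof=dof, method=method,
    )
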