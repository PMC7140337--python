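"""Confidence intervals, McNemar comparison of paired classifiers, Holm adjustment.

Thin, explicitly tagged wrappers over standard procedures: exact
(Clopper-Pearson) binomial intervals, McNemar's test on paired
correct/incorrect indicators with the conventional small-sample exact
branch, Holm's step-down multiplicity adjustment, and a stratified
percentile bootstrap for arbitrary resamplable statistics.  Every result
carries its method tag so reports are self-describing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportion_confint

logger = logging.getLogger(__name__)

#: Below this many discordant pairs McNemar uses the exact binomial test.
MCNEMAR_EXACT_LIMIT = 25


@dataclass
class IntervalEstimate:
    point: float
    lower: float
    upper: float
    level: float
    method: str

    def __post_init__(self) -> None:
        if not (0 <= self.lower <= self.point + 1e-12 and
                self.point - 1e-12 <= self.upper <= 1 + 1e-12):
            raise ValueError(
                f"interval ({self.lower}, {self.point}, {self.upper}) is not ordered in [0, 1]"
            )


@dataclass
class PairedTestResult:
    statistic: float
    p_raw: float
    method: str
    discordant_b: int
    discordant_c: int
    p_adjusted: float | None = None


def clopper_pearson(successes: int, trials: int, level: float = 0.95) -> IntervalEstimate:
    """Exact binomial confidence interval for a proportion.

    Boundary convention: lower endpoint 0 when no successes, upper endpoint 1
    when no failures.
    """
    if trials <= 0:
        raise ValueError("trials must be > 0")
    if not 0 <= successes <= trials:
        raise ValueError(f"successes {successes} outside [0, {trials}]")
    lo, hi = proportion_confint(successes, trials, alpha=1 - level, method="beta")
    lo = 0.0 if successes == 0 else float(lo)
    hi = 1.0 if successes == trials else float(hi)
    return IntervalEstimate(
        point=successes / trials, lower=lo, upper=hi,
        level=level, method="clopper_pearson",
    )


def mcnemar(correct_a: Sequence[bool], correct_b: Sequence[bool]) -> PairedTestResult:
    """McNemar's test comparing the accuracy of two classifiers on the same subjects.

    Discordant counts: b = a correct & b wrong, c = a wrong & b correct.
    Uses the exact two-sided binomial test when b + c < 25, otherwise the
    chi-squared statistic with continuity correction.  With no discordant
    pairs p = 1 by convention.
    """
    a = np.asarray(correct_a, dtype=bool).ravel()
    bb = np.asarray(correct_b, dtype=bool).ravel()
    if a.size == 0 or a.size != bb.size:
        raise ValueError("need equal-length, non-empty paired vectors")
    b = int((a & ~bb).sum())
    c = int((~a & bb).sum())
    if b + c == 0:
        return PairedTestResult(statistic=0.0, p_raw=1.0, method="mcnemar_exact",
                                discordant_b=b, discordant_c=c)
    exact = (b + c) < MCNEMAR_EXACT_LIMIT
    table = [[int((a & bb).sum()), b], [c, int((~a & ~bb).sum())]]
    res = _sm_mcnemar(table, exact=exact, correction=True)
    return PairedTestResult(
        statistic=float(res.statistic),
        p_raw=min(1.0, float(res.pvalue)),
        method="mcnemar_exact" if exact else "mcnemar_cc",
        discordant_b=b,
        discordant_c=c,
    )


def holm_adjust(p_values: Sequence[float]) -> list[float]:
    """Holm's step-down (Bonferroni-Holm) adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(p, method="holm")[1])


def bootstrap_ci(
    statistic: Callable[..., float],
    groups: Sequence[np.ndarray],
    n_boot: int = 2000,
    level: float = 0.95,
    seed: int = 0,
) -> IntervalEstimate:
    """Stratified percentile bootstrap interval for ``statistic(*groups)``.

    Each replicate resamples within each group with replacement, preserving
    every per-group sample size.  Deterministic given ``seed``.  A constant
    statistic yields a zero-width interval (with a logged warning).
    """
    groups = [np.asarray(g).ravel() for g in groups]
    if any(g.size == 0 for g in groups):
        raise ValueError("every stratum must be non-empty")
    point = float(statistic(*groups))
    rng = np.random.default_rng(seed)
    reps = np.empty(n_boot)
    for i in range(n_boot):
        reps[i] = statistic(*(rng.choice(g, size=g.size, replace=True) for g in groups))
    alpha = 1 - level
    lo, hi = np.quantile(reps, [alpha / 2, 1 - alpha / 2])
    if lo == hi:
        logger.warning("degenerate bootstrap: statistic constant across replicates")
        lo = hi = point
    # percentile interval need not cover the point estimate exactly; clamp mildly
    lo, hi = min(float(lo), point), max(float(hi), point)
    return IntervalEstimate(point=point, lower=max(0.0, lo), upper=min(1.0, hi),
                            level=level, method="bootstrap_percentile")
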