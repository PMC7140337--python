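"""Per-threshold accuracy metrics and single cut-off selection strategies.

Four strategies are provided for choosing one cut-off on a screening score
(positive iff score <= t):

* ``fixed`` — a conventional, externally given cut-off (e.g. the
  instrument's original 25/26);
* ``balanced`` — the threshold where sensitivity and specificity are as
  equal as possible (argmin |sens - spec|);
* ``youden`` — the threshold maximizing Youden's J = sens + spec - 1;
* ``percentile`` — a reference-range cut-off derived from controls alone:
  the floor of the empirical q-quantile of control scores, so that roughly
  a fraction q of healthy subjects falls at or below the cut-off.

Ties in the balanced and Youden searches are broken toward the LOWER
threshold, i.e. toward higher specificity, reflecting the priority of
avoiding false-positive classifications in cognitive screening.

The correct classification rate (CCR) is the unweighted mean
(sens + spec)/2, equivalently (J + 1)/2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import roc
from .inference import IntervalEstimate, clopper_pearson


@dataclass
class ThresholdMetrics:
    """Confusion counts and derived accuracy measures at one threshold."""

    threshold: float
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    ccr: float
    youden_j: float
    ci_sens: IntervalEstimate | None = None
    ci_spec: IntervalEstimate | None = None


@dataclass
class CutoffChoice:
    """A selected cut-off, the strategy that produced it, and its metrics."""

    strategy: str
    threshold: float
    metrics: ThresholdMetrics | None = None
    strategy_params: dict = field(default_factory=dict)

    @property
    def label(self) -> str:
        return cutoff_label(self.threshold)


def cutoff_label(t: float) -> str:
    """Conventional cut-off label: "t/(t+1)" for integers, "<= t" otherwise."""
    if float(t).is_integer():
        t = int(t)
        return f"{t}/{t + 1}"
    return f"<= {t:g}"


def display_percent(p: float) -> int:
    """Proportion -> integer percent, rounding half away from zero (78.5% -> 79%).

    The percent value is snapped to 9 decimals first so binary representation
    noise (e.g. (0.94 + 0.63)/2 -> 78.499999...) cannot flip a true .5 case.
    """
    x = round(abs(p) * 100, 9)
    return int(math.floor(x + 0.5)) * (1 if p >= 0 else -1)


def evaluate_cutoff(
    pos_scores, neg_scores, t: float, ci_level: float | None = None
) -> ThresholdMetrics:
    """Confusion table and accuracy measures with positive iff score <= t.

    With ``ci_level`` set, sensitivity and specificity get exact
    Clopper-Pearson intervals.  Proportions are kept at full precision;
    rounding to display percent happens only in report formatting.
    """
    pos = np.asarray(pos_scores, dtype=float).ravel()
    neg = np.asarray(neg_scores, dtype=float).ravel()
    if pos.size == 0 or neg.size == 0:
        raise ValueError("single-class input: need both patients and controls")
    tp = int((pos <= t).sum())
    fn = pos.size - tp
    tn = int((neg > t).sum())
    fp = neg.size - tn
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    return ThresholdMetrics(
        threshold=float(t), tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=sens, specificity=spec,
        ccr=(sens + spec) / 2, youden_j=sens + spec - 1,
        ci_sens=clopper_pearson(tp, tp + fn, ci_level) if ci_level else None,
        ci_spec=clopper_pearson(tn, tn + fp, ci_level) if ci_level else None,
    )


def metrics_at_all_thresholds(
    pos_scores, neg_scores, thresholds=None, ci_level: float | None = None
) -> list[ThresholdMetrics]:
    """One ThresholdMetrics per grid threshold, ascending (32 entries for 0-30 scores)."""
    if thresholds is None:
        thresholds = roc.threshold_grid(pos_scores, neg_scores)
    return [
        evaluate_cutoff(pos_scores, neg_scores, t, ci_level=ci_level)
        for t in np.asarray(thresholds, dtype=float)
    ]


def metrics_table(metrics: list[ThresholdMetrics]) -> pd.DataFrame:
    rows = []
    for m in metrics:
        row = {
            "threshold": m.threshold, "tp": m.tp, "fp": m.fp, "tn": m.tn, "fn": m.fn,
            "sensitivity": m.sensitivity, "specificity": m.specificity,
            "ccr": m.ccr, "youden_j": m.youden_j,
        }
        if m.ci_sens is not None:
            row["sens_ci_low"], row["sens_ci_high"] = m.ci_sens.lower, m.ci_sens.upper
        if m.ci_spec is not None:
            row["spec_ci_low"], row["spec_ci_high"] = m.ci_spec.lower, m.ci_spec.upper
        rows.append(row)
    return pd.DataFrame(rows)


def fixed_cutoff(pos_scores, neg_scores, t: float, ci_level: float | None = None) -> CutoffChoice:
    """A conventional externally specified cut-off, evaluated on the sample."""
    return CutoffChoice(
        strategy="fixed", threshold=float(t),
        metrics=evaluate_cutoff(pos_scores, neg_scores, t, ci_level=ci_level),
    )


def balanced_cutoff(metrics: list[ThresholdMetrics]) -> CutoffChoice:
    """Threshold minimizing |sensitivity - specificity|; ties go to the lower threshold."""
    if not metrics:
        raise ValueError("empty metrics list")
    ordered = sorted(metrics, key=lambda m: m.threshold)
    best = min(ordered, key=lambda m: (abs(m.sensitivity - m.specificity), m.threshold))
    return CutoffChoice(strategy="balanced", threshold=best.threshold, metrics=best)


def youden_cutoff(metrics: list[ThresholdMetrics]) -> CutoffChoice:
    """Threshold maximizing Youden's J; ties go to the lower threshold (higher specificity)."""
    if not metrics:
        raise ValueError("empty metrics list")
    ordered = sorted(metrics, key=lambda m: m.threshold)
    best = min(ordered, key=lambda m: (-m.youden_j, m.threshold))
    return CutoffChoice(strategy="youden", threshold=best.threshold, metrics=best)


def percentile_cutoff(neg_scores, q: float = 0.10) -> CutoffChoice:
    """Reference-range cut-off from controls alone.

    Computes the empirical q-quantile of control scores (linear-interpolation
    convention) and returns ``floor(quantile)`` as the threshold, so scores
    at or below it lie in (approximately) the lower q tail of the healthy
    distribution and are read as pathological.  The target specificity is
    then approximately 1 - q.  Validation against patients happens
    separately via :func:`evaluate_cutoff`.
    """
    neg = np.asarray(neg_scores, dtype=float).ravel()
    if neg.size == 0:
        raise ValueError("empty controls")
    if not 0 <= q < 1:
        raise ValueError("q must be in [0, 1)")
    quantile = float(np.quantile(neg, q))  # linear interpolation (type 7)
    threshold = float(np.floor(quantile))
    return CutoffChoice(
        strategy="percentile", threshold=threshold,
        strategy_params={"q": q, "quantile": quantile},
    )


def ppv_npv(sensitivity: float, specificity: float, prevalence: float) -> tuple[float, float]:
    """Positive and negative predictive values at a given prevalence.

    PPV = sens*prev / (sens*prev + (1-spec)*(1-prev));
    NPV = spec*(1-prev) / (spec*(1-prev) + (1-sens)*prev).
    Degenerate 0/0 cases are fixed by convention for stable report output:
    PPV = 0 at prevalence 0 and NPV = 0 at prevalence 1.
    """
    for name, v in (("sensitivity", sensitivity), ("specificity", specificity),
                    ("prevalence", prevalence)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} = {v} outside [0, 1]")
    ppv_num = sensitivity * prevalence
    ppv_den = ppv_num + (1 - specificity) * (1 - prevalence)
    npv_num = specificity * (1 - prevalence)
    npv_den = npv_num + (1 - sensitivity) * prevalence
    ppv = ppv_num / ppv_den if ppv_den > 0 else 0.0
    npv = npv_num / npv_den if npv_den > 0 else 0.0
    return ppv, npv


def prevalence(n_patients: int, n_controls_in_clinic: int) -> float:
    """Fraction of the clinic sample that carries the diagnosis."""
    total = n_patients + n_controls_in_clinic
    if total <= 0:
        raise ValueError("total sample size must be > 0")
    return n_patients / total
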