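"""Empirical ROC curves, Mann-Whitney AUC, and paired bootstrap AUC comparison.

Orientation is fixed throughout: a LOWER score indicates impairment, and a
cut-off ``t`` classifies a subject positive (impaired) iff score <= t; the
conventional label for an integer cut-off is ``"t/(t+1)"``.  For 0-30
integer scores the threshold grid is the full integer range -1..30 (so both
degenerate classifiers are included); for continuous scores such as
normative z-scores the grid is the sorted unique observed values plus one
anchor below the minimum.

AUC uses the Mann-Whitney estimator: the probability that a random patient
scores below a random control, ties counted 1/2.  This equals trapezoidal
integration of the empirical ROC polygon.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import SCORE_MAX, SCORE_MIN

ORIENTATION = "lower score = positive (impaired)"


def _asarray(scores, name: str) -> np.ndarray:
    a = np.asarray(scores, dtype=float).ravel()
    if a.size == 0:
        raise ValueError(f"single-class input: {name} scores are empty")
    return a


def integer_grid() -> np.ndarray:
    """Thresholds -1..30 covering every classification of a bounded 0-30 score."""
    return np.arange(SCORE_MIN - 1, SCORE_MAX + 1)


def threshold_grid(pos_scores, neg_scores) -> np.ndarray:
    """Default grid: integer -1..30 when all scores are integral in [0, 30],
    otherwise the sorted unique observed values with an anchor below the minimum."""
    pooled = np.concatenate([_asarray(pos_scores, "positive"),
                             _asarray(neg_scores, "negative")])
    if np.all(pooled == np.round(pooled)) and pooled.min() >= SCORE_MIN and pooled.max() <= SCORE_MAX:
        return integer_grid()
    u = np.unique(pooled)
    return np.concatenate([[u[0] - 1.0], u])


@dataclass
class RocCurve:
    """Ordered (threshold, sensitivity, specificity) triples with AUC."""

    thresholds: np.ndarray
    sens: np.ndarray
    spec: np.ndarray
    auc: float
    orientation: str = ORIENTATION

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.thresholds, "sensitivity": self.sens,
             "specificity": self.spec}
        )


def roc_curve(pos_scores, neg_scores, thresholds: np.ndarray | None = None) -> RocCurve:
    """Empirical ROC: sens(t) = fraction of patients <= t; spec(t) = fraction of
    controls > t, at every grid threshold."""
    pos = _asarray(pos_scores, "positive")
    neg = _asarray(neg_scores, "negative")
    if thresholds is None:
        thresholds = threshold_grid(pos, neg)
    thresholds = np.asarray(thresholds, dtype=float)
    sens = np.array([(pos <= t).mean() for t in thresholds])
    spec = np.array([(neg > t).mean() for t in thresholds])
    return RocCurve(thresholds=thresholds, sens=sens, spec=spec, auc=auc(pos, neg))


def auc(pos_scores, neg_scores) -> float:
    """Mann-Whitney AUC: mean over all (patient, control) pairs of
    1[patient < control] + 0.5 * 1[tie]."""
    pos = _asarray(pos_scores, "positive")
    neg = _asarray(neg_scores, "negative")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    n_pos, n_neg = pos.size, neg.size
    # rank-sum of controls counts (control > patient) pairs, ties at half weight
    u_neg = ranks[n_pos:].sum() - n_neg * (n_neg + 1) / 2
    return float(u_neg / (n_pos * n_neg))


@dataclass
class AucComparison:
    """Paired bootstrap comparison of two correlated AUCs measured on the same subjects."""

    auc_a: float
    auc_b: float
    d_stat: float
    p_two_sided: float
    n_boot: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "auc_a": self.auc_a, "auc_b": self.auc_b, "d_stat": self.d_stat,
            "p_two_sided": self.p_two_sided, "n_boot": self.n_boot,
            "seed": self.seed, "method": "paired stratified bootstrap, normal approximation",
        }


def compare_auc_paired_bootstrap(
    score_a,
    score_b,
    labels,
    n_boot: int = 2000,
    seed: int = 0,
) -> AucComparison:
    """Two-sided bootstrap significance test for two correlated ROC curves.

    ``score_a`` and ``score_b`` are two markers measured on the same
    subjects; ``labels`` is a boolean vector (True = patient).  Subjects are
    resampled with replacement stratified by class — each replicate keeps the
    original number of patients and controls — and the AUC difference is
    standardized by its bootstrap SD:

        D = (AUC_a - AUC_b) / SD_boot(AUC_a - AUC_b),   p = 2 * (1 - Phi(|D|)).

    Deterministic given ``seed``.  A degenerate bootstrap SD of zero yields
    p = 1 when the observed difference is zero and raises otherwise.
    """
    a = np.asarray(score_a, dtype=float).ravel()
    b = np.asarray(score_b, dtype=float).ravel()
    y = np.asarray(labels, dtype=bool).ravel()
    if not (a.size == b.size == y.size):
        raise ValueError("score_a, score_b and labels must have equal length")
    pos_idx = np.flatnonzero(y)
    neg_idx = np.flatnonzero(~y)
    if pos_idx.size == 0 or neg_idx.size == 0:
        raise ValueError("single-class input: both classes must be present")

    auc_a = auc(a[pos_idx], a[neg_idx])
    auc_b = auc(b[pos_idx], b[neg_idx])
    rng = np.random.default_rng(seed)
    diffs = np.empty(n_boot)
    for i in range(n_boot):
        pi = rng.choice(pos_idx, size=pos_idx.size, replace=True)
        ni = rng.choice(neg_idx, size=neg_idx.size, replace=True)
        diffs[i] = auc(a[pi], a[ni]) - auc(b[pi], b[ni])
    sd = float(np.std(diffs, ddof=1))
    observed = auc_a - auc_b
    if sd == 0.0:
        if observed == 0.0:
            d_stat, p = 0.0, 1.0
        else:
            raise ValueError("degenerate bootstrap SD of 0 with nonzero AUC difference")
    else:
        d_stat = observed / sd
        p = float(2 * stats.norm.sf(abs(d_stat)))
    return AucComparison(
        auc_a=auc_a, auc_b=auc_b, d_stat=float(d_stat), p_two_sided=p,
        n_boot=n_boot, seed=seed,
    )
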