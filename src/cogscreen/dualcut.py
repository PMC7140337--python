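"""Two cut-offs with an indecisive area, built from cumulative frequency curves.

A single cut-off on a screening score forces a trade-off between
sensitivity and specificity.  The dual-cutoff procedure instead places:

* a LOWER cut-off for "not healthy" results — scores this low are rare
  among cognitively healthy controls, so score <= lower_t is read as
  probably pathological (the fraction of controls above it is the achieved
  specificity);
* an UPPER cut-off for "not pathological" results — scores above it are
  rare among patients, so score > upper_t is read as probably healthy
  (the fraction of patients at or below it is the achieved sensitivity).

Scores strictly between the two cut-offs form an indecisive area where the
screen defers to further examination.  Both cut-offs are read off the
empirical cumulative frequency curves: sensitivity at score s is the
cumulative fraction of patients scoring <= s, specificity the complementary
fraction of controls scoring > s.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Group, SCORE_MAX, SCORE_MIN, StudyDataset


class Zone(str, enum.Enum):
    NOT_HEALTHY = "not_healthy"
    INDECISIVE = "indecisive"
    NOT_PATHOLOGICAL = "not_pathological"


@dataclass
class CumulativeCurves:
    """Per-score cumulative sensitivity (patients) and specificity (controls)."""

    scores: np.ndarray
    sens_by_score: np.ndarray
    spec_by_score: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"score": self.scores, "sensitivity": self.sens_by_score,
             "specificity": self.spec_by_score}
        )


@dataclass
class DualCutoffResult:
    lower_t: int
    upper_t: int
    target_sens: float
    target_spec: float
    achieved_sens: float
    achieved_spec: float
    indecisive_scores: list[int] = field(default_factory=list)
    mode: str = "strict"

    def to_dict(self) -> dict:
        return {
            "lower_cutoff": self.lower_t,
            "lower_label": f"{self.lower_t}/{self.lower_t + 1}",
            "upper_cutoff": self.upper_t,
            "upper_label": f"{self.upper_t}/{self.upper_t + 1}",
            "target_sensitivity": self.target_sens,
            "target_specificity": self.target_spec,
            "achieved_sensitivity": self.achieved_sens,
            "achieved_specificity": self.achieved_spec,
            "indecisive_scores": self.indecisive_scores,
            "selection_mode": self.mode,
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)


def cumulative_curves(
    patient_scores, control_scores, scores: np.ndarray | None = None
) -> CumulativeCurves:
    """Exact empirical cumulative fractions at every integer score 0..30.

    ``sens_by_score[s]`` is the proportion of patients scoring <= s;
    ``spec_by_score[s]`` the proportion of controls scoring > s.
    """
    pat = np.asarray(patient_scores, dtype=float).ravel()
    con = np.asarray(control_scores, dtype=float).ravel()
    if pat.size == 0 or con.size == 0:
        raise ValueError("both the patient and control group must be non-empty")
    if scores is None:
        scores = np.arange(SCORE_MIN, SCORE_MAX + 1)
    scores = np.asarray(scores)
    sens = np.array([(pat <= s).mean() for s in scores])
    spec = np.array([(con > s).mean() for s in scores])
    return CumulativeCurves(scores=scores, sens_by_score=sens, spec_by_score=spec)


def find_dual_cutoffs(
    curves: CumulativeCurves,
    target_sens: float = 0.90,
    target_spec: float = 0.90,
    mode: str = "strict",
) -> DualCutoffResult:
    """Place the two cut-offs for the requested sensitivity/specificity targets.

    ``strict`` mode (default) guarantees the targets on the defining samples:
    lower_t is the largest score with specificity >= target_spec, upper_t the
    smallest score with sensitivity >= target_sens.  ``nearest`` mode instead
    picks the score whose achieved value is closest to the target (ties go to
    the higher-specificity / higher-sensitivity side), matching the looser
    reading of an "approximately 90%" aim.  When the groups barely overlap,
    lower_t may exceed upper_t; the indecisive set is then empty and every
    score is decided.
    """
    if not (0 < target_sens < 1 and 0 < target_spec < 1):
        raise ValueError("targets must lie in (0, 1)")
    if mode not in ("strict", "nearest"):
        raise ValueError(f"unknown mode {mode!r}")
    scores = np.asarray(curves.scores)
    sens, spec = curves.sens_by_score, curves.spec_by_score

    if mode == "strict":
        ok_spec = np.flatnonzero(spec >= target_spec)
        if ok_spec.size == 0:
            raise ValueError(
                f"specificity target {target_spec} unattainable: "
                f"max achievable on the control curve is {spec.max():.3f}"
            )
        i_lower = ok_spec[-1]
        ok_sens = np.flatnonzero(sens >= target_sens)
        if ok_sens.size == 0:
            raise ValueError(
                f"sensitivity target {target_sens} unattainable: "
                f"max achievable on the patient curve is {sens.max():.3f}"
            )
        i_upper = ok_sens[0]
    else:
        # spec is nonincreasing in score: first argmin of |spec - target| is
        # the smallest score, i.e. the higher-specificity side of a tie
        i_lower = int(np.argmin(np.abs(spec - target_spec)))
        # sens is nondecreasing: reversed scan puts ties on the higher-sens side
        rev = np.abs(sens - target_sens)[::-1]
        i_upper = len(sens) - 1 - int(np.argmin(rev))

    lower_t = int(scores[i_lower])
    upper_t = int(scores[i_upper])
    indecisive = list(range(lower_t + 1, upper_t + 1)) if lower_t < upper_t else []
    return DualCutoffResult(
        lower_t=lower_t, upper_t=upper_t,
        target_sens=target_sens, target_spec=target_spec,
        achieved_sens=float(sens[i_upper]), achieved_spec=float(spec[i_lower]),
        indecisive_scores=indecisive, mode=mode,
    )


def classify_score(score: int, result: DualCutoffResult) -> Zone:
    """Three-zone triage of one score.

    Scores above the upper cut-off are read as not pathological, scores at
    or below the lower cut-off as not healthy, anything in between is
    indecisive.  When the cut-offs cross (non-overlapping groups) a score
    may satisfy both decided rules; "not pathological" takes precedence.
    """
    if not SCORE_MIN <= score <= SCORE_MAX:
        raise ValueError(f"score {score} outside [{SCORE_MIN}, {SCORE_MAX}]")
    if score > result.upper_t:
        return Zone.NOT_PATHOLOGICAL
    if score <= result.lower_t:
        return Zone.NOT_HEALTHY
    return Zone.INDECISIVE


def zone_summary(
    ds: StudyDataset, result: DualCutoffResult, score_field: str = "moca_adj"
) -> pd.DataFrame:
    """Counts of subjects per (diagnostic group, zone); rows sum to group sizes."""
    zones = [z.value for z in Zone]
    counts = {g.value: dict.fromkeys(zones, 0) for g in Group}
    for r in ds.records:
        val = getattr(r, score_field)
        if val is None:
            raise ValueError(f"subject {r.id}: {score_field} is missing")
        counts[r.group.value][classify_score(int(val), result).value] += 1
    return pd.DataFrame.from_dict(counts, orient="index", columns=zones)


FOLLOW_UP_ADVICE = (
    "indecisive score: begin a comprehensive neuropsychological assessment "
    "or re-screen in approximately 6 to 12 months"
)


def triage_report(score: int, result: DualCutoffResult) -> str:
    """Fixed-rule triage text for one score given configured dual cut-offs."""
    zone = classify_score(score, result)
    lines = [
        f"score: {score}",
        f"lower cut-off (not healthy): {result.lower_t}/{result.lower_t + 1} "
        f"(specificity {result.achieved_spec:.0%})",
        f"upper cut-off (not pathological): {result.upper_t}/{result.upper_t + 1} "
        f"(sensitivity {result.achieved_sens:.0%})",
        f"zone: {zone.value}",
    ]
    if zone is Zone.INDECISIVE:
        lines.append(FOLLOW_UP_ADVICE)
    return "\n".join(lines)
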