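"""Score adjustments: education correction and demographically corrected z-scores.

Two adjustment pathways exist for the MoCA total:

* the instrument's own education rule — one bonus point when formal education
  is below 12 years, capped at the instrument maximum of 30;
* a normative regression z-score, ``(raw - predicted) / residual_sd`` with
  ``predicted = intercept + beta_age*age + beta_edu*education + beta_sex*[sex = M]``.

The published normative coefficients behind the study's z-scores are external
to this package, so :class:`NormModel` is configuration: supply the real
coefficients if you have them.  A clearly labeled synthetic placeholder model
ships as default, calibrated analytically so that simulated normal-control
cohorts produce z-scores with mean close to 0 and SD close to 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

from .cohort import SCORE_MAX, SCORE_MIN, Sex, StudyDataset

logger = logging.getLogger(__name__)

#: Education threshold (years) below which one bonus point is added.
EDUCATION_THRESHOLD = 12


def education_adjust(raw: int, education: int) -> int:
    """Education-corrected MoCA total: raw + 1 if education < 12 years, capped at 30."""
    if not SCORE_MIN <= raw <= SCORE_MAX:
        raise ValueError(f"raw score {raw} outside [{SCORE_MIN}, {SCORE_MAX}]")
    if education < 0:
        raise ValueError(f"education {education} must be >= 0")
    if education < EDUCATION_THRESHOLD:
        return min(raw + 1, SCORE_MAX)
    return raw


@dataclass(frozen=True)
class NormModel:
    """Normative regression for the demographically corrected z-score.

    Sex coding: ``beta_sex`` is added to the prediction when sex is M (male
    indicator).  Units: score points, points per year of age, points per year
    of education.
    """

    intercept: float
    beta_age: float
    beta_edu: float
    beta_sex: float
    residual_sd: float

    def __post_init__(self) -> None:
        if self.residual_sd <= 0:
            raise ValueError("residual_sd must be > 0")

    def predict(self, age: float, sex: Sex, education: int) -> float:
        male = 1.0 if Sex(sex) == Sex.M else 0.0
        return (
            self.intercept
            + self.beta_age * age
            + self.beta_edu * education
            + self.beta_sex * male
        )


# Synthetic placeholder normative model (NOT the published norms).  Slopes are
# plausible for an elderly outpatient population; the intercept and residual SD
# are solved so that a control group with MoCA 26.5 (2.4), age ~73.8 (5.2),
# education ~13.6 (2.9) and 54.8% women yields z ~ Normal(0, 1):
#   intercept = 26.5 + 0.05*73.8 - 0.15*13.6 + 0.2*0.452 = 28.2404
#   residual_sd = sqrt(2.4^2 + 0.05^2*5.2^2 + 0.15^2*2.9^2 + 0.2^2*0.248) = 2.455
PLACEHOLDER_NORM_MODEL = NormModel(
    intercept=28.2404,
    beta_age=-0.05,
    beta_edu=0.15,
    beta_sex=-0.2,
    residual_sd=2.455,
)


def z_score(
    raw: int, age: float, sex: Sex, education: int, model: NormModel
) -> float:
    """Demographically corrected z-score of a raw test total under ``model``.

    Affine in ``raw`` with slope ``1/residual_sd``, so higher raw scores map
    to strictly higher z for fixed demographics.
    """
    return (raw - model.predict(age, sex, education)) / model.residual_sd


def apply_adjustments(
    ds: StudyDataset,
    model: NormModel | None = None,
    edu_adjust: bool = True,
) -> StudyDataset:
    """Return a dataset with ``moca_adj`` filled in (and ``moca_z`` where needed).

    The education adjustment is applied exactly once: ``moca_adj`` is always
    recomputed from ``moca_raw`` here, never read from input files.  With
    ``edu_adjust=False`` the adjusted score equals the raw score.  When a
    :class:`NormModel` is supplied and a record already carries a z value,
    the file value wins and a warning is logged (the study computed its
    z-scores externally).
    """
    records = []
    n_kept = 0
    for r in ds.records:
        adj = education_adjust(r.moca_raw, r.education) if edu_adjust else r.moca_raw
        z = r.moca_z
        if model is not None:
            if z is not None:
                n_kept += 1
            else:
                z = z_score(r.moca_raw, r.age, r.sex, r.education, model)
        records.append(replace(r, moca_adj=adj, moca_z=z))
    if n_kept:
        logger.warning(
            "%d record(s) already carried moca_z; file values kept, NormModel ignored",
            n_kept,
        )
    return StudyDataset(records=records, provenance=ds.provenance)
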