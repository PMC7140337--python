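"""Synthetic memory-clinic cohort generator.

Emulates the statistical structure of the study population: four diagnostic
groups (normal controls NC, clinic normal findings NF, mild and major
neurocognitive disorder), each with discrete 0-30 MoCA and MMSE totals drawn
as rounded, clipped Gaussians, truncated-normal integer demographics, a
Bernoulli sex indicator, and a Gaussian demographically corrected z-score.

Published summary statistics cover NC, NF, the Mild subgroup, and the pooled
Mild+Major patient sample — not the Major group on its own.  The Major-group
generative parameters are therefore solved at runtime from mixture-moment
identities (:func:`complement_moments`) so that the 159:288 Mild:Major
mixture reproduces the pooled mean and SD exactly at the population level.

Scores are drawn independently within subject; real MoCA/MMSE totals are
positively correlated and patient score distributions are left-skewed, so
this generator is a second-moment emulation, not a copy of the field data.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy import stats

from .adjust import NormModel, education_adjust, z_score
from .cohort import Group, Sex, StudyDataset, SubjectRecord, SCORE_MAX, SCORE_MIN


def round_half_away(x: np.ndarray | float) -> np.ndarray:
    """Round half away from zero (2.5 -> 3, -2.5 -> -3), unlike banker's rounding."""
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def draw_discrete_scores(
    rng: np.random.Generator,
    n: int,
    mean: float,
    sd: float,
    lo: int = SCORE_MIN,
    hi: int = SCORE_MAX,
) -> np.ndarray:
    """Draw ``round(Normal(mean, sd))`` clipped to [lo, hi], as an int array."""
    raw = rng.normal(mean, sd, size=n)
    return np.clip(round_half_away(raw), lo, hi).astype(int)


def discrete_score_moments(
    mean: float, sd: float, lo: int = SCORE_MIN, hi: int = SCORE_MAX
) -> tuple[float, float]:
    """Exact mean and SD of ``clip(round(Normal(mean, sd)), lo, hi)``.

    Rounding spreads each integer's mass over a half-open unit cell; clipping
    censors both tails onto the boundary scores.  Near the instrument ceiling
    this censoring pulls the mean slightly below the nominal Gaussian target
    and shrinks the SD — e.g. a Normal(29.2, 0.9) MMSE loses about 0.07
    points of mean at the 30-point cap.  These are the moments the generator
    actually realizes, and the reference for parameter-recovery checks.
    """
    if sd == 0:
        v = min(max(int(round_half_away(mean)), lo), hi)
        return float(v), 0.0
    k = np.arange(lo, hi + 1)
    upper = stats.norm.cdf((k + 0.5 - mean) / sd)
    lower = stats.norm.cdf((k - 0.5 - mean) / sd)
    p = upper - lower
    p[0] = upper[0]          # everything below lo+0.5 lands on lo
    p[-1] = 1.0 - lower[-1]  # everything above hi-0.5 lands on hi
    mu = float((k * p).sum())
    var = float(((k - mu) ** 2 * p).sum())
    return mu, float(np.sqrt(var))


def _draw_truncated_int(
    rng: np.random.Generator, n: int, mean: float, sd: float, lo: float, hi: float
) -> np.ndarray:
    """Truncated normal on [lo, hi], rounded to integer (stays inside the range)."""
    if sd <= 0:
        return np.full(n, int(round(mean)))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    vals = stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)
    return np.clip(round_half_away(vals), lo, hi).astype(int)


def complement_moments(
    n_total: int,
    mean_total: float,
    sd_total: float,
    n_sub: int,
    mean_sub: float,
    sd_sub: float,
) -> tuple[float, float]:
    """Mean and SD of the complement of a subgroup within a pooled sample.

    Given pooled moments of a mixture of ``n_total`` subjects and the moments
    of a subgroup of ``n_sub`` of them, return (mean, sd) of the remaining
    ``n_total - n_sub`` so that the weighted mixture reproduces the pooled
    mean and variance (second-moment decomposition).
    """
    n_rest = n_total - n_sub
    if n_rest <= 0:
        raise ValueError("subgroup size must be smaller than the pooled size")
    mean_rest = (n_total * mean_total - n_sub * mean_sub) / n_rest
    m2_total = sd_total**2 + mean_total**2
    m2_sub = sd_sub**2 + mean_sub**2
    m2_rest = (n_total * m2_total - n_sub * m2_sub) / n_rest
    var_rest = m2_rest - mean_rest**2
    if var_rest < 0:
        raise ValueError(
            "pooled and subgroup moments are inconsistent (negative complement variance)"
        )
    return mean_rest, float(np.sqrt(var_rest))


@dataclass
class GroupSpec:
    """Generative parameters for one diagnostic group."""

    label: Group
    n: int
    moca_mean: float
    moca_sd: float
    mmse_mean: float
    mmse_sd: float
    z_mean: float
    z_sd: float
    age_mean: float
    age_sd: float
    age_range: tuple[float, float]
    edu_mean: float
    edu_sd: float
    edu_range: tuple[float, float]
    female_fraction: float

    def validate(self) -> None:
        if self.n < 0:
            raise ValueError(f"{self.label}: n must be >= 0")
        for name in ("moca_sd", "mmse_sd", "z_sd", "age_sd", "edu_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{self.label}: {name} must be >= 0")
        for name in ("age_range", "edu_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{self.label}: {name} is not ordered")
        if not 0 <= self.female_fraction <= 1:
            raise ValueError(f"{self.label}: female_fraction must be in [0, 1]")


@dataclass
class CohortSpec:
    """Full study specification: one GroupSpec per diagnostic group plus a seed."""

    groups: list[GroupSpec]
    seed: int = 0

    def validate(self) -> None:
        labels = [g.label for g in self.groups]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate group labels in CohortSpec")
        for g in self.groups:
            g.validate()

    def digest(self) -> str:
        payload = json.dumps(
            [asdict(g) | {"label": g.label.value} for g in self.groups],
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "groups": [
                asdict(g) | {"label": g.label.value, "age_range": list(g.age_range),
                             "edu_range": list(g.edu_range)}
                for g in self.groups
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        groups = []
        for g in d["groups"]:
            g = dict(g)
            g["label"] = Group(g["label"])
            g["age_range"] = tuple(g["age_range"])
            g["edu_range"] = tuple(g["edu_range"])
            groups.append(GroupSpec(**g))
        return cls(groups=groups, seed=int(d.get("seed", 0)))


# Published per-group summary statistics: n, MoCA mean (SD), MMSE mean (SD),
# z mean (SD), age mean (SD) and range, education mean (SD) and range,
# female fraction.  The patient pool totals 447 of which 159 are Mild, so
# the Major group has 288 members and its parameters are moment-matched.
_NC = dict(n=283, moca=(26.5, 2.4), mmse=(29.2, 0.9), z=(0.0, 1.0),
           age=(73.8, 5.2, (65, 91)), edu=(13.6, 2.9, (7, 20)), female=0.548)
_NF = dict(n=49, moca=(26.5, 2.2), mmse=(29.0, 1.0), z=(0.1, 1.0),
           age=(73.1, 5.6, (65, 88)), edu=(13.8, 2.7, (8, 20)), female=0.408)
_MILD = dict(n=159, moca=(22.0, 3.6), mmse=(27.2, 2.2), z=(-1.5, 1.0),
             age=(76.0, 6.0, (65, 91)), edu=(12.4, 3.1, (7, 20)), female=0.535)
_POOLED = dict(n=447, moca=(19.1, 4.5), mmse=(25.1, 3.5), z=(-2.1, 1.0),
               age=(78.3, 5.9, (65, 91)), edu=(12.2, 3.0, (7, 20)), female=0.557)


def _groupspec(label: Group, d: dict) -> GroupSpec:
    return GroupSpec(
        label=label, n=d["n"],
        moca_mean=d["moca"][0], moca_sd=d["moca"][1],
        mmse_mean=d["mmse"][0], mmse_sd=d["mmse"][1],
        z_mean=d["z"][0], z_sd=d["z"][1],
        age_mean=d["age"][0], age_sd=d["age"][1], age_range=d["age"][2],
        edu_mean=d["edu"][0], edu_sd=d["edu"][1], edu_range=d["edu"][2],
        female_fraction=d["female"],
    )


def major_group_spec() -> GroupSpec:
    """Moment-matched Major-NCD group so Mild+Major pools to the published moments."""
    nt, ns = _POOLED["n"], _MILD["n"]
    out = {"n": nt - ns}
    for key in ("moca", "mmse", "z"):
        m, s = complement_moments(
            nt, *_POOLED[key][:2], ns, *_MILD[key][:2]
        )
        out[key] = (m, s)
    for key in ("age", "edu"):
        m, s = complement_moments(
            nt, _POOLED[key][0], _POOLED[key][1], ns, _MILD[key][0], _MILD[key][1]
        )
        out[key] = (m, s, _POOLED[key][2])
    out["female"] = (nt * _POOLED["female"] - ns * _MILD["female"]) / (nt - ns)
    return _groupspec(Group.MAJOR, out)


def default_cohort_spec(seed: int = 0) -> CohortSpec:
    """The study's default generative specification (283 NC, 49 NF, 159 Mild, 288 Major)."""
    return CohortSpec(
        groups=[
            _groupspec(Group.NC, _NC),
            _groupspec(Group.NF, _NF),
            _groupspec(Group.MILD, _MILD),
            major_group_spec(),
        ],
        seed=seed,
    )


def simulate_group(
    g: GroupSpec,
    rng: np.random.Generator,
    norm_model: NormModel | None = None,
) -> list[SubjectRecord]:
    """Simulate one diagnostic group.

    Scores are ``round(Normal(mean, sd))`` clipped to [0, 30]; age and
    education are truncated normals within the group range, rounded to whole
    years; sex is Bernoulli(female_fraction).  The z-score is drawn directly
    from ``Normal(z_mean, z_sd)`` unless a :class:`NormModel` is supplied,
    in which case it is computed from the simulated raw score and
    demographics.
    """
    g.validate()
    n = g.n
    moca = draw_discrete_scores(rng, n, g.moca_mean, g.moca_sd)
    mmse = draw_discrete_scores(rng, n, g.mmse_mean, g.mmse_sd)
    age = _draw_truncated_int(rng, n, g.age_mean, g.age_sd, *g.age_range)
    edu = _draw_truncated_int(rng, n, g.edu_mean, g.edu_sd, *g.edu_range)
    female = rng.random(n) < g.female_fraction
    if norm_model is None:
        z = rng.normal(g.z_mean, g.z_sd, size=n)
    records = []
    for i in range(n):
        sex = Sex.F if female[i] else Sex.M
        if norm_model is not None:
            zi = z_score(int(moca[i]), float(age[i]), sex, int(edu[i]), norm_model)
        else:
            zi = float(z[i])
        records.append(
            SubjectRecord(
                id=f"{g.label.value}-{i:05d}",
                group=g.label,
                age=float(age[i]),
                education=int(edu[i]),
                sex=sex,
                moca_raw=int(moca[i]),
                mmse=int(mmse[i]),
                moca_z=zi,
            )
        )
    return records


def simulate_study(
    spec: CohortSpec | None = None,
    norm_model: NormModel | None = None,
) -> StudyDataset:
    """Simulate the full four-group study; deterministic given ``spec.seed``.

    Each group draws from its own substream derived from the global seed, so
    any subset of groups is reproducible independently of the others.
    """
    if spec is None:
        spec = default_cohort_spec()
    spec.validate()
    records: list[SubjectRecord] = []
    for gi, g in enumerate(sorted(spec.groups, key=lambda g: g.label.value)):
        rng = np.random.default_rng([spec.seed, gi])
        records.extend(simulate_group(g, rng, norm_model=norm_model))
    return StudyDataset(
        records=records,
        provenance=f"simulated seed={spec.seed} spec={spec.digest()}",
    )
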