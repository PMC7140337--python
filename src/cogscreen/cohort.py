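"""Subject-level cohort data model, validation, and tabular I/O.

A cohort is a flat table of memory-clinic participants: a diagnostic group
(normal controls ``NC``, clinic patients with normal findings ``NF``, mild
neurocognitive disorder ``MILD``, major neurocognitive disorder ``MAJOR``),
demographics, and two discrete 0-30 cognitive screening scores (MoCA and
MMSE) plus an optional demographically corrected MoCA z-score.

The education-adjusted MoCA score (``moca_adj``) is always derived by the
pipeline (see :mod:`cogscreen.adjust`) and is never read from disk, so the
"+1 point for low education" rule has a single source of truth.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

SCORE_MIN = 0
SCORE_MAX = 30

#: Canonical CSV column order.  ``moca_adj`` is deliberately absent.
COLUMNS = ["id", "group", "age", "education", "sex", "moca_raw", "mmse", "moca_z"]


class Group(str, enum.Enum):
    """Diagnostic group label."""

    NC = "NC"
    NF = "NF"
    MILD = "MILD"
    MAJOR = "MAJOR"


#: The patient pool: everyone with a neurocognitive disorder.
PATIENT_GROUPS = frozenset({Group.MILD, Group.MAJOR})


class Sex(str, enum.Enum):
    F = "F"
    M = "M"


class SchemaError(ValueError):
    """The input table is missing a required column or is otherwise malformed."""


class RowError(ValueError):
    """A single row failed validation; carries the 1-based data row number."""

    def __init__(self, row: int, message: str):
        self.row = row
        super().__init__(f"row {row}: {message}")


@dataclass
class SubjectRecord:
    """One participant.

    ``moca_adj`` is the education-adjusted MoCA total (raw + 1 when
    education < 12 years, capped at 30); it is ``None`` until the
    adjustment step has run.
    """

    id: str
    group: Group
    age: float
    education: int
    sex: Sex
    moca_raw: int
    mmse: int
    moca_z: float | None = None
    moca_adj: int | None = None


@dataclass
class InclusionRules:
    """Demographic inclusion frame of the memory-clinic study design."""

    min_age: float = 65
    min_education: int = 7


#: Default study inclusion frame (age >= 65 years, education >= 7 years).
MEMORY_CLINIC_INCLUSION = InclusionRules()


def validate_record(
    r: SubjectRecord, inclusion: InclusionRules | None = None
) -> list[str]:
    """Return a list of human-readable violations (empty when valid).

    Validation is total: it never raises for in-range field types.  Range
    invariants on the scores are always checked; the demographic inclusion
    rules are checked only when ``inclusion`` is supplied, because the tool
    must also accept cohorts outside the original study's demographic frame.
    """
    v: list[str] = []
    for name in ("moca_raw", "mmse"):
        s = getattr(r, name)
        if not (SCORE_MIN <= s <= SCORE_MAX):
            v.append(f"{name} = {s} outside [{SCORE_MIN}, {SCORE_MAX}]")
    if r.moca_adj is not None:
        if not (SCORE_MIN <= r.moca_adj <= SCORE_MAX):
            v.append(f"moca_adj = {r.moca_adj} outside [{SCORE_MIN}, {SCORE_MAX}]")
        elif r.moca_adj - r.moca_raw not in (0, 1):
            v.append(
                f"moca_adj - moca_raw = {r.moca_adj - r.moca_raw}, must be 0 or 1"
            )
    if r.moca_z is not None and not math.isfinite(r.moca_z):
        v.append(f"moca_z = {r.moca_z} is not finite")
    if inclusion is not None:
        if r.age < inclusion.min_age:
            v.append(f"age {r.age} violates inclusion rule age >= {inclusion.min_age}")
        if r.education < inclusion.min_education:
            v.append(
                f"education {r.education} violates inclusion rule "
                f"education >= {inclusion.min_education}"
            )
    return v


@dataclass
class StudyDataset:
    """An ordered collection of validated subject records with provenance."""

    records: list[SubjectRecord] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate subject ids: {dup[:5]}")

    def __len__(self) -> int:
        return len(self.records)

    def group_records(self, groups: Iterable[Group]) -> list[SubjectRecord]:
        wanted = {Group(g) for g in groups}
        return [r for r in self.records if r.group in wanted]

    def scores(self, groups: Iterable[Group], field_name: str) -> np.ndarray:
        """Score vector (float array) for the given groups; errors on missing values."""
        out = []
        for r in self.group_records(groups):
            val = getattr(r, field_name)
            if val is None:
                raise ValueError(
                    f"subject {r.id}: {field_name} is missing; "
                    "run the adjustment step or supply the column"
                )
            out.append(val)
        return np.asarray(out, dtype=float)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "id": r.id,
                "group": r.group.value,
                "age": r.age,
                "education": r.education,
                "sex": r.sex.value,
                "moca_raw": r.moca_raw,
                "mmse": r.mmse,
                "moca_z": r.moca_z,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=COLUMNS)


def _parse_row(i: int, row: dict) -> SubjectRecord:
    def intfield(name: str) -> int:
        raw = row[name]
        try:
            val = float(raw)
        except (TypeError, ValueError):
            raise RowError(i, f"cannot parse {name} = {raw!r} as a number")
        if not val.is_integer():
            raise RowError(i, f"{name} = {raw!r} is not an integer")
        return int(val)

    try:
        group = Group(str(row["group"]).strip().upper())
    except ValueError:
        raise RowError(
            i, f"unknown group {row['group']!r}; expected one of NC, NF, MILD, MAJOR"
        )
    try:
        sex = Sex(str(row["sex"]).strip().upper())
    except ValueError:
        raise RowError(i, f"unknown sex {row['sex']!r}; expected F or M")
    try:
        age = float(row["age"])
    except (TypeError, ValueError):
        raise RowError(i, f"cannot parse age = {row['age']!r}")

    z_raw = row.get("moca_z")
    if z_raw is None or (isinstance(z_raw, float) and math.isnan(z_raw)) or str(z_raw).strip() == "":
        moca_z = None
    else:
        try:
            moca_z = float(z_raw)
        except (TypeError, ValueError):
            raise RowError(i, f"cannot parse moca_z = {z_raw!r}")

    rec = SubjectRecord(
        id=str(row["id"]),
        group=group,
        age=age,
        education=intfield("education"),
        sex=sex,
        moca_raw=intfield("moca_raw"),
        mmse=intfield("mmse"),
        moca_z=moca_z,
    )
    violations = [v for v in validate_record(rec) if "inclusion" not in v]
    if violations:
        raise RowError(i, "; ".join(violations))
    return rec


def read_cohort(path: str | Path, delimiter: str = ",") -> StudyDataset:
    """Read a cohort table.

    The header is mandatory; required columns are ``id, group, age,
    education, sex, moca_raw, mmse`` (``moca_z`` may be absent or empty;
    an on-disk ``moca_adj`` column is ignored and always recomputed).
    Group and sex labels are case-insensitive.  A malformed value raises
    :class:`RowError` with the 1-based data row number; a missing column
    raises :class:`SchemaError` naming it.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    required = [c for c in COLUMNS if c != "moca_z"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
    if "moca_z" not in df.columns:
        df["moca_z"] = ""
    records = [
        _parse_row(i + 1, row) for i, row in enumerate(df.to_dict(orient="records"))
    ]
    return StudyDataset(records=records, provenance=f"file:{path}")


def write_cohort(ds: StudyDataset, path: str | Path, delimiter: str = ",") -> None:
    """Write the cohort as UTF-8 delimited text with the canonical column order.

    Output is deterministic for identical input; an empty dataset yields a
    header-only file.  ``moca_adj`` is intentionally not written.
    """
    df = ds.to_frame()
    df.to_csv(path, sep=delimiter, index=False, encoding="utf-8")


def with_record(r: SubjectRecord, **changes) -> SubjectRecord:
    """Non-mutating field update (thin wrapper over dataclasses.replace)."""
    return replace(r, **changes)


def validate_dataset(
    ds: StudyDataset,
    inclusion: InclusionRules | None = None,
    strict: bool = False,
) -> dict[str, list[str]]:
    """Validate every record; map of subject id -> violations (non-empty only).

    With ``strict=True`` any violation raises ``ValueError`` summarizing the
    first few offenders; otherwise violations are returned for the caller to
    warn about.
    """
    bad: dict[str, list[str]] = {}
    for r in ds.records:
        v = validate_record(r, inclusion)
        if v:
            bad[r.id] = v
    if strict and bad:
        head = "; ".join(
            f"{sid}: {msgs[0]}" for sid, msgs in list(bad.items())[:3]
        )
        raise ValueError(f"{len(bad)} record(s) failed validation ({head} ...)")
    return bad
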