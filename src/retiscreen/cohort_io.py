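"""Longitudinal cohort containers, CSV round-trip and study selection filters.

A cohort is a list of :class:`PatientHistory`, one per patient, each holding the
time-ordered visit records (integer months since the patient entered care).
Retinopathy severity uses the EURODIAB scale, grades 0-5; grades 3-5 are
sight-threatening retinopathy (STR), the referral threshold.

The on-disk format is a long CSV, one row per visit, with missing values as
empty fields::

    patient_id,sex,t_months,grade,hba1c_mmol_mol,sbp_mmhg,duration_years,follow_up_months
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional

import numpy as np
import pandas as pd

STR_GRADE = 3
GRADES = (0, 1, 2, 3, 4, 5)
CSV_COLUMNS = [
    "patient_id",
    "sex",
    "t_months",
    "grade",
    "hba1c_mmol_mol",
    "sbp_mmhg",
    "duration_years",
    "follow_up_months",
]


class CohortValidationError(ValueError):
    """Raised when a cohort file or in-memory cohort violates the format contract.

    Carries the full list of offences so a malformed file is reported once,
    with line numbers, rather than failing on the first bad row.
    """

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__("cohort validation failed:\n  " + "\n  ".join(self.problems))


@dataclass(frozen=True)
class VisitRecord:
    """One patient-visit row. ``None`` marks a missing measurement."""

    patient_id: str
    t_months: int
    grade: Optional[int]
    hba1c: Optional[float]
    sbp: Optional[float]
    duration_years: Optional[float]


@dataclass
class PatientHistory:
    """One patient's ordered visit records.

    Visit-level arrays are aligned and sorted strictly by ``t_months``; missing
    values are ``nan``.  ``follow_up_months`` is the administrative exit time
    and is always >= the last visit time.
    """

    patient_id: str
    sex: str  # "male" | "female"
    follow_up_months: int
    t_months: np.ndarray
    grade: np.ndarray
    hba1c: np.ndarray
    sbp: np.ndarray
    duration_years: np.ndarray
    age_years: Optional[float] = None  # baseline age; informational only

    def __post_init__(self):
        self.t_months = np.asarray(self.t_months, dtype=int)
        for name in ("grade", "hba1c", "sbp", "duration_years"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))

    @property
    def n_visits(self) -> int:
        return len(self.t_months)

    @property
    def visits(self) -> Iterator[VisitRecord]:
        for i in range(self.n_visits):
            yield VisitRecord(
                self.patient_id,
                int(self.t_months[i]),
                None if math.isnan(self.grade[i]) else int(self.grade[i]),
                None if math.isnan(self.hba1c[i]) else float(self.hba1c[i]),
                None if math.isnan(self.sbp[i]) else float(self.sbp[i]),
                None
                if math.isnan(self.duration_years[i])
                else float(self.duration_years[i]),
            )

    def baseline_grade(self) -> float:
        """Grade at the earliest visit with a non-missing grade (nan if none)."""
        obs = ~np.isnan(self.grade)
        return float(self.grade[obs][0]) if obs.any() else float("nan")

    def has_any_grade(self) -> bool:
        return bool((~np.isnan(self.grade)).any())

    def copy(self) -> "PatientHistory":
        return replace(
            self,
            t_months=self.t_months.copy(),
            grade=self.grade.copy(),
            hba1c=self.hba1c.copy(),
            sbp=self.sbp.copy(),
            duration_years=self.duration_years.copy(),
        )


def _validate_history(h: PatientHistory, problems: list[str]) -> None:
    pid = h.patient_id
    if h.sex not in ("male", "female"):
        problems.append(f"patient {pid}: sex must be 'male'/'female', got {h.sex!r}")
    if np.any(np.diff(h.t_months) <= 0):
        problems.append(f"patient {pid}: visit times not strictly increasing")
    if np.any(h.t_months < 0):
        problems.append(f"patient {pid}: negative visit time")
    if h.n_visits and h.follow_up_months < int(h.t_months.max()):
        problems.append(f"patient {pid}: follow_up_months < last visit time")
    g = h.grade[~np.isnan(h.grade)]
    if np.any((g < 0) | (g > 5) | (g != np.round(g))):
        problems.append(f"patient {pid}: grade outside {{0..5}}")
    for name, arr in (("hba1c", h.hba1c), ("sbp", h.sbp)):
        v = arr[~np.isnan(arr)]
        if np.any(v <= 0):
            problems.append(f"patient {pid}: non-positive {name}")


def validate_cohort(cohort: Iterable[PatientHistory]) -> None:
    problems: list[str] = []
    for h in cohort:
        _validate_history(h, problems)
    if problems:
        raise CohortValidationError(problems)


def read_cohort(path) -> list[PatientHistory]:
    """Read and validate a long-format cohort CSV.

    Malformed content raises :class:`CohortValidationError` listing every
    offence with its CSV line number (header = line 1).
    """
    df = pd.read_csv(path, dtype={"patient_id": str, "sex": str})
    problems: list[str] = []
    missing_cols = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing_cols:
        raise CohortValidationError([f"missing required column(s): {missing_cols}"])

    lines = df.index.to_numpy() + 2  # CSV line numbers
    grade = pd.to_numeric(df["grade"], errors="coerce")
    bad_grade = df["grade"].notna() & (
        grade.isna() | (grade != grade.round()) | (grade < 0) | (grade > 5)
    )
    for ln, val in zip(lines[bad_grade.to_numpy()], df.loc[bad_grade, "grade"]):
        problems.append(f"line {ln}: grade must be an integer in 0..5, got {val!r}")

    dup = df.duplicated(subset=["patient_id", "t_months"], keep=False)
    for ln, (pid, t) in zip(
        lines[dup.to_numpy()], df.loc[dup, ["patient_id", "t_months"]].to_numpy()
    ):
        problems.append(f"line {ln}: duplicate (patient_id, t_months) = ({pid}, {t})")
    if problems:
        raise CohortValidationError(problems)

    cohort: list[PatientHistory] = []
    for pid, grp in df.groupby("patient_id", sort=False):
        grp = grp.sort_values("t_months")
        cohort.append(
            PatientHistory(
                patient_id=str(pid),
                sex=str(grp["sex"].iloc[0]),
                follow_up_months=int(grp["follow_up_months"].iloc[0]),
                t_months=grp["t_months"].to_numpy(dtype=int),
                grade=pd.to_numeric(grp["grade"], errors="coerce").to_numpy(float),
                hba1c=grp["hba1c_mmol_mol"].to_numpy(float),
                sbp=grp["sbp_mmhg"].to_numpy(float),
                duration_years=grp["duration_years"].to_numpy(float),
            )
        )
    validate_cohort(cohort)
    return cohort


def write_cohort(cohort: Iterable[PatientHistory], path) -> None:
    """Write the long-format cohort CSV (missing values as empty fields)."""
    rows = []
    for h in cohort:
        for i in range(h.n_visits):
            rows.append(
                (
                    h.patient_id,
                    h.sex,
                    int(h.t_months[i]),
                    "" if math.isnan(h.grade[i]) else int(h.grade[i]),
                    h.hba1c[i],
                    h.sbp[i],
                    h.duration_years[i],
                    h.follow_up_months,
                )
            )
    df = pd.DataFrame(rows, columns=CSV_COLUMNS)
    df.to_csv(path, index=False)


@dataclass
class ExclusionCounts:
    """Patients removed per selection criterion, in the order applied."""

    no_grade: int = 0
    baseline_str: int = 0
    short_follow_up: int = 0
    retained: int = 0

    @property
    def total_input(self) -> int:
        return self.no_grade + self.baseline_str + self.short_follow_up + self.retained


def select_analysis_cohort(
    cohort: Iterable[PatientHistory], min_follow_up_months: int = 60
) -> tuple[list[PatientHistory], ExclusionCounts]:
    """Apply the study inclusion criteria, in order.

    1. at least one non-missing retinopathy grade;
    2. no STR (grade >= 3) at baseline, baseline being the earliest visit with
       a non-missing grade;
    3. at least ``min_follow_up_months`` of follow-up (default 60, the maximal
       screening interval the personalised model can assign).

    Each excluded patient is attributed to the first failing criterion only, so
    retained + per-criterion exclusions always totals the input count.
    """
    kept: list[PatientHistory] = []
    counts = ExclusionCounts()
    for h in cohort:
        if not h.has_any_grade():
            counts.no_grade += 1
        elif h.baseline_grade() >= STR_GRADE:
            counts.baseline_str += 1
        elif h.follow_up_months < min_follow_up_months:
            counts.short_follow_up += 1
        else:
            kept.append(h)
    counts.retained = len(kept)
    return kept, counts
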