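"""Missing-data handling for the longitudinal cohort.

Three rules, applied in this order:

1. :func:`interpolate_grades` — internal runs of missing retinopathy grades
   flanked by two observed sub-STR grades are filled: with the common grade if
   the flanks agree, otherwise with an integer-rounded draw from a continuous
   uniform between the two flanking grades.  Gaps that end in an STR grade
   (>= 3) are deliberately left missing: they define the onset uncertainty the
   fast/slow scenarios resolve.
2. :func:`assign_str_onset` — for each patient whose grades ever reach STR,
   the onset time under one of two extreme progression scenarios: *fast* puts
   onset at the first possible time point (the first missing-grade visit after
   the last observed sub-STR grade), *slow* at the last possible time point
   (the first visit with an observed STR grade).  By construction
   fast onset <= slow onset per patient.
3. :func:`impute_covariates` — missing HbA1c / SBP / diabetes duration are
   replaced by the cohort-wide mean conditional on the visit's retinopathy
   grade (falling back to the overall mean for empty strata, with a warning).

All stochastic fills are driven by per-patient substreams of one master seed,
so results are reproducible under cohort subsetting.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from ._utils import substream
from .cohort_io import STR_GRADE, PatientHistory

SCENARIOS = ("fast", "slow")


class ContractViolation(RuntimeError):
    """An upstream guarantee was broken (e.g. baseline STR reached imputation)."""


@dataclass(frozen=True)
class ImputationScenario:
    """Which extreme STR-progression assumption to apply, plus its seed."""

    str_progression: str  # "fast" | "slow"
    rng_seed: int = 0

    def __post_init__(self):
        if self.str_progression not in SCENARIOS:
            raise ValueError(
                f"str_progression must be one of {SCENARIOS}, got {self.str_progression!r}"
            )


def interpolate_grades(history: PatientHistory, seed: int = 0) -> PatientHistory:
    """Fill internal missing-grade runs flanked by observed sub-STR grades.

    Equal flanks (a == b) fill deterministically with that grade; differing
    flanks fill each missing slot with an independent draw from U[min(a,b),
    max(a,b)] rounded half-away-from-zero to an integer.  Leading/trailing
    missing grades, and gaps whose right flank is an STR grade, are left
    untouched.  Deterministic for a fixed seed.
    """
    h = history.copy()
    obs = np.flatnonzero(~np.isnan(h.grade))
    if len(obs) == 0:
        raise ValueError(f"patient {h.patient_id}: no observed grade to interpolate from")
    rng = substream(seed, "interp", h.patient_id)
    for left, right in zip(obs[:-1], obs[1:]):
        if right - left <= 1:
            continue
        a, b = h.grade[left], h.grade[right]
        if b >= STR_GRADE:
            continue  # onset gap: resolved by the fast/slow scenarios
        lo, hi = sorted((a, b))
        gap = slice(left + 1, right)
        if lo == hi:
            h.grade[gap] = lo
        else:
            draws = rng.uniform(lo, hi, size=right - left - 1)
            h.grade[gap] = np.floor(draws + 0.5)  # round half away from zero (draws >= 0)
    return h


def assign_str_onset(history: PatientHistory, scenario: ImputationScenario) -> Optional[int]:
    """STR onset time (months) under the given progression scenario.

    Returns ``None`` for patients never reaching an observed grade >= 3.  For
    STR cases, let T be the first visit with an observed STR grade and S the
    last visit before T with an observed sub-STR grade: the *slow* scenario
    returns T; the *fast* scenario returns the first missing-grade visit after
    S (or T when every intervening visit has an observed grade).
    """
    g = history.grade
    t = history.t_months
    str_idx = np.flatnonzero(~np.isnan(g) & (g >= STR_GRADE))
    if len(str_idx) == 0:
        return None
    first_str = int(str_idx[0])
    pre = np.flatnonzero(~np.isnan(g[:first_str]) & (g[:first_str] < STR_GRADE))
    if len(pre) == 0:
        raise ContractViolation(
            f"patient {history.patient_id}: first observed grade is STR; "
            "baseline-STR patients must be excluded upstream"
        )
    if scenario.str_progression == "slow":
        return int(t[first_str])
    last_sub = int(pre[-1])
    gap = np.flatnonzero(np.isnan(g[last_sub + 1 : first_str]))
    if len(gap) == 0:
        return int(t[first_str])
    return int(t[last_sub + 1 + gap[0]])


def impute_covariates(cohort: Iterable[PatientHistory]) -> list[PatientHistory]:
    """Replace missing HbA1c/SBP/duration by grade-conditional cohort means.

    The stratum of a visit is its (possibly interpolated) grade; visits with a
    still-missing grade use the overall mean.  Non-missing values are never
    altered.
    """
    cohort = [h.copy() for h in cohort]
    fields = ("hba1c", "sbp", "duration_years")

    all_grades = np.concatenate([h.grade for h in cohort]) if cohort else np.array([])
    values = {f: np.concatenate([getattr(h, f) for h in cohort]) for f in fields} if cohort else {}

    means: dict[str, dict] = {}
    for f in fields:
        v = values[f]
        overall = float(np.nanmean(v)) if np.any(~np.isnan(v)) else float("nan")
        per_grade = {}
        for g in np.unique(all_grades[~np.isnan(all_grades)]):
            sel = (all_grades == g) & ~np.isnan(v)
            if sel.any():
                per_grade[float(g)] = float(v[sel].mean())
            else:
                warnings.warn(
                    f"no observed {f} in grade-{int(g)} stratum; falling back to overall mean"
                )
                per_grade[float(g)] = overall
        means[f] = {"overall": overall, "per_grade": per_grade}

    for h in cohort:
        for f in fields:
            arr = getattr(h, f)
            for i in np.flatnonzero(np.isnan(arr)):
                g = h.grade[i]
                if math.isnan(g):
                    arr[i] = means[f]["overall"]
                else:
                    arr[i] = means[f]["per_grade"].get(float(g), means[f]["overall"])
    return cohort


def apply_scenario(
    cohort: Iterable[PatientHistory], scenario: ImputationScenario | str, seed: int | None = None
) -> tuple[list[PatientHistory], dict[str, Optional[int]]]:
    """Full imputation pipeline: interpolate grades, impute covariates, assign onsets.

    Returns the imputed cohort and a patient_id -> onset-month map (``None``
    for non-STR patients).
    """
    if isinstance(scenario, str):
        scenario = ImputationScenario(scenario, rng_seed=seed if seed is not None else 0)
    eff_seed = scenario.rng_seed if seed is None else seed
    interpolated = [interpolate_grades(h, eff_seed) for h in cohort]
    onsets = {h.patient_id: assign_str_onset(h, scenario) for h in interpolated}
    imputed = impute_covariates(interpolated)
    return imputed, onsets
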