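"""Personalised screening-interval engine.

Time to sight-threatening retinopathy (STR) is modelled with a Weibull
proportional-hazards cumulative incidence

    F(t | x) = 1 - exp(-exp(beta' x) * t^p),    t in months,

where x collects sex, log diabetes duration, log HbA1c, log systolic blood
pressure and an indicator for present (sub-STR) retinopathy.  The personalised
screening interval at a preset risk margin ``eps`` (the accepted probability of
developing STR before the next screen) is the analytic inversion

    t*(eps | x) = ( -ln(1 - eps) / exp(beta' x) )^(1/p),

clamped to the model's admissible range, 6 to 60 months by default, and rounded
down to whole months.  Higher-risk covariates shorten the interval; a zero
margin always yields the 6-month floor.

Coefficient values are not hard-coded: they ship in a versioned config
(``configs/risk_model.yaml`` mirrors :data:`DEFAULT_COEFFICIENTS`) so the engine
is correct under any transcription; everything here except the clamp values is
coefficient-agnostic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import yaml

COEFFICIENT_NAMES = (
    "intercept",
    "male",
    "log_duration",
    "log_hba1c",
    "log_sbp",
    "retinopathy_present",
)

#: Default Weibull-PH parameterisation shipped with the package.  Calibrated so
#: that a typical type 2 diabetes profile (HbA1c ~56 mmol/mol, SBP ~143 mmHg,
#: short duration, no retinopathy) gets a ~26-month interval at a 2.0% margin,
#: the lowest-risk profiles exceed the 60-month cap at 4.0%, and extreme
#: high-risk profiles fall below the 6-month floor.
DEFAULT_COEFFICIENTS: dict[str, float] = {
    "intercept": -23.0,
    "male": 0.15,
    "log_duration": 0.35,
    "log_hba1c": 1.8,
    "log_sbp": 1.3,
    "retinopathy_present": 1.2,
}
DEFAULT_SHAPE = 1.6


@dataclass(frozen=True)
class RiskModelParams:
    """Parametric survival coefficients plus interval clamps."""

    shape: float = DEFAULT_SHAPE
    coefficients: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COEFFICIENTS)
    )
    min_interval_months: int = 6
    max_interval_months: int = 60
    snap_to_menu: bool = False
    menu_months: tuple[int, ...] = (6, 12, 24, 36, 48, 60)

    def __post_init__(self):
        if not self.shape > 0:
            raise ValueError(f"shape must be > 0, got {self.shape}")
        if not self.min_interval_months < self.max_interval_months:
            raise ValueError("min_interval_months must be < max_interval_months")
        missing = [k for k in COEFFICIENT_NAMES if k not in self.coefficients]
        if missing:
            raise ValueError(f"missing coefficient(s): {missing}")

    @classmethod
    def from_yaml(cls, path) -> "RiskModelParams":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            shape=float(raw["shape"]),
            coefficients={k: float(v) for k, v in raw["coefficients"].items()},
            min_interval_months=int(raw.get("min_interval_months", 6)),
            max_interval_months=int(raw.get("max_interval_months", 60)),
            snap_to_menu=bool(raw.get("snap_to_menu", False)),
            menu_months=tuple(raw.get("menu_months", (6, 12, 24, 36, 48, 60))),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "shape": self.shape,
                    "coefficients": dict(self.coefficients),
                    "min_interval_months": self.min_interval_months,
                    "max_interval_months": self.max_interval_months,
                    "snap_to_menu": self.snap_to_menu,
                    "menu_months": list(self.menu_months),
                },
                fh,
                sort_keys=False,
            )


def default_params() -> RiskModelParams:
    return RiskModelParams()


@dataclass(frozen=True)
class RiskProfile:
    """Covariate profile at a screen (post-imputation, all fields present)."""

    male: bool
    diabetes_duration_years: float
    hba1c: float  # mmol/mol
    sbp: float  # mmHg
    retinopathy_present: bool

    def __post_init__(self):
        for name in ("diabetes_duration_years", "hba1c", "sbp"):
            v = getattr(self, name)
            if not (v > 0 and math.isfinite(v)):
                raise ValueError(f"{name} must be positive and finite, got {v}")


def linear_predictor(profile: RiskProfile, params: RiskModelParams) -> float:
    """beta' x for one profile."""
    c = params.coefficients
    eta = (
        c["intercept"]
        + c["male"] * float(profile.male)
        + c["log_duration"] * math.log(profile.diabetes_duration_years)
        + c["log_hba1c"] * math.log(profile.hba1c)
        + c["log_sbp"] * math.log(profile.sbp)
        + c["retinopathy_present"] * float(profile.retinopathy_present)
    )
    if not math.isfinite(eta):
        raise ArithmeticError(f"non-finite linear predictor for profile {profile}")
    return eta


def cumulative_incidence(t_months, profile: RiskProfile, params: RiskModelParams):
    """F(t | x): probability of STR onset by month ``t``.

    Accepts a scalar or array ``t``; strictly increasing in t with F(0) = 0.
    """
    t = np.asarray(t_months, dtype=float)
    if np.any(t < 0):
        raise ValueError("t_months must be >= 0")
    lam = math.exp(linear_predictor(profile, params))
    out = -np.expm1(-lam * t**params.shape)
    return float(out) if np.isscalar(t_months) else out


def invert_interval_months(
    profile: RiskProfile, risk_margin: float, params: RiskModelParams
) -> float:
    """Unclamped analytic inversion: the t with F(t | x) = risk_margin."""
    if risk_margin < 0:
        raise ValueError(f"risk_margin must be >= 0, got {risk_margin}")
    if risk_margin >= 1:
        raise ValueError("risk_margin must be < 1")
    if risk_margin == 0:
        return 0.0
    lam = math.exp(linear_predictor(profile, params))
    return (-math.log1p(-risk_margin) / lam) ** (1.0 / params.shape)


def personalised_interval(
    profile: RiskProfile, risk_margin: float, params: RiskModelParams
) -> int:
    """Screening interval (whole months) at the given risk margin.

    Analytic inversion, clamped to ``[min_interval, max_interval]``, then
    rounded down to whole months (optionally snapped down to a discrete menu).
    Monotone non-decreasing in the margin; non-increasing in each risk-raising
    covariate.
    """
    t = invert_interval_months(profile, risk_margin, params)
    t = min(max(t, float(params.min_interval_months)), float(params.max_interval_months))
    months = int(math.floor(t))
    if params.snap_to_menu:
        menu = sorted(params.menu_months)
        candidates = [m for m in menu if m <= months]
        months = candidates[-1] if candidates else menu[0]
    return months


def interval_grid(
    profiles: Sequence[RiskProfile],
    margins: Sequence[float],
    params: RiskModelParams,
) -> np.ndarray:
    """Per-patient, per-margin interval matrix (months), shape (n, len(margins))."""
    margins = np.asarray(margins, dtype=float)
    if np.any(np.diff(margins) <= 0):
        raise ValueError("margins must be strictly increasing")
    out = np.empty((len(profiles), len(margins)), dtype=int)
    for i, prof in enumerate(profiles):
        for j, eps in enumerate(margins):
            out[i, j] = personalised_interval(prof, float(eps), params)
    return out


def default_margin_grid(step: float = 0.001, stop: float = 0.04) -> np.ndarray:
    """Risk margins 0.0% to 4.0% in 0.1% steps, as fractions."""
    n = int(round(stop / step))
    return np.round(np.linspace(0.0, stop, n + 1), 10)
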