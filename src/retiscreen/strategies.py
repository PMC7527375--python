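"""The three screening policies behind one interface.

A policy maps the state observed at a screen (the grades seen at screens so
far, plus the current covariate profile) to a :class:`PolicyDecision`: either
"screen again after N months" or "refer to ophthalmology" when the observed
grade is sight-threatening (>= 3).

* annual: fixed 12-month interval;
* Dutch guideline: 24 months after a retinopathy-free screen, 36 months after
  two consecutive retinopathy-free screens, 12 months for mild retinopathy
  (grades 1-2).  A grade-0 screen following a grade-1/2 screen restarts at
  24 months (36 requires two consecutive retinopathy-free screens);
* personalised: the risk-model interval at a chosen risk margin.

Policies are pure functions of the state.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

from .risk_model import RiskModelParams, RiskProfile, personalised_interval

REFER = "refer"
SCREEN_AFTER = "screen_after"


@dataclass(frozen=True)
class PolicyDecision:
    action: str  # "screen_after" | "refer"
    interval_months: Optional[int] = None

    def __post_init__(self):
        if self.action == SCREEN_AFTER and not (
            self.interval_months is not None and self.interval_months >= 1
        ):
            raise ValueError("screen_after decisions need interval_months >= 1")
        if self.action == REFER and self.interval_months is not None:
            raise ValueError("refer decisions carry no interval")


@dataclass(frozen=True)
class ScreenState:
    """What the policy can see at a screen.

    ``grades``: grades observed at all screens so far, oldest first, current
    screen last.  ``profile``: current covariates (needed by the personalised
    policy only).
    """

    grades: tuple[int, ...]
    profile: Optional[RiskProfile] = None

    @property
    def current_grade(self) -> int:
        if not self.grades:
            raise ValueError("empty screen-grade history")
        return self.grades[-1]


Policy = Callable[[ScreenState], PolicyDecision]


def _check_grade(state: ScreenState) -> int:
    g = state.current_grade
    if g is None or not (0 <= g <= 5):
        raise ContractViolationGrade(f"invalid grade at screen: {g!r}")
    return g


class ContractViolationGrade(RuntimeError):
    """A screen observed no valid grade (screens observe grades by construction)."""


def annual_policy(state: ScreenState) -> PolicyDecision:
    """Fixed annual screening; refer at STR."""
    g = _check_grade(state)
    if g >= 3:
        return PolicyDecision(REFER)
    return PolicyDecision(SCREEN_AFTER, 12)


def dutch_guideline_policy(state: ScreenState) -> PolicyDecision:
    """Stratified 1-3 year screening based on the previous retinopathy grades."""
    g = _check_grade(state)
    if g >= 3:
        return PolicyDecision(REFER)
    if g >= 1:
        return PolicyDecision(SCREEN_AFTER, 12)
    # current grade 0: 36 months only after two consecutive retinopathy-free screens
    if len(state.grades) >= 2 and state.grades[-2] == 0:
        return PolicyDecision(SCREEN_AFTER, 36)
    return PolicyDecision(SCREEN_AFTER, 24)


def personalised_policy(
    state: ScreenState, risk_margin: float, params: RiskModelParams
) -> PolicyDecision:
    """Risk-model interval at the configured margin; refer at STR."""
    g = _check_grade(state)
    if g >= 3:
        return PolicyDecision(REFER)
    if state.profile is None:
        raise ContractViolationGrade("personalised policy needs a covariate profile")
    return PolicyDecision(
        SCREEN_AFTER, personalised_interval(state.profile, risk_margin, params)
    )


def make_policy(
    name: str,
    risk_margin: float | None = None,
    params: RiskModelParams | None = None,
) -> Policy:
    """Policy factory by strategy name: 'annual' | 'guideline' | 'personalised'."""
    if name == "annual":
        return annual_policy
    if name == "guideline":
        return dutch_guideline_policy
    if name == "personalised":
        if risk_margin is None or params is None:
            raise ValueError("personalised policy needs risk_margin and params")
        return lambda state: personalised_policy(state, risk_margin, params)
    raise ValueError(f"unknown strategy {name!r}")
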