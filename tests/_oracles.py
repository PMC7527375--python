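"""Independent reference implementations used to cross-check the package.

Deliberately written with naive month-by-month loops and plain-Python visit
lookups, sharing no schedule or state logic with the implementation under
test.
"""

from __future__ import annotations

import math

from scipy.optimize import brentq

from retiscreen.risk_model import RiskProfile, cumulative_incidence
from retiscreen.strategies import ScreenState


def _locf_grade(history, t):
    g = None
    for i in range(history.n_visits):
        if history.t_months[i] > t:
            break
        if not math.isnan(history.grade[i]):
            g = int(history.grade[i])
    if g is None:  # fall back to the first observed grade
        for i in range(history.n_visits):
            if not math.isnan(history.grade[i]):
                return int(history.grade[i])
        raise AssertionError("no observed grade")
    return g


def _profile(history, t):
    i = None
    for k in range(history.n_visits):
        if history.t_months[k] <= t:
            i = k
    assert i is not None
    return RiskProfile(
        male=history.sex == "male",
        diabetes_duration_years=float(history.duration_years[i]) + (t - int(history.t_months[i])) / 12.0,
        hba1c=float(history.hba1c[i]),
        sbp=float(history.sbp[i]),
        retinopathy_present=1 <= _locf_grade(history, t) < 3,
    )


def brute_force_screens(history, onset, policy):
    """Month-by-month event loop reproducing the screening schedule."""
    screens, grades = [], []
    due = 0
    for t in range(history.follow_up_months + 1):
        if t != due:
            continue
        screens.append(t)
        if onset is not None and t >= onset:
            grades.append(3)
        else:
            grades.append(min(_locf_grade(history, t), 2))
        decision = policy(ScreenState(tuple(grades), _profile(history, t)))
        if decision.action == "refer":
            break
        due = t + decision.interval_months
    return screens


def brute_force_delay(history, onset, policy):
    """Assessment-anchored delay computed from first principles."""
    if onset is None:
        return False, 0
    anchor = None
    grades = []
    for i in range(history.n_visits):
        t = int(history.t_months[i])
        if t >= onset:
            break
        if not math.isnan(history.grade[i]):
            anchor = t
            grades.append(min(int(history.grade[i]), 2))
    assert anchor is not None
    # LOCF within the assessed sequence: grades list already holds observed ones
    decision = policy(ScreenState(tuple(grades), _profile(history, anchor)))
    assert decision.action == "screen_after"
    delay = max(0, decision.interval_months - (onset - anchor))
    return delay > 0, delay


def bisect_interval_months(profile, risk_margin, params):
    """Root-finding inversion of the cumulative incidence (unclamped)."""
    if risk_margin == 0:
        return 0.0
    f = lambda t: cumulative_incidence(t, profile, params) - risk_margin
    hi = 1.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e9:
            raise AssertionError("bisection bracket failed")
    return brentq(f, 0.0, hi, xtol=1e-10, rtol=1e-14, maxiter=500)
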