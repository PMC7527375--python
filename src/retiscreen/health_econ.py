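"""Cost accounting, risk-margin optimisation, bootstrap PSA and CEAC curves.

Costs per screen fall into three categories — screening itself (healthcare
perspective) plus travel and productivity losses (societal perspective) —
each specified as a (min, max) range in euros.  A two-parameter gamma
distribution is fitted to every range by matching its 2.5% / 97.5% quantiles,
and drives the probabilistic sensitivity analysis.  Costs are discounted at
4.0%/year; the (optional) effect discount is 1.5%/year.

The personalised strategy's risk margin is optimised by a stepwise rule over
the 0.0-4.0% grid: for each 0.1% step, the incremental cost saving per extra
delayed STR diagnosis is computed (plateau steps carry their savings
forward), and the best margin is the one with the lowest delayed count at
which that incremental saving peaks.

Uncertainty is quantified with a two-stage bootstrap: stage 1 resamples
patients to get a distribution of best margins; stage 2, at the stage-1 mean
margin, resamples patients *and* draws unit costs from the gamma
distributions, yielding cost-effectiveness planes, percentile confidence
intervals and cost-effectiveness acceptability curves (CEACs).
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats

from ._utils import substream
from .cohort_io import PatientHistory, STR_GRADE
from .risk_model import RiskModelParams, default_margin_grid
from .screening_sim import ScreeningOutcome, simulate_patient
from .strategies import make_policy

DEFAULT_COST_RANGES: dict[str, tuple[float, float]] = {
    "screening": (15.25, 41.07),
    "travel": (1.58, 14.19),
    "productivity": (2.63, 16.62),
}
PERSPECTIVES = ("healthcare", "societal")
_SOCIETAL_EXTRA = ("travel", "productivity")


class NoOptimumError(ValueError):
    """The margin grid has no step with a positive delayed-count increment."""


@dataclass(frozen=True)
class EconParams:
    """Cost ranges, discount rates and perspective (2015 price level)."""

    cost_ranges: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_COST_RANGES)
    )
    discount_rate_costs: float = 0.04
    discount_rate_effects: float = 0.015
    perspective: str = "healthcare"
    price_year: int = 2015
    gamma_fit: str = "quantile"  # "quantile" (2.5/97.5 match) or "moment"
    discount_effects: bool = False

    def __post_init__(self):
        for cat, (lo, hi) in self.cost_ranges.items():
            if not (0 < lo < hi):
                raise ValueError(f"cost range for {cat!r} must satisfy 0 < min < max")
        if self.discount_rate_costs < 0 or self.discount_rate_effects < 0:
            raise ValueError("discount rates must be >= 0")
        if self.perspective not in PERSPECTIVES:
            raise ValueError(f"perspective must be one of {PERSPECTIVES}")
        if self.gamma_fit not in ("quantile", "moment"):
            raise ValueError("gamma_fit must be 'quantile' or 'moment'")


def econ_params_from_yaml(path) -> EconParams:
    """Load cost ranges, discount rates and perspective from a YAML config."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    kwargs = {}
    if "cost_ranges" in raw:
        kwargs["cost_ranges"] = {
            k: (float(v[0]), float(v[1])) for k, v in raw["cost_ranges"].items()
        }
    for key in (
        "discount_rate_costs",
        "discount_rate_effects",
        "perspective",
        "price_year",
        "gamma_fit",
        "discount_effects",
    ):
        if key in raw:
            kwargs[key] = raw[key]
    return EconParams(**kwargs)


@dataclass(frozen=True)
class GammaCost:
    """Gamma uncertainty distribution for one cost category (euros)."""

    shape: float
    rate: float
    category: str = "cost"

    def __post_init__(self):
        if not (self.shape > 0 and self.rate > 0):
            raise ValueError("gamma shape and rate must be > 0")

    @property
    def mean(self) -> float:
        return self.shape / self.rate

    def quantile(self, q: float) -> float:
        return float(stats.gamma.ppf(q, self.shape, scale=1.0 / self.rate))

    def sample(self, rng: np.random.Generator, size=None):
        return rng.gamma(self.shape, 1.0 / self.rate, size)


def fit_gamma_from_range(
    min_cost: float, max_cost: float, category: str = "cost", method: str = "quantile"
) -> GammaCost:
    """Gamma distribution matching a (min, max) cost range.

    ``quantile`` (default): shape/rate solved numerically so the 2.5% and
    97.5% quantiles equal (min, max).  ``moment``: mean = (min+max)/2 and
    SD = (max-min)/4.  Deterministic.
    """
    if not (0 < min_cost < max_cost):
        raise ValueError(f"need 0 < min < max, got ({min_cost}, {max_cost})")
    if method == "moment":
        mean = (min_cost + max_cost) / 2.0
        sd = (max_cost - min_cost) / 4.0
        shape = (mean / sd) ** 2
        return GammaCost(shape=shape, rate=mean / sd**2, category=category)

    ratio = max_cost / min_cost

    def gap(log10_k: float) -> float:
        k = 10.0**log10_k
        q = stats.gamma.ppf([0.025, 0.975], k)
        if q[0] <= 0:  # extreme small shapes underflow the lower quantile
            return float("inf")
        return q[1] / q[0] - ratio

    # quantile ratio is strictly decreasing in the shape; expand the bracket
    # until it straddles the root
    lo, hi = 0.0, 1.0
    while gap(lo) < 0:
        lo -= 1.0
    while gap(hi) > 0:
        lo, hi = hi, hi + 1.0
        if hi > 16:
            raise ArithmeticError(f"gamma fit failed for range ({min_cost}, {max_cost})")
    sol = optimize.brentq(gap, lo, hi, xtol=1e-13, rtol=8.9e-16, maxiter=200)
    shape = 10.0**sol
    scale = min_cost / float(stats.gamma.ppf(0.025, shape))
    return GammaCost(shape=shape, rate=1.0 / scale, category=category)


def fit_cost_gammas(econ: EconParams) -> dict[str, GammaCost]:
    return {
        cat: fit_gamma_from_range(lo, hi, category=cat, method=econ.gamma_fit)
        for cat, (lo, hi) in econ.cost_ranges.items()
    }


def discount_factor(t_months: float, annual_rate: float) -> float:
    return (1.0 + annual_rate) ** (-(t_months / 12.0))


def screen_cost_weight(screen_times_months: Sequence[int], annual_rate: float) -> float:
    """Sum of discount factors over a patient's screen times (unit-cost multiplier)."""
    return float(sum(discount_factor(t, annual_rate) for t in screen_times_months))


def perspective_unit_cost(unit_costs: Mapping[str, float], perspective: str) -> float:
    if perspective not in PERSPECTIVES:
        raise ValueError(f"perspective must be one of {PERSPECTIVES}")
    total = unit_costs["screening"]
    if perspective == "societal":
        total += sum(unit_costs[c] for c in _SOCIETAL_EXTRA)
    return total


def discounted_cost(
    outcome: ScreeningOutcome, unit_costs: Mapping[str, float], econ: EconParams
) -> float:
    """Discounted cost (euros) of one patient's simulated screens."""
    unit = perspective_unit_cost(unit_costs, econ.perspective)
    return unit * screen_cost_weight(outcome.screen_times_months, econ.discount_rate_costs)


def effect_weight(outcome: ScreeningOutcome, econ: EconParams) -> float:
    """Delayed-diagnosis effect: 1/0 indicator, optionally discounted at 1.5%/yr."""
    if not outcome.delayed:
        return 0.0
    if not econ.discount_effects:
        return 1.0
    return discount_factor(outcome.detection_time_months, econ.discount_rate_effects)


# --------------------------------------------------------------------------
# per-patient precomputation for the margin grid and the bootstrap


@dataclass
class CohortMatrices:
    """Per-patient discounted screen weights and delayed flags, all strategies."""

    patient_ids: list[str]
    fu_years: np.ndarray  # (n,)
    str_case: np.ndarray  # (n,) bool
    margins: np.ndarray  # (m,) fractions
    pers_weight: np.ndarray  # (n, m)
    pers_delayed: np.ndarray  # (n, m) int
    pers_screens: np.ndarray  # (n, m) int
    pers_interval_first: np.ndarray  # (n, m) interval at baseline screen
    annual_weight: np.ndarray
    annual_delayed: np.ndarray
    annual_screens: np.ndarray
    guideline_weight: np.ndarray
    guideline_delayed: np.ndarray
    guideline_screens: np.ndarray

    def weight(self, strategy: str, margin_idx: int | None = None) -> np.ndarray:
        if strategy == "personalised":
            return self.pers_weight[:, margin_idx]
        return getattr(self, f"{strategy}_weight")

    def delayed(self, strategy: str, margin_idx: int | None = None) -> np.ndarray:
        if strategy == "personalised":
            return self.pers_delayed[:, margin_idx]
        return getattr(self, f"{strategy}_delayed")


def _patient_precompute(h: PatientHistory, params: RiskModelParams):
    """Visit-level pieces of the linear predictor for fast interval lookup."""
    coef = params.coefficients
    t = h.t_months
    n = len(t)
    base = np.empty(n)
    dur = np.empty(n)
    b0 = h.baseline_grade()
    locf = min(b0, STR_GRADE - 1) if not math.isnan(b0) else 0.0
    g_locf = np.empty(n)
    for i in range(n):
        if not math.isnan(h.grade[i]) and h.grade[i] < STR_GRADE:
            locf = h.grade[i]
        g_locf[i] = locf
        base[i] = (
            coef["intercept"]
            + coef["male"] * (h.sex == "male")
            + coef["log_hba1c"] * math.log(h.hba1c[i])
            + coef["log_sbp"] * math.log(h.sbp[i])
            + coef["retinopathy_present"] * (1 <= g_locf[i] < STR_GRADE)
        )
        dur[i] = h.duration_years[i]
    return t, base, dur


def _interval_at(t_query, tv, base, dur, eps, params) -> int:
    i = bisect_right(tv, t_query) - 1
    d = dur[i] + (t_query - tv[i]) / 12.0
    eta = base[i] + params.coefficients["log_duration"] * math.log(d)
    if eps <= 0.0:
        raw = 0.0
    else:
        raw = (-math.log1p(-eps) / math.exp(eta)) ** (1.0 / params.shape)
    raw = min(max(raw, float(params.min_interval_months)), float(params.max_interval_months))
    return int(raw)


def _replay_personalised(h, onset, anchor, tv_list, base, dur, eps, params, rate):
    """Fast schedule replay + assessment-anchored delay for one patient and margin.

    ``anchor`` is the last visit before onset with an observed grade (``None``
    for non-STR patients); must match the anchor screening_sim derives.
    """
    fu = h.follow_up_months
    weight = 0.0
    screens = 0
    t = 0
    while True:
        screens += 1
        weight += (1.0 + rate) ** (-(t / 12.0))
        if onset is not None and t >= onset:
            break  # referral
        iv = _interval_at(t, tv_list, base, dur, eps, params)
        t_next = t + iv
        if t_next > fu:
            break
        t = t_next
    first_iv = _interval_at(0, tv_list, base, dur, eps, params)
    if onset is None:
        return weight, screens, 0, first_iv
    iv = _interval_at(anchor, tv_list, base, dur, eps, params)
    delayed = 1 if iv > (onset - anchor) else 0
    return weight, screens, delayed, first_iv


def compute_cohort_matrices(
    cohort: Sequence[PatientHistory],
    onsets: Mapping[str, Optional[int]],
    margins: Sequence[float],
    econ: EconParams,
    params: RiskModelParams,
) -> CohortMatrices:
    """Simulate every strategy once per patient (and per margin) and cache results."""
    margins = np.asarray(margins, dtype=float)
    n, m = len(cohort), len(margins)
    rate = econ.discount_rate_costs
    pw = np.zeros((n, m))
    pd_ = np.zeros((n, m), dtype=int)
    ps = np.zeros((n, m), dtype=int)
    pi = np.zeros((n, m), dtype=int)
    aw = np.zeros(n)
    ad = np.zeros(n, dtype=int)
    asc = np.zeros(n, dtype=int)
    gw = np.zeros(n)
    gd = np.zeros(n, dtype=int)
    gs = np.zeros(n, dtype=int)
    str_case = np.zeros(n, dtype=bool)
    fu_years = np.zeros(n)
    annual = make_policy("annual")
    guideline = make_policy("guideline")
    for i, h in enumerate(cohort):
        onset = onsets.get(h.patient_id)
        str_case[i] = onset is not None
        fu_years[i] = h.follow_up_months / 12.0
        oa = simulate_patient(h, onset, annual)
        og = simulate_patient(h, onset, guideline)
        aw[i] = screen_cost_weight(oa.screen_times_months, rate)
        ad[i] = int(oa.delayed)
        asc[i] = oa.screens_count
        gw[i] = screen_cost_weight(og.screen_times_months, rate)
        gd[i] = int(og.delayed)
        gs[i] = og.screens_count
        tv, base, dur = _patient_precompute(h, params)
        tv_list = [int(x) for x in tv]
        anchor = None
        if onset is not None:
            assessed = (h.t_months < onset) & ~np.isnan(h.grade)
            anchor = int(h.t_months[assessed][-1])
        for j, eps in enumerate(margins):
            w, s, d, f_iv = _replay_personalised(
                h, onset, anchor, tv_list, base, dur, float(eps), params, rate
            )
            pw[i, j] = w
            ps[i, j] = s
            pd_[i, j] = d
            pi[i, j] = f_iv
    return CohortMatrices(
        patient_ids=[h.patient_id for h in cohort],
        fu_years=fu_years,
        str_case=str_case,
        margins=margins,
        pers_weight=pw,
        pers_delayed=pd_,
        pers_screens=ps,
        pers_interval_first=pi,
        annual_weight=aw,
        annual_delayed=ad,
        annual_screens=asc,
        guideline_weight=gw,
        guideline_delayed=gd,
        guideline_screens=gs,
    )


# --------------------------------------------------------------------------
# margin grid and best-margin rule


@dataclass
class MarginGridResult:
    """Per-margin cost/outcome curves for the personalised strategy."""

    margins: np.ndarray  # fractions
    cost_per_patient: np.ndarray  # euros, discounted, chosen perspective
    delayed_count: np.ndarray  # int
    mean_first_interval: np.ndarray  # months, at the baseline screen
    matrices: CohortMatrices
    unit_cost: float  # point unit cost used (gamma means)

    def to_frame(self) -> pd.DataFrame:
        ratios = np.full(len(self.margins), np.nan)
        dd = np.diff(self.delayed_count)
        dc = -np.diff(self.cost_per_patient)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratios[1:] = np.where(dd > 0, dc / dd, np.nan)
        return pd.DataFrame(
            {
                "risk_margin_pct": self.margins * 100.0,
                "cost_per_patient_eur": self.cost_per_patient,
                "delayed_count": self.delayed_count,
                "mean_first_interval_months": self.mean_first_interval,
                "incremental_saving_per_delayed": ratios,
            }
        )


def margin_grid_analysis(
    cohort: Sequence[PatientHistory],
    onsets: Mapping[str, Optional[int]],
    margins: Sequence[float] | None = None,
    econ: EconParams | None = None,
    params: RiskModelParams | None = None,
    matrices: CohortMatrices | None = None,
) -> MarginGridResult:
    """Mean discounted cost per patient and delayed count across risk margins."""
    econ = econ or EconParams()
    params = params or RiskModelParams()
    margins = default_margin_grid() if margins is None else np.asarray(margins, float)
    if matrices is None:
        matrices = compute_cohort_matrices(cohort, onsets, margins, econ, params)
    gammas = fit_cost_gammas(econ)
    unit = perspective_unit_cost({c: g.mean for c, g in gammas.items()}, econ.perspective)
    return MarginGridResult(
        margins=margins,
        cost_per_patient=unit * matrices.pers_weight.mean(axis=0),
        delayed_count=matrices.pers_delayed.sum(axis=0),
        mean_first_interval=matrices.pers_interval_first.mean(axis=0),
        matrices=matrices,
        unit_cost=unit,
    )


def best_risk_margin(
    margins: Sequence[float] | MarginGridResult,
    cost_per_patient: Sequence[float] | None = None,
    delayed_count: Sequence[float] | None = None,
) -> float:
    """Stepwise optimum: margin where incremental saving per delayed case peaks.

    Steps with no extra delayed diagnoses carry their savings forward to the
    next step with a positive increment.  Ties are broken toward the lowest
    delayed count, then the lowest margin.  Raises :class:`NoOptimumError`
    when the delayed counts never increase.
    """
    if isinstance(margins, MarginGridResult):
        grid = margins
        margins, cost_per_patient, delayed_count = (
            grid.margins,
            grid.cost_per_patient,
            grid.delayed_count,
        )
    margins = np.asarray(margins, float)
    cost = np.asarray(cost_per_patient, float)
    delayed = np.asarray(delayed_count, float)
    candidates: list[tuple[float, float, float]] = []  # (ratio, delayed, margin)
    carry = 0.0
    d_prev = delayed[0]
    for k in range(1, len(margins)):
        carry += cost[k - 1] - cost[k]
        dd = delayed[k] - d_prev
        if dd > 0:
            candidates.append((carry / dd, delayed[k], float(margins[k])))
            carry = 0.0
            d_prev = delayed[k]
    if not candidates:
        raise NoOptimumError("delayed counts are flat across the margin grid")
    best_ratio = max(c[0] for c in candidates)
    tied = [c for c in candidates if c[0] == best_ratio]
    tied.sort(key=lambda c: (c[1], c[2]))
    return tied[0][2]


# --------------------------------------------------------------------------
# bootstrap, cost-effectiveness planes and CEAC


@dataclass
class CEAResult:
    """Everything the two-stage bootstrap produces."""

    margins: np.ndarray
    point_grid: MarginGridResult
    stage1_margins: np.ndarray  # (B,)
    best_margin_mean: float
    best_margin_ci: tuple[float, float]
    margin_star: float  # stage-2 margin (grid point nearest the mean)
    strategies: tuple[str, ...]
    total_cost_draws: dict[tuple[str, str], np.ndarray]  # (strategy, perspective) -> (B,)
    delayed_draws: dict[str, np.ndarray]  # strategy -> (B,)
    pyears_draws: np.ndarray  # (B,)
    increments: dict[tuple[str, str, str], np.ndarray]  # (strategy, comparator, persp) -> dCost
    delayed_increments: dict[tuple[str, str], np.ndarray]  # (strategy, comparator) -> dDelayed
    ceac_thresholds: np.ndarray
    ceac_curves: dict[tuple[str, str, str], np.ndarray]
    table: pd.DataFrame
    seed: int
    n_bootstrap: int


def ceac(draws: np.ndarray, thresholds: Sequence[float]) -> np.ndarray:
    """Acceptance probability per willingness-to-pay threshold.

    ``draws`` is a (B, 2) array of (delta cost, delta delayed) pairs of a
    strategy against its comparator; a draw accepts the strategy at threshold
    lambda when the net benefit lambda * (-delta_delayed) - delta_cost is
    positive (a delayed diagnosis avoided is the unit of effect).
    """
    draws = np.asarray(draws, dtype=float)
    if draws.size == 0:
        raise ValueError("ceac needs at least one draw")
    if draws.ndim != 2 or draws.shape[1] != 2:
        raise ValueError("draws must have shape (B, 2): (delta_cost, delta_delayed)")
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any(thresholds < 0):
        raise ValueError("thresholds must be >= 0")
    dc, dd = draws[:, 0], draws[:, 1]
    nb = thresholds[:, None] * (-dd[None, :]) - dc[None, :]
    return (nb > 0).mean(axis=1)


def _percentile_ci(x: np.ndarray) -> tuple[float, float]:
    return float(np.percentile(x, 2.5)), float(np.percentile(x, 97.5))


def _icer_summary(dcost_saving: np.ndarray, ddelayed: np.ndarray) -> dict[str, float]:
    """Saving per extra delayed diagnosis: mean of per-draw ratios + CI.

    Draws with a zero delayed increment have no defined ratio and are
    excluded from the mean-of-ratios; the ratio of means is also reported.
    """
    ok = ddelayed != 0
    ratios = dcost_saving[ok] / ddelayed[ok]
    out = {
        "mean_of_ratios": float(ratios.mean()) if ok.any() else float("nan"),
        "ci_low": float(np.percentile(ratios, 2.5)) if ok.any() else float("nan"),
        "ci_high": float(np.percentile(ratios, 97.5)) if ok.any() else float("nan"),
        "ratio_of_means": float(dcost_saving.mean() / ddelayed.mean())
        if ddelayed.mean() != 0
        else float("nan"),
        "n_defined": int(ok.sum()),
    }
    return out


def bootstrap_two_stage(
    cohort: Sequence[PatientHistory],
    onsets: Mapping[str, Optional[int]],
    B: int = 1000,
    econ: EconParams | None = None,
    params: RiskModelParams | None = None,
    seed: int = 0,
    margins: Sequence[float] | None = None,
    identity_resample: bool = False,
    ceac_thresholds: Sequence[float] | None = None,
    matrices: CohortMatrices | None = None,
) -> CEAResult:
    """Two-stage bootstrap over patients and unit costs.

    Stage 1: ``B`` patient resamples (with replacement, original size); the
    best risk margin of each resample (healthcare perspective, point unit
    costs) gives the margin distribution, its mean and percentile 95% CI.
    Stage 2: at the grid margin nearest the stage-1 mean, ``B`` fresh
    iterations resample patients *and* draw unit costs from the gamma
    distributions, producing total-cost and delayed-count draws for the
    annual, Dutch-guideline and personalised strategies under both
    perspectives, plus incremental draws, ICER summaries and CEAC curves.

    ``identity_resample=True`` replaces every resample by the identity (for
    degenerate-bootstrap testing).  Fixed ``seed`` gives bit-identical output.
    """
    if B < 1:
        raise ValueError(f"B must be >= 1, got {B}")
    econ = econ or EconParams()
    params = params or RiskModelParams()
    margins = default_margin_grid() if margins is None else np.asarray(margins, float)
    n = len(cohort)
    if matrices is None:
        matrices = compute_cohort_matrices(cohort, onsets, margins, econ, params)
    gammas = fit_cost_gammas(econ)
    point_units = {c: g.mean for c, g in gammas.items()}
    unit_hc_point = perspective_unit_cost(point_units, "healthcare")
    point_grid = MarginGridResult(
        margins=margins,
        cost_per_patient=unit_hc_point * matrices.pers_weight.mean(axis=0),
        delayed_count=matrices.pers_delayed.sum(axis=0),
        mean_first_interval=matrices.pers_interval_first.mean(axis=0),
        matrices=matrices,
        unit_cost=unit_hc_point,
    )

    # ---- stage 1: best margin per patient resample (healthcare costs) ----
    rng1 = substream(seed, "stage1-resample")
    stage1 = np.empty(B)
    for b in range(B):
        idx = np.arange(n) if identity_resample else rng1.integers(0, n, n)
        cost_col = unit_hc_point * matrices.pers_weight[idx].mean(axis=0)
        delayed_col = matrices.pers_delayed[idx].sum(axis=0)
        try:
            stage1[b] = best_risk_margin(margins, cost_col, delayed_col)
        except NoOptimumError:
            stage1[b] = float(margins[-1])  # cheapest margin, no marginal harm seen
    best_mean = float(stage1.mean())
    best_ci = _percentile_ci(stage1)
    j_star = int(np.argmin(np.abs(margins - best_mean)))
    margin_star = float(margins[j_star])

    # ---- stage 2: resample patients and draw unit costs ----
    rng2 = substream(seed, "stage2-resample")
    rng3 = substream(seed, "stage2-costs")
    strategies = ("annual", "guideline", "personalised")
    weights = {
        "annual": matrices.annual_weight,
        "guideline": matrices.guideline_weight,
        "personalised": matrices.pers_weight[:, j_star],
    }
    delayed = {
        "annual": matrices.annual_delayed,
        "guideline": matrices.guideline_delayed,
        "personalised": matrices.pers_delayed[:, j_star],
    }
    total_cost = {(s, p): np.empty(B) for s in strategies for p in PERSPECTIVES}
    delayed_draws = {s: np.empty(B) for s in strategies}
    pyears = np.empty(B)
    for b in range(B):
        idx = np.arange(n) if identity_resample else rng2.integers(0, n, n)
        units = {c: float(g.sample(rng3)) for c, g in gammas.items()}
        u_hc = perspective_unit_cost(units, "healthcare")
        u_soc = perspective_unit_cost(units, "societal")
        pyears[b] = matrices.fu_years[idx].sum()
        for s in strategies:
            w = weights[s][idx].sum()
            total_cost[(s, "healthcare")][b] = u_hc * w
            total_cost[(s, "societal")][b] = u_soc * w
            delayed_draws[s][b] = delayed[s][idx].sum()

    pairs = (("personalised", "annual"), ("guideline", "annual"), ("personalised", "guideline"))
    increments = {}
    delayed_increments = {}
    for s, comp in pairs:
        delayed_increments[(s, comp)] = delayed_draws[s] - delayed_draws[comp]
        for p in PERSPECTIVES:
            increments[(s, comp, p)] = total_cost[(s, p)] - total_cost[(comp, p)]

    thresholds = (
        np.linspace(0.0, 50_000.0, 201)
        if ceac_thresholds is None
        else np.asarray(ceac_thresholds, float)
    )
    curves = {}
    for s, comp in pairs:
        for p in PERSPECTIVES:
            draws = np.column_stack(
                [increments[(s, comp, p)], delayed_increments[(s, comp)]]
            )
            curves[(s, comp, p)] = ceac(draws, thresholds)

    # ---- Table-2-style summary ----
    rows = []
    for s in strategies:
        for p in PERSPECTIVES:
            x = total_cost[(s, p)]
            lo, hi = _percentile_ci(x)
            rows.append((f"total_cost_{s}", p, float(x.mean()), lo, hi))
    for s in ("personalised", "guideline"):
        for p in PERSPECTIVES:
            saving = (total_cost[("annual", p)] - total_cost[(s, p)]) / pyears
            lo, hi = _percentile_ci(saving)
            rows.append((f"saving_per_patient_year_{s}_vs_annual", p, float(saving.mean()), lo, hi))
    for s in ("personalised", "guideline"):
        for p in PERSPECTIVES:
            summ = _icer_summary(
                total_cost[("annual", p)] - total_cost[(s, p)],
                delayed_increments[(s, "annual")],
            )
            rows.append(
                (f"icer_saving_per_delayed_{s}_vs_annual", p, summ["mean_of_ratios"],
                 summ["ci_low"], summ["ci_high"])
            )
    for s in ("personalised", "guideline"):
        x = delayed_draws[s]
        lo, hi = _percentile_ci(x)
        rows.append((f"delayed_diagnoses_{s}", "both", float(x.mean()), lo, hi))
    table = pd.DataFrame(rows, columns=["item", "perspective", "mean", "ci_2.5", "ci_97.5"])

    return CEAResult(
        margins=margins,
        point_grid=point_grid,
        stage1_margins=stage1,
        best_margin_mean=best_mean,
        best_margin_ci=best_ci,
        margin_star=margin_star,
        strategies=strategies,
        total_cost_draws=total_cost,
        delayed_draws=delayed_draws,
        pyears_draws=pyears,
        increments=increments,
        delayed_increments=delayed_increments,
        ceac_thresholds=thresholds,
        ceac_curves=curves,
        table=table,
        seed=seed,
        n_bootstrap=B,
    )
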