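import math

import numpy as np
import pytest

from retiscreen.health_econ import compute_cohort_matrices, EconParams, screen_cost_weight
from retiscreen.imputation import ContractViolation
from retiscreen.screening_sim import simulate_cohort, simulate_patient, summarise
from retiscreen.strategies import make_policy

from _oracles import brute_force_delay, brute_force_screens
from conftest import make_history
from test_risk_model import flat_params, ANY_PROFILE


def interval_params(months, margin=0.02):
    """Flat-risk params whose interval at `margin` floors to exactly `months`."""
    return flat_params(-math.log1p(-margin) / (months + 0.5), shape=1.0)


class TestSinglePatient:
    def test_annual_detects_on_grid_onset_without_delay(self):
        h = make_history([0, 0, 3, 3], follow_up=48)
        out = simulate_patient(h, 24, make_policy("annual"))
        assert out.str_case and not out.delayed
        assert out.delay_months == 0
        assert out.detection_time_months == 24
        assert out.screen_times_months == [0, 12, 24]  # referral stops the schedule

    def test_overshooting_interval_delays_by_the_overshoot(self):
        params = interval_params(24)
        h = make_history([0, 3, 3], follow_up=36)
        out = simulate_patient(h, 12, make_policy("personalised", 0.02, params))
        assert out.delayed and out.delay_months == 12
        assert out.detection_time_months == 24

    def test_hand_traced_guideline_schedule(self):
        # grade 0 everywhere: screens 0 -> +24 -> 24 -> +36 -> 60 == follow-up end
        h = make_history([0] * 6, follow_up=60)
        out = simulate_patient(h, None, make_policy("guideline"))
        assert out.screen_times_months == [0, 24, 60]
        assert out.screens_count == 3
        assert not out.str_case and not out.delayed

    def test_screen_beyond_follow_up_not_performed(self):
        h = make_history([0, 0], follow_up=30)
        out = simulate_patient(h, None, make_policy("guideline"))
        assert out.screen_times_months == [0, 24]  # 24 + 36 > 30

    def test_onset_at_baseline_is_contract_violation(self):
        h = make_history([0, 3], follow_up=12)
        with pytest.raises(ContractViolation):
            simulate_patient(h, 0, make_policy("annual"))


class TestCohortAggregation:
    def test_zero_str_cases_reports_no_fraction(self):
        cohort = [make_history([0, 0, 0], pid=f"P{i}") for i in range(3)]
        _, summary = simulate_cohort(cohort, {}, make_policy("annual"))
        assert summary.str_cases == 0
        assert summary.delayed_count == 0
        assert summary.delayed_pct_of_str is None
        assert summary.delay_median is None

    def test_single_delayed_patient_summary(self):
        params = interval_params(24)
        h = make_history([0, 3, 3], follow_up=36)
        out = simulate_patient(h, 12, make_policy("personalised", 0.02, params))
        summary = summarise([out])
        assert summary.delayed_count == 1
        assert summary.delay_median == 12
        assert summary.delayed_pct_of_str == 100.0


class TestStructuralProperties:
    def test_annual_never_delayed(self, analysis_cohort):
        imputed, onsets_fast, onsets_slow = analysis_cohort
        for onsets in (onsets_fast, onsets_slow):
            _, summary = simulate_cohort(imputed, onsets, make_policy("annual"))
            assert summary.delayed_count == 0

    @pytest.mark.parametrize("margin", [0.005, 0.02, 0.04])
    def test_delay_bounded_by_max_interval_minus_spacing(
        self, analysis_cohort, params, margin
    ):
        imputed, onsets_fast, _ = analysis_cohort
        policy = make_policy("personalised", margin, params)
        outcomes, _ = simulate_cohort(imputed, onsets_fast, policy)
        for o in outcomes:
            assert o.delay_months <= 48
            assert o.delayed == (o.delay_months > 0)
            if o.delayed:
                assert o.str_case

    def test_per_patient_delay_monotone_in_margin(self, analysis_cohort, params):
        imputed, onsets_fast, _ = analysis_cohort
        margins = [0.0, 0.005, 0.01, 0.02, 0.03, 0.04]
        prev = None
        for margin in margins:
            policy = make_policy("personalised", margin, params)
            outcomes, _ = simulate_cohort(imputed, onsets_fast, policy)
            delays = np.array([o.delay_months for o in outcomes])
            if prev is not None:
                assert np.all(delays >= prev)
            prev = delays

    def test_fast_scenario_dominates_slow_per_patient(self, analysis_cohort, params):
        imputed, onsets_fast, onsets_slow = analysis_cohort
        for policy in (
            make_policy("annual"),
            make_policy("guideline"),
            make_policy("personalised", 0.02, params),
        ):
            out_f, _ = simulate_cohort(imputed, onsets_fast, policy)
            out_s, _ = simulate_cohort(imputed, onsets_slow, policy)
            for a, b in zip(out_f, out_s):
                assert a.delay_months >= b.delay_months


class TestOracleEquivalence:
    def test_brute_force_event_loop_matches(self, analysis_cohort, params):
        imputed, onsets_fast, _ = analysis_cohort
        policies = [
            make_policy("annual"),
            make_policy("guideline"),
            make_policy("personalised", 0.02, params),
        ]
        for h in imputed[:40]:
            onset = onsets_fast.get(h.patient_id)
            for policy in policies:
                out = simulate_patient(h, onset, policy)
                assert out.screen_times_months == brute_force_screens(h, onset, policy)
                delayed, delay = brute_force_delay(h, onset, policy)
                assert (out.delayed, out.delay_months) == (delayed, delay)

    def test_fast_path_matrices_match_simulator(self, analysis_cohort, params):
        """The vectorised economics precomputation equals the reference simulator."""
        imputed, onsets_fast, _ = analysis_cohort
        econ = EconParams()
        margins = np.array([0.0, 0.01, 0.02, 0.04])
        mats = compute_cohort_matrices(imputed, onsets_fast, margins, econ, params)
        for j, margin in enumerate(margins):
            policy = make_policy("personalised", float(margin), params)
            outcomes, _ = simulate_cohort(imputed, onsets_fast, policy)
            for i, o in enumerate(outcomes):
                assert mats.pers_screens[i, j] == o.screens_count
                assert mats.pers_delayed[i, j] == int(o.delayed)
                assert mats.pers_weight[i, j] == pytest.approx(
                    screen_cost_weight(o.screen_times_months, econ.discount_rate_costs)
                )
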