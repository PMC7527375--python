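import numpy as np
import pytest

from retiscreen.health_econ import (
    DEFAULT_COST_RANGES,
    EconParams,
    NoOptimumError,
    best_risk_margin,
    bootstrap_two_stage,
    ceac,
    discounted_cost,
    econ_params_from_yaml,
    fit_gamma_from_range,
    margin_grid_analysis,
)
from retiscreen.risk_model import default_margin_grid
from retiscreen.screening_sim import ScreeningOutcome


def outcome(screens, pid="P1", delayed=False, delay=0):
    return ScreeningOutcome(pid, list(screens), delayed or delay > 0, delay > 0, delay,
                            None)


class TestGammaFit:
    @pytest.mark.parametrize("lo, hi", list(DEFAULT_COST_RANGES.values()))
    def test_quantiles_reproduce_range(self, lo, hi):
        g = fit_gamma_from_range(lo, hi)
        assert g.quantile(0.025) == pytest.approx(lo, rel=1e-6)
        assert g.quantile(0.975) == pytest.approx(hi, rel=1e-6)

    def test_near_degenerate_range(self):
        g = fit_gamma_from_range(10.0, 10.0001)
        assert g.shape > 1e9
        assert g.quantile(0.025) == pytest.approx(10.0, rel=1e-6)
        assert g.quantile(0.975) == pytest.approx(10.0001, rel=1e-6)

    def test_sampled_mean_matches_moment_identity(self):
        g = fit_gamma_from_range(15.25, 41.07)
        rng = np.random.default_rng(0)
        n = 1_000_000
        x = g.sample(rng, n)
        se = x.std() / n**0.5
        assert abs(x.mean() - g.mean) < 3 * se

    def test_moment_variant(self):
        g = fit_gamma_from_range(10.0, 30.0, method="moment")
        assert g.mean == pytest.approx(20.0)
        assert (g.shape / g.rate**2) ** 0.5 == pytest.approx(5.0)

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError):
            fit_gamma_from_range(5.0, 5.0)


class TestDiscounting:
    def test_no_discount_at_time_zero(self):
        cost = discounted_cost(outcome([0]), {"screening": 20.0}, EconParams())
        assert cost == 20.0

    def test_one_year_discount(self):
        cost = discounted_cost(outcome([12]), {"screening": 20.0}, EconParams())
        assert cost == pytest.approx(20.0 / 1.04, abs=1e-10)

    def test_societal_at_least_healthcare(self):
        units = {"screening": 20.0, "travel": 5.0, "productivity": 8.0}
        o = outcome([0, 12, 30])
        hc = discounted_cost(o, units, EconParams(perspective="healthcare"))
        soc = discounted_cost(o, units, EconParams(perspective="societal"))
        assert soc >= hc
        assert soc == pytest.approx(hc * 33.0 / 20.0)


class TestBestMargin:
    def test_worked_example(self):
        # brute-force over the steps: ratios (7, 4/3, 2) -> peak at the first
        margins = [0.00, 0.01, 0.02, 0.03]
        assert best_risk_margin(margins, [27, 20, 16, 14], [0, 1, 4, 5]) == 0.01

    def test_plateau_savings_carry_forward(self):
        # no new delays at step 1; its saving counts toward step 2
        margins = [0.00, 0.01, 0.02]
        assert best_risk_margin(margins, [27, 20, 10], [0, 0, 2]) == 0.02

    def test_single_step(self):
        assert best_risk_margin([0.0, 0.04], [27, 14], [0, 5]) == 0.04

    def test_tie_prefers_lowest_delayed_count(self):
        margins = [0.00, 0.01, 0.02]
        # both steps have ratio 1.0; the first has fewer delayed cases
        assert best_risk_margin(margins, [10, 8, 5], [0, 2, 5]) == 0.01

    def test_flat_delays_signal_no_optimum(self):
        with pytest.raises(NoOptimumError):
            best_risk_margin([0.0, 0.01], [27, 20], [0, 0])


class TestCEAC:
    def test_threshold_zero_is_probability_cheaper(self):
        rng = np.random.default_rng(1)
        draws = np.column_stack([rng.normal(-100, 400, 500), rng.integers(1, 5, 500)])
        prob = ceac(draws, [0.0])[0]
        assert prob == (draws[:, 0] < 0).mean()
        # complement identity when no draw has exactly zero cost difference
        assert prob + (draws[:, 0] > 0).mean() == pytest.approx(1.0)

    def test_large_threshold_is_probability_fewer_delays(self):
        rng = np.random.default_rng(2)
        draws = np.column_stack(
            [rng.normal(0, 100, 500), rng.integers(-3, 4, 500)]
        )
        prob = ceac(draws, [1e12])[0]
        dd, dc = draws[:, 1], draws[:, 0]
        expected = ((dd < 0) | ((dd == 0) & (dc < 0))).mean()
        assert prob == pytest.approx(expected)

    def test_single_atom_step_function(self):
        draws = np.tile([-5000.0, 2.0], (100, 1))  # cheaper, two extra delays
        lam = np.array([0.0, 2499.0, 2500.0, 10_000.0])
        probs = ceac(draws, lam)
        assert np.array_equal(probs, [1.0, 1.0, 0.0, 0.0])

    def test_empty_draws_rejected(self):
        with pytest.raises(ValueError):
            ceac(np.empty((0, 2)), [0.0])


class TestMarginGrid:
    def test_curves_monotone_and_margin_zero_most_expensive(
        self, analysis_cohort, params
    ):
        imputed, onsets_fast, _ = analysis_cohort
        grid = margin_grid_analysis(
            imputed, onsets_fast, default_margin_grid(), EconParams(), params
        )
        assert np.all(np.diff(grid.cost_per_patient) <= 1e-9)
        assert np.all(np.diff(grid.delayed_count) >= 0)
        assert grid.cost_per_patient[0] == grid.cost_per_patient.max()
        assert grid.delayed_count[0] == 0  # 6-month floor cannot overshoot a visit
        assert grid.mean_first_interval[0] == 6.0

    def test_frame_has_incremental_ratios(self, analysis_cohort, params):
        imputed, onsets_fast, _ = analysis_cohort
        grid = margin_grid_analysis(
            imputed, onsets_fast, np.array([0.0, 0.01, 0.02]), EconParams(), params
        )
        df = grid.to_frame()
        assert list(df.columns[:3]) == [
            "risk_margin_pct",
            "cost_per_patient_eur",
            "delayed_count",
        ]
        assert len(df) == 3


@pytest.fixture(scope="module")
def result(analysis_cohort, params):
    imputed, onsets_fast, _ = analysis_cohort
    return bootstrap_two_stage(
        imputed, onsets_fast, B=200, econ=EconParams(), params=params, seed=42,
        margins=default_margin_grid(),
    )


class TestBootstrap:
    def test_fixed_seed_bit_identical(self, analysis_cohort, params, result):
        imputed, onsets_fast, _ = analysis_cohort
        again = bootstrap_two_stage(
            imputed, onsets_fast, B=200, econ=EconParams(), params=params, seed=42,
            margins=default_margin_grid(),
        )
        assert np.array_equal(result.stage1_margins, again.stage1_margins)
        for k in result.total_cost_draws:
            assert np.array_equal(result.total_cost_draws[k], again.total_cost_draws[k])
        for k in result.ceac_curves:
            assert np.array_equal(result.ceac_curves[k], again.ceac_curves[k])

    def test_identity_resample_recovers_full_sample_margin(
        self, analysis_cohort, params
    ):
        imputed, onsets_fast, _ = analysis_cohort
        res = bootstrap_two_stage(
            imputed, onsets_fast, B=1, econ=EconParams(), params=params, seed=0,
            margins=default_margin_grid(), identity_resample=True,
        )
        expected = best_risk_margin(res.point_grid)
        assert res.stage1_margins[0] == expected
        assert res.best_margin_mean == expected

    def test_percentile_ci_contains_point_estimate(self, result):
        grid = result.point_grid
        n = len(grid.matrices.fu_years)
        for (strategy, perspective), draws in result.total_cost_draws.items():
            lo, hi = np.percentile(draws, [2.5, 97.5])
            assert lo <= draws.mean() <= hi
        # healthcare point estimate of the personalised strategy lies inside its CI
        j = int(np.argmin(np.abs(grid.margins - result.margin_star)))
        point = grid.unit_cost * grid.matrices.pers_weight[:, j].sum()
        lo, hi = np.percentile(result.total_cost_draws[("personalised", "healthcare")], [2.5, 97.5])
        assert lo <= point <= hi

    def test_societal_saving_dominates_healthcare(self, result):
        for s in ("personalised", "guideline"):
            d_hc = result.increments[(s, "annual", "healthcare")]
            d_soc = result.increments[(s, "annual", "societal")]
            # both strategies screen less often than annual: every extra cost
            # category makes the societal saving larger in absolute value
            assert np.all(np.abs(d_soc) >= np.abs(d_hc) - 1e-9)

    def test_invalid_b_rejected(self, analysis_cohort, params):
        imputed, onsets_fast, _ = analysis_cohort
        with pytest.raises(ValueError, match="B must be >= 1"):
            bootstrap_two_stage(imputed, onsets_fast, B=0, params=params)


class TestEconConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            EconParams(cost_ranges={"screening": (10.0, 5.0)})
        with pytest.raises(ValueError):
            EconParams(perspective="payer")

    def test_yaml_loading(self, tmp_path):
        path = tmp_path / "econ.yaml"
        path.write_text(
            "cost_ranges:\n  screening: [10, 20]\n  travel: [1, 2]\n"
            "  productivity: [2, 3]\ndiscount_rate_costs: 0.03\nperspective: societal\n"
        )
        econ = econ_params_from_yaml(path)
        assert econ.cost_ranges["screening"] == (10.0, 20.0)
        assert econ.discount_rate_costs == 0.03
        assert econ.perspective == "societal"
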