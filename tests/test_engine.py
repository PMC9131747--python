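import numpy as np
import pytest

from lungcea.engine import (
    CohortSpec,
    CohortTrace,
    ConfigurationError,
    EngineError,
    StrategyOutcome,
    _run_arm,
    accumulate_outcomes,
    default_cohorts,
    discount_factor,
    evaluate_strategies,
    run_chain,
    run_cohort,
    run_strategy,
    single_age_cohorts,
)
from lungcea.fixtures import closed_form_expected_payoff, geometric_chain, make_toy_chain
from lungcea.screening import get_strategy
from lungcea.states import HealthState


class TestDiscountFactor:
    def test_cycle_zero(self):
        assert discount_factor(0, 0.05) == 1.0

    def test_cycle_one(self):
        assert discount_factor(1, 0.05) == pytest.approx(0.9523810, abs=1e-7)

    def test_cycle_ten(self):
        assert discount_factor(10, 0.05) == pytest.approx(0.6139133, abs=1e-7)

    def test_domain(self):
        with pytest.raises(ValueError):
            discount_factor(1, -1.5)
        with pytest.raises(ValueError):
            discount_factor(-1, 0.05)


class TestRunChain:
    def test_geometric_life_years_undiscounted(self):
        chain = geometric_chain(p_death=0.5)
        _, (_, ly, qaly) = run_chain(
            chain.transition, 80, chain.costs, chain.utilities, 0.0
        )
        assert ly == pytest.approx(2.0, abs=1e-10)
        assert qaly == pytest.approx(2.0, abs=1e-10)

    def test_geometric_life_years_discounted(self):
        # sum 0.5^t (1.05)^-t = 1 / (1 - 0.5/1.05)
        chain = geometric_chain(p_death=0.5)
        _, (_, ly, _) = run_chain(
            chain.transition, 200, chain.costs, chain.utilities, 0.05
        )
        assert ly == pytest.approx(1 / (1 - 0.5 / 1.05), abs=1e-10)

    def test_death_monotone(self):
        chain = make_toy_chain(4, seed=3)
        trace, _ = run_chain(chain.transition, 50, chain.costs, chain.utilities)
        assert np.all(np.diff(trace[:, -1]) >= -1e-15)

    def test_matches_fundamental_matrix(self):
        for seed in range(5):
            chain = make_toy_chain(5, seed=seed)
            oracle = closed_form_expected_payoff(chain, 1.0)
            _, (cost, ly, qaly) = run_chain(
                chain.transition, 1200, chain.costs, chain.utilities, 0.0
            )
            assert cost == pytest.approx(oracle["cost"][0], abs=1e-10)
            assert ly == pytest.approx(oracle["life_years"][0], abs=1e-10)
            assert qaly == pytest.approx(oracle["qaly"][0], abs=1e-10)


class TestAccumulateOutcomes:
    def test_flat_utility_counts_cycles(self):
        trace = np.zeros((5, 3))
        trace[:, 0] = 1.0
        cost, ly, qaly = accumulate_outcomes(
            trace, np.zeros(3), np.array([1.0, 1.0, 0.0]), 0.0, death_index=2
        )
        assert qaly == 5.0
        assert ly == 5.0
        assert cost == 0.0

    def test_stage_iv_single_cycle(self, base_params):
        trace = np.zeros((1, 12))
        trace[0, HealthState.STAGE_IV] = 1.0
        _, _, qaly = accumulate_outcomes(
            trace, np.zeros(12), base_params.utility_vector(), 0.0
        )
        assert qaly == 0.75

    def test_missing_state_payoff_rejected(self):
        with pytest.raises(ConfigurationError):
            accumulate_outcomes(np.zeros((2, 12)), np.zeros(5), np.zeros(12))

    def test_effect_discounting_switch(self):
        trace = np.zeros((10, 2))
        trace[:, 0] = 1.0
        _, ly_disc, _ = accumulate_outcomes(
            trace, np.zeros(2), np.ones(2), 0.05, death_index=1
        )
        _, ly_undisc, _ = accumulate_outcomes(
            trace, np.zeros(2), np.ones(2), 0.05, discount_effects=False, death_index=1
        )
        assert ly_undisc == 10.0
        assert ly_disc < 10.0


class TestCohortSpec:
    def test_entry_age_bounds(self):
        with pytest.raises(ConfigurationError):
            CohortSpec(entry_age=45)
        with pytest.raises(ConfigurationError):
            CohortSpec(entry_age=75)

    def test_birth_year(self):
        assert CohortSpec(entry_age=50).birth_year == 1971

    def test_default_population(self):
        cohorts = default_cohorts()
        assert len(cohorts) == 8
        assert sum(c.size for c in cohorts) == 80_000
        assert sorted(c.birth_year for c in cohorts) == [
            1947, 1950, 1954, 1957, 1961, 1964, 1968, 1971,
        ]


class TestCohortTrace:
    def test_mass_drift_rejected(self):
        occ = np.zeros((3, 12))
        occ[:, 0] = 1.0
        occ[2, 0] = 0.5  # loses mass
        with pytest.raises(EngineError, match="drift"):
            CohortTrace(entry_age=60, occupancy=occ)

    def test_death_monotonicity_enforced(self):
        occ = np.zeros((3, 12))
        occ[:, 0] = 1.0
        occ[1, 0], occ[1, 11] = 0.6, 0.4
        occ[2, 0], occ[2, 11] = 0.8, 0.2  # resurrection
        with pytest.raises(EngineError, match="death"):
            CohortTrace(entry_age=60, occupancy=occ)


class TestRunCohort:
    def test_trace_shape_and_start(self, base_params):
        trace, _ = run_cohort(CohortSpec(entry_age=65), get_strategy(0), base_params)
        assert trace.n_cycles == 15  # ages 65..79
        assert trace.occupancy[0, HealthState.NORMAL] == 1.0
        assert trace.occupancy[0, HealthState.DEATH] == 0.0

    def test_mass_conserved(self, base_params):
        trace, _ = run_cohort(CohortSpec(entry_age=50), get_strategy(2), base_params)
        assert np.abs(trace.occupancy.sum(axis=1) - 1.0).max() < 1e-10

    def test_death_final_geq_first(self, base_params):
        trace, _ = run_cohort(CohortSpec(entry_age=50), get_strategy(0), base_params)
        death = trace.occupancy[:, HealthState.DEATH]
        assert death[-1] >= death[1] > 0

    def test_outcome_invariants(self, base_params):
        _, outcome = run_cohort(CohortSpec(entry_age=60), get_strategy(4), base_params)
        assert 0 < outcome.qalys <= outcome.life_years
        assert outcome.cost > 0

    def test_discount_monotonicity(self, params):
        totals = []
        for rate in (0.0, 0.03, 0.05, 0.08):
            params.discount_rate = rate
            _, o = run_cohort(CohortSpec(entry_age=55), get_strategy(0), params)
            totals.append((o.cost, o.life_years, o.qalys))
        for a, b in zip(totals, totals[1:]):
            assert all(x >= y for x, y in zip(a, b))

    def test_null_screening_equals_no_screening(self, params):
        """Zero test costs + zero sensitivity + perfect specificity
        reproduces the unscreened arm exactly."""
        params.cost_ldct = 0.0
        params.sens_ldct = 0.0
        params.spec_ldct = 1.0
        strategy = get_strategy(0)
        rr = strategy.relative_risk(params)
        null = _run_arm(60, "male", rr, strategy, params)
        unscreened = _run_arm(60, "male", rr, None, params)
        assert null.cost == pytest.approx(unscreened.cost, abs=1e-9)
        assert null.qalys == pytest.approx(unscreened.qalys, abs=1e-12)
        np.testing.assert_allclose(null.trace, unscreened.trace, atol=1e-14)

    def test_half_cycle_correction_reduces_totals(self, params):
        _, full = run_cohort(CohortSpec(entry_age=60), get_strategy(0), params)
        params.half_cycle_correction = True
        _, hcc = run_cohort(CohortSpec(entry_age=60), get_strategy(0), params)
        assert hcc.life_years < full.life_years
        assert hcc.qalys < full.qalys

    def test_mixture_weights(self, params):
        """With eligible fraction f, outcomes interpolate the two strata."""
        params.eligible_fraction_30py = 0.3
        strategy = get_strategy(0)
        _, mixed = run_cohort(CohortSpec(entry_age=60), strategy, params)
        elig = _run_arm(60, "male", strategy.relative_risk(params), strategy, params)
        inel = _run_arm(60, "male", 1.0, None, params)
        elig_f = _run_arm(60, "female", strategy.relative_risk(params), strategy, params)
        inel_f = _run_arm(60, "female", 1.0, None, params)
        expected = 0.5 * (0.3 * elig.cost + 0.7 * inel.cost) + 0.5 * (
            0.3 * elig_f.cost + 0.7 * inel_f.cost
        )
        assert mixed.cost == pytest.approx(expected, rel=1e-12)


class TestRunStrategy:
    def test_population_total(self, base_params):
        outcome = run_strategy(get_strategy(0), default_cohorts(), base_params)
        assert outcome.population == 80_000

    def test_single_cohort_identity(self, base_params):
        cohort = CohortSpec(entry_age=65, size=80_000)
        _, alone = run_cohort(cohort, get_strategy(0), base_params)
        aggregated = run_strategy(get_strategy(0), [cohort], base_params)
        assert aggregated.cost == pytest.approx(alone.cost)
        assert aggregated.qalys == pytest.approx(alone.qalys)

    def test_size_linearity(self, base_params):
        small = run_strategy(
            get_strategy(0), [CohortSpec(entry_age=60, size=10_000)], base_params
        )
        big = run_strategy(
            get_strategy(0), [CohortSpec(entry_age=60, size=20_000)], base_params
        )
        assert big.cost == pytest.approx(small.cost)  # per-person unchanged
        assert big.cost_millions == pytest.approx(2 * small.cost_millions)

    def test_overlapping_cohorts_rejected(self, base_params):
        cohorts = [CohortSpec(entry_age=60), CohortSpec(entry_age=60)]
        with pytest.raises(ConfigurationError, match="overlapping"):
            run_strategy(get_strategy(0), cohorts, base_params)

    def test_empty_cohorts_rejected(self, base_params):
        with pytest.raises(ConfigurationError):
            run_strategy(get_strategy(0), [], base_params)

    def test_evaluate_strategies_matches_individual_runs(self, base_params):
        cohorts = single_age_cohorts(60)
        shared = evaluate_strategies(
            [get_strategy(0), get_strategy(6)], cohorts, base_params
        )
        solo = run_strategy(get_strategy(6), cohorts, base_params)
        assert shared[6].cost == pytest.approx(solo.cost, rel=1e-14)
        assert shared[6].qalys == pytest.approx(solo.qalys, rel=1e-14)


class TestStrategyOutcome:
    def test_presentation_units(self):
        o = StrategyOutcome(0, cost=25_000.0, life_years=10.0, qalys=9.5, population=80_000)
        assert o.cost_millions == pytest.approx(2000.0)
        assert o.ly_10k == pytest.approx(80.0)
        assert o.qaly_10k == pytest.approx(76.0)

    def test_qaly_cannot_exceed_ly(self):
        with pytest.raises(EngineError):
            StrategyOutcome(0, cost=0.0, life_years=1.0, qalys=2.0)
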