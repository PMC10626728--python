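"""Cohort propagation, discounting, accrual arithmetic and engine-level
monotonicity properties."""

import dataclasses

import numpy as np
import pytest

import rehabcea as r
from rehabcea.engine import accrual_weights, discounted_state_time

from conftest import make_toy_instance, naive_strategy_outcomes


class TestRunCohort:
    def test_identity_matrix_keeps_occupancy_constant(self, paper_model):
        ch, _, _ = paper_model
        trace = r.run_cohort(r.TransitionMatrix(np.eye(5)), ch.cohort, 120)
        assert np.all(trace.occupancy == ch.cohort.initial_counts)

    def test_two_state_survival_closed_form(self):
        toy = make_toy_instance(survival=0.9, cycles=12)
        trace = r.run_cohort(toy.matrix, toy.cohort, 12)
        assert trace.occupancy[12, 0] == pytest.approx(0.9**12, abs=1e-15)
        assert trace.occupancy[12, 0] == pytest.approx(0.282429536481, abs=1e-12)

    def test_first_cycle_occupancy_matches_hand_arithmetic(self, paper_model):
        """One step of the CH matrix moves 1795*0.981 + 172*0.068 + 280*0.004
        persons into NYHA I."""
        ch, _, _ = paper_model
        trace = r.run_cohort(ch.matrix, ch.cohort, 1)
        expected = 1795 * 0.981 + 172 * 0.068 + 280 * 0.004  # = 1773.711
        assert trace.occupancy[1, 0] == pytest.approx(expected, abs=1e-9)

    def test_conservation_and_death_monotonicity(self):
        for seed in range(8):
            inst, _ = r.random_model_instance(seed=seed)
            trace = r.run_cohort(inst.matrix, inst.cohort, 120)
            sums = trace.occupancy.sum(axis=1)
            np.testing.assert_allclose(sums, inst.cohort.size, atol=1e-9)
            deaths = trace.occupancy[:, r.HealthState.DEATH]
            assert np.all(np.diff(deaths) >= -1e-12)
            assert np.all(trace.occupancy >= -1e-15)

    def test_invalid_matrix_rejected(self, paper_model):
        _, dt, _ = paper_model
        with pytest.raises(ValueError, match="row-stochastic"):
            r.run_cohort(dt.matrix, dt.cohort, 10)  # raw DT rows sum to 0.999/1.001

    def test_zero_cycles_rejected(self, paper_model):
        ch, _, _ = paper_model
        with pytest.raises(ValueError, match="cycles"):
            r.run_cohort(ch.matrix, ch.cohort, 0)


class TestDiscounting:
    def test_first_cycle_undiscounted(self):
        assert r.discount_factor(1, 0.03, 12) == 1.0

    def test_one_year_later_is_one_discount_step(self):
        assert r.discount_factor(13, 0.03, 12) == pytest.approx(1 / 1.03, abs=1e-12)

    def test_zero_rate_is_flat(self):
        assert r.discount_factor(77, 0.0, 12) == 1.0

    def test_errors(self):
        with pytest.raises(ValueError):
            r.discount_factor(0, 0.03, 12)
        with pytest.raises(ValueError):
            r.discount_factor(1, -0.01, 12)

    def test_vector_matches_scalar(self):
        d = r.discount_factors(120, 0.03, 12)
        assert d[0] == 1.0
        assert d[12] == pytest.approx(r.discount_factor(13, 0.03, 12), abs=1e-15)


class TestAccrual:
    def test_ch_nyha1_person_month_cost(self, paper_model):
        """(1012.25 + 45720)/12 + 0.004 * 35587.73 per person-month."""
        ch, _, _ = paper_model
        occ = np.array([1.0, 0, 0, 0, 0])
        expected = (1012.25 + 45_720) / 12 + 0.004 * 35_587.73
        got = r.accrue_cycle_cost(occ, ch.costs, ch.hospitalization)
        assert got == pytest.approx(expected, abs=1e-9)
        assert got == pytest.approx(4036.7051, abs=5e-4)

    def test_dt_nyha1_person_month_cost_includes_dtx_fee(self, paper_model):
        _, dt, _ = paper_model
        occ = np.array([1.0, 0, 0, 0, 0])
        expected = (1012.25 + 45_720 + 180) / 12 + 0.003 * 35_587.73
        got = r.accrue_cycle_cost(occ, dt.costs, dt.hospitalization)
        assert got == pytest.approx(expected, abs=1e-9)

    def test_death_accrues_nothing(self, paper_model):
        ch, _, _ = paper_model
        occ = np.array([0.0, 0, 0, 0, 2315.0])
        assert r.accrue_cycle_cost(occ, ch.costs, ch.hospitalization) == 0.0
        assert r.accrue_cycle_qaly(occ, ch.utilities) == 0.0

    def test_negative_occupancy_rejected(self, paper_model):
        ch, _, _ = paper_model
        with pytest.raises(ValueError, match="negative"):
            r.accrue_cycle_cost(np.array([-1.0, 0, 0, 0, 0]), ch.costs, ch.hospitalization)

    def test_qaly_one_month_in_nyha1(self, paper_model):
        ch, _, _ = paper_model
        occ = np.array([1.0, 0, 0, 0, 0])
        assert r.accrue_cycle_qaly(occ, ch.utilities) == pytest.approx(0.87976 / 12, abs=1e-12)

    def test_year_in_nyha2_without_mortality_or_discounting(self, paper_model):
        ch, _, _ = paper_model
        occ = np.array([0.0, 1.0, 0, 0, 0])
        total = 12 * r.accrue_cycle_qaly(occ, ch.utilities)
        assert total == pytest.approx(0.71178, abs=1e-12)

    def test_out_of_range_utility_rejected(self):
        bad = r.UtilityProfile(np.array([1.5, 0.5, 0.5, 0.5]), np.full(4, 0.01))
        with pytest.raises(ValueError, match="utility"):
            r.accrue_cycle_qaly(np.array([1.0, 0, 0, 0, 0]), bad)


class TestEvaluateStrategy:
    def test_geometric_series_closed_form_undiscounted(self):
        toy = make_toy_instance(survival=0.9, cycles=12, discount_rate=0.0)
        res = r.evaluate_strategy(toy)
        expected = (1 - 0.9**12) / (0.1 * 12)
        assert res.total_discounted_qaly == pytest.approx(expected, abs=1e-12)
        assert res.annualized_qaly == pytest.approx(expected, abs=1e-12)  # 1-year horizon
        assert res.total_discounted_cost == 0.0

    def test_geometric_series_with_discounting(self):
        toy = make_toy_instance(survival=0.9, cycles=24, discount_rate=0.03)
        res = r.evaluate_strategy(toy)
        s, m = 0.9, (1.03) ** (-1 / 12)
        expected = sum(s**t * m**t for t in range(24)) / 12
        assert res.total_discounted_qaly == pytest.approx(expected, abs=1e-12)

    def test_zero_cost_zero_utility_instance(self):
        toy = make_toy_instance(survival=0.9, utility=0.0, cycles=12)
        res = r.evaluate_strategy(toy)
        assert res.total_discounted_cost == 0.0
        assert res.total_discounted_qaly == 0.0

    def test_totals_equal_cycle_sums(self, paper_model):
        ch, dt, _ = paper_model
        for inst in (ch, dt):
            res = r.evaluate_strategy(inst)
            assert res.total_discounted_cost == pytest.approx(res.cycle_costs.sum(), abs=1e-9)
            assert res.total_discounted_qaly == pytest.approx(res.cycle_qalys.sum(), abs=1e-9)

    def test_agrees_with_independent_accrual_implementation(self, paper_model):
        ch, dt, _ = paper_model
        cases = [ch, dt, make_toy_instance(0.85, cycles=24, discount_rate=0.05)]
        cases += [r.random_model_instance(seed=s)[0] for s in (3, 4)]
        half = dataclasses.replace(ch.settings, half_cycle=True)
        cases.append(ch.replace(settings=half))
        for inst in cases:
            res = r.evaluate_strategy(inst)
            cost, qaly = naive_strategy_outcomes(inst)
            assert res.total_discounted_cost == pytest.approx(cost, rel=1e-9)
            assert res.total_discounted_qaly == pytest.approx(qaly, rel=1e-9, abs=1e-12)

    def test_discount_monotonicity(self, paper_model):
        ch, _, _ = paper_model
        prev_cost, prev_qaly = np.inf, np.inf
        for rate in (0.0, 0.03, 0.08):
            res = r.evaluate_strategy(
                ch.replace(settings=dataclasses.replace(ch.settings, annual_discount_rate=rate))
            )
            assert res.total_discounted_cost <= prev_cost
            assert res.total_discounted_qaly <= prev_qaly
            prev_cost, prev_qaly = res.total_discounted_cost, res.total_discounted_qaly

    def test_utility_monotonicity(self, paper_model):
        ch, _, _ = paper_model
        base = r.evaluate_strategy(ch).total_discounted_qaly
        for i in range(4):
            mean = ch.utilities.mean.copy()
            mean[i] = min(1.0, mean[i] + 0.05)
            up = ch.replace(utilities=r.UtilityProfile(mean, ch.utilities.variance))
            assert r.evaluate_strategy(up).total_discounted_qaly >= base

    def test_raising_death_probability_lowers_qalys(self, paper_model):
        ch, _, _ = paper_model
        base = r.evaluate_strategy(ch).total_discounted_qaly
        for i in range(4):
            P = ch.matrix.probs.copy()
            shift = min(0.05, P[i, i])
            P[i, i] -= shift
            P[i, 4] += shift
            worse = ch.replace(matrix=r.TransitionMatrix(P))
            assert r.evaluate_strategy(worse).total_discounted_qaly <= base

    def test_half_cycle_weights_average_start_and_end(self, paper_model):
        ch, _, _ = paper_model
        trace = r.run_cohort(ch.matrix, ch.cohort, 3)
        w = accrual_weights(trace, half_cycle=True)
        np.testing.assert_allclose(w, 0.5 * (trace.occupancy[:-1] + trace.occupancy[1:]))

    def test_state_time_weights_reproduce_totals(self, paper_model):
        """Costs and QALYs are linear functionals of discounted state-time."""
        ch, _, _ = paper_model
        trace = r.run_cohort(ch.matrix, ch.cohort, 120)
        w = discounted_state_time(trace, ch.settings)
        res = r.evaluate_strategy(ch)
        cost = w[:4] @ r.monthly_state_cost(ch.costs, ch.hospitalization)
        qaly = w[:4] @ (ch.utilities.mean / 12)
        assert cost == pytest.approx(res.total_discounted_cost, rel=1e-12)
        assert qaly == pytest.approx(res.total_discounted_qaly, rel=1e-12)

    def test_per_life_year_annualization(self, paper_model):
        ch, _, _ = paper_model
        inst = ch.replace(
            settings=dataclasses.replace(ch.settings, annualization_mode="per_life_year")
        )
        res = r.evaluate_strategy(inst)
        assert res.annualized_cost == pytest.approx(
            res.total_discounted_cost / res.life_years, rel=1e-12
        )
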