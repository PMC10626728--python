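"""Distribution fitting, tornado/two-way analyses, PSA sampling and CEAC."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import rehabcea as r
from rehabcea.engine import discounted_state_time
from rehabcea.sensitivity import _group_bounds, tornado_frame


@pytest.fixture(scope="module")
def fits(paper_model):
    ch, dt, ranges = paper_model
    return r.build_psa_fits(ch, dt, ranges)


class TestGammaFit:
    def test_dtx_fee_method_of_moments(self):
        fit = r.fit_gamma_from_mean_range(180.0, 144.0, 216.0)
        sd = (216.0 - 144.0) / (2 * 1.96)
        assert fit.params["shape"] == pytest.approx(180.0**2 / sd**2, rel=1e-9)
        assert fit.params["shape"] == pytest.approx(96.04, abs=5e-3)
        assert fit.params["scale"] == pytest.approx(sd**2 / 180.0, rel=1e-9)
        assert fit.mean() == pytest.approx(180.0, rel=1e-12)
        assert fit.variance() == pytest.approx(sd**2, rel=1e-9)

    def test_sample_mean_converges(self):
        fit = r.fit_gamma_from_mean_range(180.0, 144.0, 216.0)
        rng = np.random.default_rng(42)
        draws, resampled = fit.sample(rng, 200_000)
        assert resampled == 0
        se = draws.std(ddof=1) / math.sqrt(len(draws))
        assert abs(draws.mean() - 180.0) < 3 * se

    def test_degenerate_range_is_point_mass(self):
        fit = r.fit_gamma_from_mean_range(180.0, 180.0, 180.0)
        assert fit.near_deterministic
        draws, _ = fit.sample(np.random.default_rng(0), 5)
        assert np.all(draws == 180.0)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            r.fit_gamma_from_mean_range(0.0, 1.0, 2.0)


class TestBetaFit:
    def test_symmetric_closed_form(self):
        fit = r.fit_beta_from_mean_variance(0.5, 0.05)
        assert fit.params["a"] == pytest.approx(2.0, rel=1e-12)
        assert fit.params["b"] == pytest.approx(2.0, rel=1e-12)

    def test_nyha1_utility_fit(self):
        m, v = 0.87976, 0.00827
        fit = r.fit_beta_from_mean_variance(m, v)
        c = m * (1 - m) / v - 1
        assert fit.params["a"] == pytest.approx(m * c, rel=1e-12)
        assert fit.params["b"] == pytest.approx((1 - m) * c, rel=1e-12)
        assert fit.params["a"] == pytest.approx(10.37, abs=0.01)
        assert fit.params["b"] == pytest.approx(1.418, abs=0.01)

    @given(
        st.floats(0.05, 0.95),
        st.floats(0.001, 0.2),
    )
    def test_moments_roundtrip(self, mean, variance):
        if variance >= mean * (1 - mean):
            variance = 0.5 * mean * (1 - mean)
        fit = r.fit_beta_from_mean_variance(mean, variance)
        assert fit.mean() == pytest.approx(mean, abs=1e-9)
        assert fit.variance() == pytest.approx(variance, abs=1e-9)

    def test_infeasible_variance_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            r.fit_beta_from_mean_variance(0.5, 0.3)


class TestLognormalFit:
    def test_risk_ratio_fit(self):
        fit = r.fit_lognormal_from_median_range(0.75, 0.36, 0.85)
        assert fit.params["mu"] == pytest.approx(math.log(0.75), rel=1e-12)
        assert fit.params["sigma"] == pytest.approx(math.log(0.85 / 0.36) / (2 * 1.96), rel=1e-12)
        assert fit.median() == pytest.approx(0.75, rel=1e-12)

    def test_sample_median_converges(self):
        fit = r.fit_lognormal_from_median_range(0.75, 0.36, 0.85)
        draws, _ = fit.sample(np.random.default_rng(7), 200_000)
        # asymptotic SE of the median of log-draws
        se = 1.2533 * fit.params["sigma"] / math.sqrt(len(draws))
        assert abs(math.log(np.median(draws)) - fit.params["mu"]) < 3 * se

    def test_nonpositive_bounds_rejected(self):
        with pytest.raises(ValueError):
            r.fit_lognormal_from_median_range(0.75, 0.0, 0.85)


class TestOneWayAndTornado:
    def test_pinning_group_at_base_values_gives_zero_swing(self, paper_model):
        ch, dt, _ = paper_model
        base_vals = ch.costs.indirect_annual
        entry = r.one_way_sensitivity((ch, dt), "indirect", base_vals, base_vals)
        assert entry.swing == pytest.approx(0.0, abs=1e-9)

    def test_dtx_swing_consistent_with_discounted_alive_time(self, paper_model):
        """With fixed effectiveness, moving only the DTx fee shifts the DT
        cost by (fee difference) x discounted alive person-years / 12, so the
        ICER swing is predictable in closed form."""
        ch, dt, _ = paper_model
        entry = r.one_way_sensitivity((ch, dt), "dtx_cost", 144.0, 216.0)
        P = r.normalize_rows(dt.matrix, dt.settings.normalization)
        trace = r.run_cohort(P, dt.cohort, dt.settings.cycles)
        w_alive = discounted_state_time(trace, dt.settings)[:4].sum()
        cea = r.compare_strategies(r.evaluate_strategy(ch), r.evaluate_strategy(dt))
        predicted = (216.0 - 144.0) * w_alive / 12 / dt.settings.horizon_years / cea.delta_qaly
        assert entry.icer_at_high - entry.icer_at_low == pytest.approx(predicted, rel=1e-9)
        # and the bounds bracket the base-case ICER (fee is monotone in cost)
        assert entry.icer_at_low < cea.icer < entry.icer_at_high

    def test_unknown_group_rejected(self, paper_model):
        ch, dt, _ = paper_model
        with pytest.raises(ValueError, match="unknown parameter group"):
            r.one_way_sensitivity((ch, dt), "discount", 0.0, 0.05)

    def test_full_tornado_sorted_with_dtx_smallest(self, paper_model):
        ch, dt, ranges = paper_model
        entries = r.tornado((ch, dt), ranges)
        assert len(entries) == 6
        swings = [e.swing for e in entries]
        assert swings == sorted(swings, reverse=True)
        assert entries[-1].group in ("dtx_cost", "direct_nonmedical")
        assert all(s >= 0 for s in swings)
        frame = tornado_frame(entries)
        assert list(frame.columns) == ["parameter", "icer_at_low", "icer_at_high", "swing"]


class TestTwoWay:
    def test_single_point_grid_at_base_values_is_base_icer(self, paper_model):
        ch, dt, _ = paper_model
        base = r.compare_strategies(r.evaluate_strategy(ch), r.evaluate_strategy(dt)).icer
        grid = r.two_way_sensitivity(
            (ch, dt), "dtx_cost", [180.0], "indirect", [ch.costs.indirect_annual]
        )
        assert grid.shape == (1, 1)
        assert grid[0, 0] == pytest.approx(base, rel=1e-12)

    def test_corners_match_sequential_substitution(self, paper_model):
        ch, dt, ranges = paper_model
        lo1, hi1 = _group_bounds(ranges, "dtx_cost")
        lo2, hi2 = _group_bounds(ranges, "indirect")
        grid = r.two_way_sensitivity((ch, dt), "dtx_cost", [lo1, hi1], "indirect", [lo2, hi2])
        for i, v1 in enumerate((lo1, hi1)):
            for j, v2 in enumerate((lo2, hi2)):
                ch1, dt1 = r.apply_parameter_group(ch, dt, "dtx_cost", v1)
                ch2, dt2 = r.apply_parameter_group(ch1, dt1, "indirect", v2)
                icer = r.compare_strategies(
                    r.evaluate_strategy(ch2), r.evaluate_strategy(dt2)
                ).icer
                assert grid[i, j] == pytest.approx(icer, rel=1e-12)

    def test_icer_monotone_in_dtx_fee(self, paper_model):
        ch, dt, ranges = paper_model
        lo2, hi2 = _group_bounds(ranges, "indirect")
        grid = r.two_way_sensitivity(
            (ch, dt), "dtx_cost", [144.0, 180.0, 216.0], "indirect", [lo2, hi2]
        )
        assert np.all(np.diff(grid, axis=0) > 0)


class TestPSA:
    def test_fixed_seed_is_bit_reproducible(self, paper_model, fits):
        ch, dt, _ = paper_model
        a = r.run_psa((ch, dt), fits, 500, seed=7)
        b = r.run_psa((ch, dt), fits, 500, seed=7)
        assert np.array_equal(a.points, b.points)
        c = r.run_psa((ch, dt), fits, 500, seed=8)
        assert not np.array_equal(a.points, c.points)

    def test_collapsed_single_draw_equals_base_case(self, paper_model, fits):
        ch, dt, _ = paper_model
        psa = r.run_psa((ch, dt), fits, 1, seed=0, collapse=True)
        cea = r.compare_strategies(r.evaluate_strategy(ch), r.evaluate_strategy(dt))
        assert psa.delta_cost[0] == pytest.approx(cea.delta_cost, rel=1e-9)
        assert psa.delta_qaly[0] == pytest.approx(cea.delta_qaly, rel=1e-9)

    def test_utility_draws_respect_envelope(self, paper_model, fits):
        ch, dt, ranges = paper_model
        psa = r.run_psa((ch, dt), fits, 300, seed=3)
        assert fits.utilities[0].support == (0.66, 0.96)  # NYHA I inside envelope
        assert fits.utilities[3].support is None  # NYHA IV mean below envelope
        assert all(v >= 0 for v in psa.resample_counts.values())

    def test_cloud_mean_matches_model_at_distribution_means(self, paper_model):
        """Outcomes are linear in the sampled parameters, so the CE-cloud mean
        converges to the model evaluated at the distribution means (envelope
        truncation off, so beta means equal the base utilities)."""
        ch, dt, ranges = paper_model
        fits0 = r.build_psa_fits(ch, dt, ranges, utility_envelope=False)
        psa = r.run_psa((ch, dt), fits0, 4000, seed=11)
        rr_mean = np.array([f.mean() for f in fits0.hospitalization_rr])
        ch_m, dt_m = r.apply_parameter_group(ch, dt, "hospitalization_rr", rr_mean)
        cea = r.compare_strategies(r.evaluate_strategy(ch_m), r.evaluate_strategy(dt_m))
        se_dc = psa.delta_cost.std(ddof=1) / math.sqrt(psa.n_iterations)
        se_dq = psa.delta_qaly.std(ddof=1) / math.sqrt(psa.n_iterations)
        assert abs(psa.delta_cost.mean() - cea.delta_cost) < 3 * se_dc
        assert abs(psa.delta_qaly.mean() - cea.delta_qaly) < 3 * se_dq

    def test_global_utility_mode_is_comonotone(self, paper_model):
        ch, dt, ranges = paper_model
        fits_g = r.build_psa_fits(ch, dt, ranges, utility_mode="global")
        psa = r.run_psa((ch, dt), fits_g, 200, seed=5)
        assert np.all((psa.qaly_ch > 0) & (psa.qaly_dt > 0))
        # same seed reproducible in this mode too
        psa2 = r.run_psa((ch, dt), fits_g, 200, seed=5)
        assert np.array_equal(psa.points, psa2.points)

    def test_independent_utility_arms_widens_the_qaly_spread(self, paper_model, fits):
        ch, dt, _ = paper_model
        shared = r.run_psa((ch, dt), fits, 2000, seed=9)
        indep = r.run_psa((ch, dt), fits, 2000, seed=9, independent_utility_arms=True)
        assert indep.delta_qaly.std() > 3 * shared.delta_qaly.std()

    def test_bad_iteration_count_rejected(self, paper_model, fits):
        ch, dt, _ = paper_model
        with pytest.raises(ValueError):
            r.run_psa((ch, dt), fits, 0, seed=1)


class TestCEAC:
    def test_endpoint_identities(self, paper_model, fits):
        ch, dt, _ = paper_model
        psa = r.run_psa((ch, dt), fits, 1000, seed=2)
        curve = r.ceac(psa, [0.0, 1e12])
        frac_cheaper = float(np.mean(psa.delta_cost < 0))
        frac_effective = float(np.mean(psa.delta_qaly > 0))
        assert curve[0].probability_cost_effective == pytest.approx(frac_cheaper, abs=1e-12)
        assert curve[1].probability_cost_effective == pytest.approx(frac_effective, abs=1e-12)

    def test_probabilities_bounded(self, paper_model, fits):
        ch, dt, _ = paper_model
        psa = r.run_psa((ch, dt), fits, 500, seed=4)
        curve = r.ceac(psa, r.default_wtp_grid(100_000, 10_000))
        probs = [p.probability_cost_effective for p in curve]
        assert all(0.0 <= p <= 1.0 for p in probs)

    def test_empty_points_rejected(self):
        with pytest.raises(ValueError):
            r.ceac(np.empty((0, 2)), [0.0])

    def test_default_grid_covers_both_thresholds(self):
        grid = r.default_wtp_grid()
        assert grid[0] == 0.0
        assert grid[-1] == 300_000.0
        assert 85_698 < grid[-1] and 257_094 < grid[-1]
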