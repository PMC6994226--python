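import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from edpelt import (
    EmpiricalDistributionCost,
    LinearTrendCost,
    NMCDCost,
    TimeSeries,
    build_quantile_grid,
    default_K,
    ed_segment_cost,
    empirical_cdf,
    linear_trend_cost,
    nmcd_segment_cost,
    segment_loglik,
)

from helpers import brute_ed_cost, brute_nmcd_cost


class TestEmpiricalCdf:
    @pytest.mark.parametrize(
        "values,t,expected",
        [
            ([1, 2, 3], 10, 1.0),  # all values below t
            ([5], 5, 0.5),  # a tie contributes weight 0.5
            ([1, 2, 2, 4], 2, 0.5),  # (1 + 0.5*2)/4
            ([1, 2, 3], -10, 0.0),
        ],
    )
    def test_hand_values(self, values, t, expected):
        assert empirical_cdf(values, t) == pytest.approx(expected)

    def test_empty_segment_rejected(self):
        with pytest.raises(ValueError):
            empirical_cdf([], 1.0)

    @given(
        st.lists(st.floats(-50, 50), min_size=1, max_size=30),
        st.floats(-60, 60),
    )
    def test_bounded_and_monotone_in_t(self, values, t):
        F = empirical_cdf(values, t)
        assert 0.0 <= F <= 1.0
        assert empirical_cdf(values, t + 1.0) >= F


class TestSegmentLoglik:
    @pytest.mark.parametrize(
        "F,length,expected",
        [
            (0.0, 7, 0.0),  # 0 log 0 convention
            (1.0, 3, 0.0),
            (0.5, 2, 2 * math.log(0.5)),
        ],
    )
    def test_hand_values(self, F, length, expected):
        assert segment_loglik(F, length) == pytest.approx(expected)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            segment_loglik(1.2, 3)
        with pytest.raises(ValueError):
            segment_loglik(-0.1, 3)

    @given(st.floats(0, 1), st.integers(1, 100))
    def test_nonpositive(self, F, length):
        assert segment_loglik(F, length) <= 0.0


class TestQuantileGrid:
    def test_constant_c(self, rng):
        grid = build_quantile_grid(rng.normal(size=1000), 10)
        assert grid.c == pytest.approx(-math.log(1999))
        assert grid.c == pytest.approx(-7.600402, abs=1e-6)

    @pytest.mark.parametrize("n,K", [(50, 7), (200, 21), (1000, 28)])
    def test_probability_symmetry_and_monotonicity(self, rng, n, K):
        grid = build_quantile_grid(rng.normal(size=n), K)
        assert np.all(np.diff(grid.p) > 0)
        np.testing.assert_allclose(grid.p + grid.p[::-1], 1.0, atol=1e-12)
        assert np.all((grid.z > -1) & (grid.z < 1))

    def test_tail_probabilities_approach_extremes(self, rng):
        n = 500
        grid = build_quantile_grid(rng.normal(size=n), 4 * n)
        assert grid.p[0] >= (1 / (2 * n)) * (1 - 1e-6)
        assert grid.p[0] == pytest.approx(1 / (2 * n), rel=0.05)
        assert grid.p[-1] == pytest.approx((2 * n - 1) / (2 * n), rel=0.05)

    def test_prefix_tables_bounded(self, rng):
        grid = build_quantile_grid(rng.normal(size=60), 9)
        tot = grid.prefix_lt + grid.prefix_eq
        assert np.all(tot <= np.arange(61)[None, :])

    def test_prefix_cdf_matches_raw_recomputation_exhaustively(self, rng):
        x = np.round(rng.normal(size=40), 1)  # rounding forces ties
        grid = build_quantile_grid(x, 11)
        for u in range(40):
            for v in range(u + 1, 41):
                expected = [empirical_cdf(x[u:v], t) for t in grid.t]
                np.testing.assert_allclose(grid.cdf(u, v), expected, atol=1e-12)

    def test_invalid_K(self, rng):
        with pytest.raises(ValueError):
            build_quantile_grid(rng.normal(size=20), 0)


class TestDefaultK:
    @pytest.mark.parametrize(
        "n,expected",
        [(100, 19), (500, 25), (1000, 28), (2000, 31), (5000, 35), (10000, 37)],
    )
    def test_reference_values(self, n, expected):
        assert default_K(n) == expected


class TestEdSegmentCost:
    def test_degenerate_segment_costs_zero(self, rng):
        # values of this segment all exceed every evaluation point -> F=0
        x = np.concatenate([rng.uniform(0, 1, 95), rng.uniform(100, 101, 5)])
        grid = build_quantile_grid(x, 2)  # few quantiles: all below 100
        assert np.all(grid.t < 100)
        assert ed_segment_cost(grid, 95, 100) == pytest.approx(0.0, abs=1e-12)

    def test_matches_bruteforce_recomputation(self, rng):
        x = rng.normal(size=80)
        grid = build_quantile_grid(x, 17)
        for u, v in [(0, 10), (5, 15), (30, 80), (0, 80), (77, 80)]:
            assert ed_segment_cost(grid, u, v) == pytest.approx(
                brute_ed_cost(x, u, v, 17), rel=1e-10
            )

    def test_batch_equals_scalar(self, rng):
        model = EmpiricalDistributionCost(rng.normal(size=100), K=15)
        us = np.array([0, 3, 40, 98])
        np.testing.assert_allclose(
            model.cost_batch(us, 99),
            [model.cost(int(u), 99) for u in us],
            rtol=1e-12,
        )

    def test_bounds_errors(self, rng):
        grid = build_quantile_grid(rng.normal(size=20), 5)
        for u, v in [(-1, 5), (5, 5), (10, 25)]:
            with pytest.raises(IndexError):
                ed_segment_cost(grid, u, v)

    def test_superadditivity_on_random_triples(self, rng):
        x = np.concatenate([rng.normal(size=150), rng.normal(3, 2, size=150)])
        model = EmpiricalDistributionCost(x, K=21)
        for _ in range(300):
            u, v, T = np.sort(rng.choice(301, size=3, replace=False))
            if u == v or v == T:
                continue
            whole = model.cost(u, T)
            assert whole >= model.cost(u, v) + model.cost(v, T) - 1e-9
            assert whole >= -1e-12

    def test_stabilises_for_large_K(self, rng):
        # once K reaches a multiple of the sample size the cost settles:
        # successive doublings of K change it by < 0.2% (relative)
        x = rng.normal(size=30)
        vals = [
            ed_segment_cost(build_quantile_grid(x, m * 30), 5, 25)
            for m in (8, 16, 32, 64)
        ]
        rel_steps = np.abs(np.diff(vals)) / np.abs(vals[-1])
        assert np.all(rel_steps < 2e-3)


class TestNmcdCost:
    def test_matches_double_loop_on_all_segments(self, rng):
        x = rng.normal(size=6)
        for u in range(6):
            for v in range(u + 1, 7):
                assert nmcd_segment_cost(x, u, v) == pytest.approx(
                    brute_nmcd_cost(x, u, v), rel=1e-10
                )

    def test_low_extreme_segment_has_vanishing_low_order_terms(self):
        # identical segment values at the extreme low end: order statistics
        # below the segment minimum contribute nothing, so the only
        # nonzero terms come from the two tied order statistics themselves
        x = np.array([-5.0, -5.0, 1.0, 2.0, 3.0, 4.0])
        cost = nmcd_segment_cost(x, 0, 2)
        n = 6
        # terms t=1,2 are the tied -5 values (F=0.5 within the segment);
        # terms t=3..6 have F=1 and vanish
        expected = sum(
            n * 2 * math.log(2) / ((t - 0.5) * (n - t + 0.5)) for t in (1, 2)
        )
        assert cost == pytest.approx(expected, rel=1e-10)

    def test_superadditivity_on_random_triples(self, rng):
        x = rng.standard_t(3, size=120)
        model = NMCDCost(x)
        for _ in range(300):
            u, v, T = np.sort(rng.choice(121, size=3, replace=False))
            if u == v or v == T:
                continue
            assert model.cost(u, T) >= model.cost(u, v) + model.cost(v, T) - 1e-9


class TestLinearTrendCost:
    def test_perfect_line_costs_zero(self):
        i = np.arange(1, 21)
        assert linear_trend_cost(3.0 + 2.0 * i, 0, 20) == pytest.approx(0.0, abs=1e-9)
        assert linear_trend_cost(3.0 + 2.0 * i, 4, 12) == pytest.approx(0.0, abs=1e-9)

    def test_matches_ols_oracle(self, rng):
        y = np.array([0.0, 1.0, 2.0, 4.0])
        i = np.arange(1, 5)
        slope, intercept = np.polyfit(i, y, 1)
        rss = np.sum((y - intercept - slope * i) ** 2)
        assert linear_trend_cost(y, 0, 4) == pytest.approx(rss, rel=1e-10)

        x = rng.normal(size=50)
        model = LinearTrendCost(x)
        for u, v in [(0, 50), (3, 9), (20, 45)]:
            i = np.arange(u + 1, v + 1)
            slope, intercept = np.polyfit(i, x[u:v], 1)
            rss = np.sum((x[u:v] - intercept - slope * i) ** 2)
            assert model.cost(u, v) == pytest.approx(rss, rel=1e-8, abs=1e-10)

    def test_invariant_to_global_linear_trend(self, rng):
        x = rng.normal(size=40)
        i = np.arange(1, 41)
        shifted = x + 7.5 - 0.3 * i
        assert linear_trend_cost(x, 5, 30) == pytest.approx(
            linear_trend_cost(shifted, 5, 30), abs=1e-8
        )

    def test_short_segment_rejected(self, rng):
        with pytest.raises(ValueError):
            linear_trend_cost(rng.normal(size=10), 4, 5)


class TestTimeSeries:
    def test_rejects_nan_and_short(self):
        with pytest.raises(ValueError):
            TimeSeries(np.array([1.0, np.nan]))
        with pytest.raises(ValueError):
            TimeSeries(np.array([1.0]))
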