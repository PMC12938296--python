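"""CV, candidate trend models, the Pettitt test, and the decision cascade."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecovuln.synthetic import generate_vi_series
from ecovuln.trend import (
    ABRUPT,
    LINEAR_DECREASE,
    LINEAR_INCREASE,
    NO_TREND,
    PATTERN_DI,
    PATTERN_ID,
    bin_turning_years,
    classify_trend,
    coefficient_of_variation,
    fit_linear,
    fit_piecewise,
    pettitt_test,
)


def _brute_force_pettitt(x):
    n = len(x)
    u = []
    for t in range(n - 1):
        u.append(sum(np.sign(x[j] - x[i]) for i in range(t + 1) for j in range(t + 1, n)))
    u = np.array(u, dtype=float)
    return float(np.max(np.abs(u))), int(np.argmax(np.abs(u)))


class TestCV:
    def test_constant_series(self):
        cv, b = coefficient_of_variation(np.full(10, 2.0))
        assert cv == 0.0 and b == "<20"

    def test_hand_computed_example(self):
        cv, b = coefficient_of_variation(np.array([1.0, 1.0, 1.0, 3.0]))
        assert cv == pytest.approx(100.0 / 1.5)  # sample sd 1, mean 1.5
        assert b == ">30"

    def test_matches_two_pass_oracle(self, rng):
        x = rng.uniform(0.5, 2.0, 36)
        cv, _ = coefficient_of_variation(x)
        mean = sum(x) / len(x)
        sd = np.sqrt(sum((v - mean) ** 2 for v in x) / (len(x) - 1))
        assert cv == pytest.approx(100 * sd / mean)

    def test_zero_mean_flagged(self):
        cv, b = coefficient_of_variation(np.zeros(10))
        assert b == "invalid" and np.isnan(cv)

    @pytest.mark.parametrize("cv_val,expected", [(19.9, "<20"), (20.1, "20-30"),
                                                 (29.9, "20-30"), (30.1, ">30")])
    def test_bin_edges(self, cv_val, expected):
        # Two-point series with (up to round-off) the requested CV.
        mean = 1.0
        sd = cv_val / 100.0
        x = np.array([mean - sd / np.sqrt(2), mean + sd / np.sqrt(2)])
        cv, b = coefficient_of_variation(x)
        assert cv == pytest.approx(cv_val)
        assert b == expected


class TestFitLinear:
    def test_exact_line(self):
        y = 0.01 * np.arange(36) + 2.0
        res = fit_linear(y)
        assert res["slope"] == pytest.approx(0.01)
        assert res["p_value"] < 1e-10

    def test_type_one_error_near_nominal(self):
        rng = np.random.default_rng(0)
        rejections = sum(
            fit_linear(rng.standard_normal(36))["p_value"] < 0.05 for _ in range(1000)
        )
        assert 30 <= rejections <= 70  # binomial around 50

    def test_aic_matches_independent_formula(self, rng):
        y = rng.standard_normal(20)
        res = fit_linear(y)
        x = np.arange(20.0)
        slope, intercept = np.polyfit(x, y, 1)
        rss = np.sum((y - slope * x - intercept) ** 2)
        assert res["aic"] == pytest.approx(20 * np.log(rss / 20) + 6)

    def test_zero_variance_series(self):
        res = fit_linear(np.full(12, 3.0))
        assert res["slope"] == 0.0 and res["p_value"] == 1.0


class TestFitPiecewise:
    def test_noise_free_v_recovers_break_exactly(self):
        _, y, truth = generate_vi_series(("piecewise", 20, -0.02, 0.02), 36, 1e-15, seed=0)
        res = fit_piecewise(y)
        assert res["break_index"] == 20
        assert res["slopes"][0] == pytest.approx(-0.02, abs=1e-6)
        assert res["slopes"][1] == pytest.approx(0.02, abs=1e-6)

    def test_break_recovery_rate_under_noise(self):
        hits = 0
        for i in range(200):
            _, y, truth = generate_vi_series(("piecewise", 20, -0.02, 0.02), 36, 0.04, seed=i)
            res = fit_piecewise(y)
            hits += abs(res["break_index"] - 20) <= 2
        assert hits >= 180

    def test_search_is_exhaustive_minimum(self, rng):
        y = rng.standard_normal(24)
        res = fit_piecewise(y, min_segment=5)
        x = np.arange(24.0)
        for k in range(4, 19):
            X = np.column_stack([np.ones(24), x, np.maximum(x - x[k], 0)])
            coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
            rss = np.sum((y - X @ coef) ** 2)
            assert res["rss"] <= rss + 1e-9

    def test_short_series_unavailable(self):
        assert fit_piecewise(np.arange(8.0))["available"] is False


class TestPettitt:
    def test_matches_brute_force_for_small_n(self, rng):
        for _ in range(200):
            n = rng.integers(8, 13)
            x = rng.standard_normal(n)
            res = pettitt_test(x)
            k_bf, idx_bf = _brute_force_pettitt(x)
            assert res["k_statistic"] == k_bf
            assert res["change_index"] == idx_bf

    def test_null_calibration(self):
        rng = np.random.default_rng(1)
        rej = sum(pettitt_test(rng.standard_normal(36))["p_value"] < 0.05
                  for _ in range(1000))
        assert 30 <= rej <= 70

    def test_constant_series_is_null(self):
        res = pettitt_test(np.full(12, 1.5))
        assert res["k_statistic"] == 0.0 and res["p_value"] == 1.0

    def test_step_series_detected(self):
        x = np.r_[np.zeros(10), np.ones(10)] + np.random.default_rng(3).normal(0, 0.05, 20)
        res = pettitt_test(x)
        assert res["change_index"] == 9
        assert res["p_value"] < 0.01


class TestClassify:
    def test_noise_free_v_is_abrupt_di(self):
        _, y, _ = generate_vi_series(("piecewise", 20, -0.02, 0.02), 36, 1e-12, seed=0)
        c = classify_trend(y, 1985, 2020)
        assert c.trend_type == ABRUPT
        assert c.turning_pattern == PATTERN_DI
        assert c.turning_year == 2005

    def test_v_shape_recovery_rates(self):
        detected, within2, di = 0, 0, 0
        for i in range(200):
            _, y, truth = generate_vi_series(("piecewise", 20, -0.02, 0.02), 36, 0.04, seed=i)
            c = classify_trend(y, 1985, 2020)
            if c.trend_type == ABRUPT:
                detected += 1
                within2 += abs(c.turning_year - truth["break_year"]) <= 2
                di += c.turning_pattern == PATTERN_DI
        assert within2 >= 0.9 * 200
        assert di >= 0.95 * detected

    def test_linear_series_not_called_abrupt(self):
        linear = 0
        for i in range(200):
            _, y, _ = generate_vi_series(("linear", 0.02), 36, 0.07, seed=i)
            c = classify_trend(y, 1985, 2020)
            linear += c.trend_type == LINEAR_INCREASE
        assert linear >= 160

    def test_pure_noise_mostly_no_trend(self):
        none = 0
        for i in range(200):
            _, y, _ = generate_vi_series(("none",), 36, 0.05, seed=i)
            c = classify_trend(y, 1985, 2020)
            none += c.trend_type == NO_TREND
        assert none >= 180

    @pytest.mark.parametrize("break_index", [2, 33])
    def test_boundary_breaks_never_abrupt(self, break_index):
        for i in range(100):
            _, y, _ = generate_vi_series(
                ("piecewise", break_index, -0.02, 0.02), 36, 0.04, seed=i)
            c = classify_trend(y, 1985, 2020)
            assert c.trend_type in (NO_TREND, LINEAR_INCREASE, LINEAR_DECREASE)

    def test_decreasing_line_labeled_decrease(self):
        _, y, _ = generate_vi_series(("linear", -0.02), 36, 0.03, seed=5)
        c = classify_trend(y, 1985, 2020)
        assert c.trend_type == LINEAR_DECREASE

    @settings(deadline=None, max_examples=50)
    @given(st.integers(0, 2**31 - 1))
    def test_every_series_gets_exactly_one_type(self, seed):
        rng = np.random.default_rng(seed)
        y = np.abs(rng.standard_normal(36).cumsum() / 6 + 5)
        c = classify_trend(y, 1985, 2020)
        assert c.trend_type in (NO_TREND, LINEAR_INCREASE, LINEAR_DECREASE, ABRUPT)
        assert (c.turning_year is not None) == (c.trend_type == ABRUPT)


class TestBinTurningYears:
    def _abrupt(self, year):
        from ecovuln.trend import TrendClassification

        return TrendClassification(0, 10.0, "<20", ABRUPT,
                                   turning_pattern=PATTERN_DI, turning_year=year)

    def test_empty_when_no_abrupt(self):
        t = bin_turning_years([])
        assert t["count"].sum() == 0

    def test_cluster_in_final_bin(self):
        cs = [self._abrupt(y) for y in (2011, 2012, 2014)]
        t = bin_turning_years(cs)
        assert t.loc[t["bin"] == "2010-2015", "count"].item() == 3

    def test_totals_match_brute_force_histogram(self, rng):
        years = rng.integers(1991, 2016, 50)
        cs = [self._abrupt(int(y)) for y in years]
        t = bin_turning_years(cs)
        edges = [1990, 1995, 2000, 2005, 2010, 2015]
        brute = [sum(1 for y in years if e1 <= y < e2) for e1, e2 in zip(edges, edges[1:])]
        brute[-1] = sum(1 for y in years if 2010 <= y <= 2015)
        assert t["count"].to_numpy().tolist() == brute
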