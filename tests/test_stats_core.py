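import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ferrolux.stats_core import (
    FitFailureError,
    InvalidInputError,
    RangedMajorAxis,
    anova_tukey,
    fit_tanh_response,
    rma_regression,
    rolling_mean,
    ttest_unpaired,
)
from oracles import (
    oneway_anova_oracle,
    rma_oracle,
    tukey_reject_oracle,
    welch_ttest_oracle,
)


class TestRangedMajorAxis:
    def test_collinear_exact(self):
        res = rma_regression([1, 2, 3, 4], [3, 5, 7, 9], n_boot=99)
        assert res.slope == pytest.approx(2.0, abs=1e-12)
        assert res.intercept == pytest.approx(1.0, abs=1e-12)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_collinear_axis_interchange(self):
        res = rma_regression([3, 5, 7, 9], [1, 2, 3, 4], n_boot=99)
        assert res.slope == pytest.approx(0.5, abs=1e-12)

    def test_collinear_matches_ols(self):
        # on exactly collinear points every slope estimator coincides
        x = np.array([0.0, 1.0, 2.5, 4.0, 7.0])
        y = -1.3 * x + 0.4
        res = rma_regression(x, y, n_boot=0)
        ols = np.polyfit(x, y, 1)[0]
        assert res.slope == pytest.approx(ols, rel=1e-12)

    def test_matches_eigen_oracle(self, rng):
        for _ in range(100):
            n = rng.integers(5, 30)
            x = rng.normal(size=n)
            y = 0.7 * x + rng.normal(scale=0.5, size=n)
            res = rma_regression(x, y, n_boot=0)
            slope, intercept = rma_oracle(x, y)
            assert res.slope == pytest.approx(slope, rel=1e-8)
            assert res.intercept == pytest.approx(intercept, rel=1e-6, abs=1e-8)

    @given(c=st.floats(min_value=0.1, max_value=50.0))
    @settings(max_examples=25, deadline=None)
    def test_scale_equivariance(self, c):
        rng = np.random.default_rng(7)
        x = rng.normal(size=40)
        y = 1.5 * x + rng.normal(scale=0.3, size=40)
        base = rma_regression(x, y, n_boot=0).slope
        scaled = rma_regression(x, c * y, n_boot=0).slope
        assert scaled == pytest.approx(c * base, rel=1e-10)

    def test_ci_brackets_estimate_and_p_value(self, rng):
        x = rng.normal(size=60)
        y = 0.4 * x + rng.normal(scale=0.4, size=60)
        res = rma_regression(x, y, seed=3, n_boot=499)
        assert res.slope_ci_low <= res.slope <= res.slope_ci_high
        assert 0 < res.p_value <= 1
        perm = rma_regression(x, y, seed=3, n_boot=0, n_permutations=499)
        # permutation and parametric association tests agree on strength
        assert perm.p_value < 0.01 and res.p_value < 0.01

    @pytest.mark.parametrize(
        "x, y, msg",
        [
            ([1, 2, 3], [1, 2], "length"),
            ([1, 2], [3, 4], "3 finite pairs"),
            ([1, 1, 1], [1, 2, 3], "zero range"),
            ([1, 2, 3], [5, 5, 5], "zero range"),
        ],
    )
    def test_invalid_inputs(self, x, y, msg):
        with pytest.raises(InvalidInputError, match=msg):
            rma_regression(x, y)

    def test_bootstrap_coverage_on_simulated_slope(self):
        # weak slope 0.05 with Gaussian noise on BOTH variables, error
        # SDs proportional to each variable's range (the error structure
        # a ranged type II estimator assumes): the nominal 95% interval
        # should cover the truth in at least 90% of simulations
        truth = 0.05
        hits = 0
        n_rep = 500
        master = np.random.default_rng(2024)
        for i in range(n_rep):
            signal = master.normal(size=200)
            x = signal + master.normal(scale=0.2, size=200)
            y = truth * signal + master.normal(scale=truth * 0.2, size=200)
            res = RangedMajorAxis(y, x).fit(n_boot=499, seed=i)
            hits += res.slope_ci_low <= truth <= res.slope_ci_high
        assert hits / n_rep >= 0.90


class TestTanhResponse:
    def test_noiseless_recovery(self):
        par = np.linspace(0.0, 2000.0, 60)
        a, b = 0.6, 0.004
        y = a * np.tanh(b * par / a)
        fit = fit_tanh_response(par, y)
        assert fit.a == pytest.approx(a, rel=1e-6)
        assert fit.b == pytest.approx(b, rel=1e-6)
        assert fit.residual_rms < 1e-10

    def test_plateau_limit_and_origin(self):
        par = np.linspace(500.0, 2000.0, 30)
        y0 = 0.42
        fit = fit_tanh_response(par, np.full_like(par, y0) * np.tanh(par / 50))
        assert fit.a == pytest.approx(y0, rel=1e-3)
        assert fit.predict(0.0) == pytest.approx(0.0, abs=1e-12)

    def test_constant_response_flagged_degenerate(self):
        par = np.linspace(0.0, 2000.0, 20)
        fit = fit_tanh_response(par, np.full_like(par, 0.3))
        assert fit.degenerate
        assert fit.a == pytest.approx(0.3)

    def test_too_few_points(self):
        with pytest.raises(InvalidInputError):
            fit_tanh_response([0, 500, 1000], [0, 0.3, 0.4])

    def test_unbiased_under_noise(self):
        # 5% multiplicative noise, many seeds: mean estimates hit the
        # generating parameters within Monte-Carlo error
        par = np.linspace(0.0, 2000.0, 50)
        a, b = 0.6, 0.004
        clean = a * np.tanh(b * par / a)
        estimates = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            y = clean * (1.0 + rng.normal(0.0, 0.05, size=par.size))
            fit = fit_tanh_response(par, y)
            estimates.append((fit.a, fit.b))
        means = np.mean(estimates, axis=0)
        sems = np.std(estimates, axis=0, ddof=1) / np.sqrt(len(estimates))
        assert abs(means[0] - a) < 4 * sems[0] + 0.01 * a
        assert abs(means[1] - b) < 4 * sems[1] + 0.01 * b


class TestAnovaTukey:
    def test_identical_groups(self):
        res = anova_tukey({"a": [1, 1, 1], "b": [1, 1, 1], "c": [1, 1, 1]})
        assert res.f_statistic == 0.0
        assert not res.pairs["reject"].any()

    def test_two_groups_f_equals_t_squared(self):
        x, y = [1.0, 2.0, 3.0], [2.5, 3.5, 4.5]
        res = anova_tukey({"a": x, "b": y})
        t, p = ttest_unpaired(x, y, equal_var=True)
        assert res.f_statistic == pytest.approx(t**2, rel=1e-10)
        assert res.p_value == pytest.approx(p, rel=1e-10)

    def test_three_group_textbook_oracle(self):
        groups = {
            "control": [0.20, 0.22, 0.19],
            "fe": [0.40, 0.44, 0.41],
            "n": [0.21, 0.24, 0.20],
        }
        f, p = oneway_anova_oracle(groups)
        res = anova_tukey(groups)
        assert res.f_statistic == pytest.approx(f, rel=1e-10)
        assert res.p_value == pytest.approx(p, rel=1e-10)
        expected = tukey_reject_oracle(groups)
        got = {
            tuple(sorted((r["group1"], r["group2"]))): r["reject"]
            for _, r in res.pairs.iterrows()
        }
        for pair, reject in expected.items():
            assert got[tuple(sorted(pair))] == reject

    def test_small_group_rejected(self):
        with pytest.raises(InvalidInputError):
            anova_tukey({"a": [1.0], "b": [1.0, 2.0]})


class TestTTest:
    def test_identical_samples_p_one(self):
        assert ttest_unpaired([2.0, 2.0, 2.0], [2.0, 2.0]) == (0.0, 1.0)

    def test_large_shift_significant(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0.0, 0.1, 20)
        y = rng.normal(10.0, 0.1, 20)
        _, p = ttest_unpaired(x, y)
        assert p < 1e-6

    def test_matches_welch_oracle(self, rng):
        x = rng.normal(0.0, 1.0, 12)
        y = rng.normal(0.5, 2.0, 9)
        t, p = ttest_unpaired(x, y)
        t0, p0 = welch_ttest_oracle(x, y)
        assert t == pytest.approx(t0, rel=1e-12)
        assert p == pytest.approx(p0, rel=1e-12)


class TestRollingMean:
    def _times(self, n, step_min=1):
        return pd.date_range("2020-01-01", periods=n, freq=f"{step_min}min")

    def test_constant_unchanged(self):
        t = self._times(30)
        out = rolling_mean(t, np.full(30, 3.3), window=17)
        assert np.allclose(out, 3.3)

    def test_single_point(self):
        out = rolling_mean(self._times(1), [5.0], window=25)
        assert out[0] == 5.0

    def test_linear_ramp_interior_unchanged(self):
        t = self._times(61)
        vals = np.arange(61, dtype=float)
        out = rolling_mean(t, vals, window=10)
        # centred symmetric window leaves a linear ramp untouched away
        # from the edges
        assert np.allclose(out[10:-10], vals[10:-10])

    def test_nan_ignored(self):
        t = self._times(5)
        vals = np.array([1.0, np.nan, 3.0, np.nan, 5.0])
        out = rolling_mean(t, vals, window=2)
        assert np.allclose(out, [1.0, 2.0, 3.0, 4.0, 5.0])

    def test_non_monotone_rejected(self):
        t = pd.DatetimeIndex(["2020-01-02", "2020-01-01", "2020-01-03"])
        with pytest.raises(InvalidInputError):
            rolling_mean(t, [1.0, 2.0, 3.0], window=60)
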