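"""Least-squares core, parallelism test and calibration metrics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize

from cdpreform import (
    DegenerateInputError,
    calibrate,
    fit_line,
    parallelism_test,
)


class TestFitLine:
    def test_exact_collinear_points(self):
        fit = fit_line([(0, 1), (1, 3), (2, 5)])
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.r == pytest.approx(1.0)
        assert fit.residual_ss == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_three_points(self):
        # symmetric tent data: zero slope, intercept = mean = 1/3
        fit = fit_line([(0, 0), (1, 1), (2, 0)])
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert fit.intercept == pytest.approx(1.0 / 3.0)

    def test_two_points_exact(self):
        fit = fit_line([(0, 0), (1, 5)])
        assert fit.slope == pytest.approx(5.0)
        assert fit.slope_se == 0.0 and fit.intercept_se == 0.0
        assert fit.residual_ss == 0.0

    def test_single_x_value_degenerate(self):
        with pytest.raises(DegenerateInputError, match="x"):
            fit_line([(1.0, 0.0), (1.0, 2.0), (1.0, 4.0)])

    def test_r_squared_matches_explained_variance(self, rng):
        x = rng.uniform(0, 10, 20)
        y = 2.5 * x - 1 + rng.normal(0, 1, 20)
        fit = fit_line(list(zip(x, y)))
        ss_tot = np.sum((y - y.mean()) ** 2)
        assert fit.r**2 == pytest.approx(1 - fit.residual_ss / ss_tot, rel=1e-9)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_ols_parity_with_numeric_minimizer(self, seed):
        """OLS solution agrees with direct numeric minimization of squared error."""
        r = np.random.default_rng(seed)
        n = int(r.integers(3, 12))
        x = r.uniform(-5, 5, n)
        x[1] = x[0] + 1.0  # guarantee two distinct x
        y = r.uniform(-5, 5, n)
        fit = fit_line(list(zip(x, y)))

        def sse(p):
            return float(np.sum((y - p[0] * x - p[1]) ** 2))

        res = minimize(sse, x0=[0.0, 0.0], method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 20_000})
        assert fit.slope == pytest.approx(res.x[0], rel=1e-6, abs=1e-6)
        assert fit.intercept == pytest.approx(res.x[1], rel=1e-6, abs=1e-6)
        assert fit.residual_ss <= sse(res.x) + 1e-9


class TestParallelism:
    NOISY = [(0, 0.1), (1, 0.9), (2, 2.2), (3, 2.9)]

    def test_series_vs_itself(self):
        res = parallelism_test(self.NOISY, self.NOISY)
        assert res.t0 == 0.0
        assert not res.significant
        assert res.df == 4

    def test_zero_residual_slopes_differ(self):
        a = [(t, -0.001 * t + 1) for t in range(5)]
        b = [(t, -0.002 * t + 1) for t in range(5)]
        res = parallelism_test(a, b)
        assert res.exact_separation
        assert res.significant
        assert math.isinf(res.t0) and res.t0 > 0  # a1 - a2 = +0.001

    def test_antisymmetric_in_arguments(self, rng):
        a = [(t, 2 * t + rng.normal()) for t in range(6)]
        b = [(t, 3 * t + rng.normal()) for t in range(6)]
        res_ab = parallelism_test(a, b)
        res_ba = parallelism_test(b, a)
        assert res_ab.t0 == pytest.approx(-res_ba.t0, rel=1e-12)
        assert res_ab.significant == res_ba.significant

    def test_insufficient_df(self):
        two = [(0, 0), (1, 1)]
        with pytest.raises(DegenerateInputError, match="degrees of freedom"):
            parallelism_test(two, two)

    def test_matches_manual_pooled_formula(self):
        a = [(0, 0.0), (1, 1.1), (2, 1.9), (3, 3.2)]
        b = [(0, 0.5), (1, 1.2), (2, 2.4), (3, 3.0)]
        fa, fb = fit_line(a), fit_line(b)
        pooled = (fa.residual_ss + fb.residual_ss) / (4 + 4 - 4)
        se = math.sqrt(pooled * (1 / fa.sxx + 1 / fb.sxx))
        res = parallelism_test(a, b)
        assert res.t0 == pytest.approx((fa.slope - fb.slope) / se, rel=1e-12)

    def test_pinned_student_quantile(self):
        """The two-sided 5% Student quantile at f = 10 is the classic 2.228."""
        series = [(t, float(t)) for t in range(7)]
        res = parallelism_test(series, series, alpha=0.05)  # df = 7+7-4 = 10
        assert res.df == 10
        assert res.t_critical == pytest.approx(2.228, abs=5e-4)


class TestCalibrate:
    LINE = [(0.0, 0.1), (0.1, 0.4), (0.2, 0.7), (0.3, 1.0)]  # slope 3

    def test_direct_substitution(self):
        res = calibrate(self.LINE, low_range_sd=0.03)
        assert res.lod == pytest.approx(0.03)
        assert res.loq == pytest.approx(0.10)

    def test_noise_free_limit(self):
        res = calibrate(self.LINE, low_range_sd=0.0)
        assert res.lod == 0.0 and res.loq == 0.0

    def test_loq_is_ten_thirds_lod(self, rng):
        for sd in rng.uniform(0.001, 1.0, 5):
            res = calibrate(self.LINE, low_range_sd=sd)
            assert res.loq == pytest.approx(res.lod * 10.0 / 3.0, rel=1e-12)

    def test_scales_linearly_with_sd(self):
        r1 = calibrate(self.LINE, low_range_sd=0.01)
        r2 = calibrate(self.LINE, low_range_sd=0.02)
        assert r2.lod == pytest.approx(2 * r1.lod)
        assert r2.loq == pytest.approx(2 * r1.loq)

    def test_zero_slope_undefined(self):
        flat = [(0.0, 1.0), (1.0, 1.0), (2.0, 1.0)]
        with pytest.raises(ZeroDivisionError, match="LOD"):
            calibrate(flat, low_range_sd=0.01)

    def test_rsd_from_replicates(self):
        # six determinations with mean 0.19 mg/mL and sample SD exactly 0.002
        d = math.sqrt(5.0 / 6.0) * 0.002
        reps = [0.19 + d, 0.19 - d] * 3
        res = calibrate(self.LINE, low_range_sd=0.002, replicates=reps, nominal=0.20)
        assert res.rsd_pct == pytest.approx(1.05, abs=0.01)
        assert res.recovery_pct == pytest.approx(95.0, rel=1e-6)
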