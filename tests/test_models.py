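"""The four kinematic model fits and their derived quantities."""

import numpy as np
import pytest
import statsmodels.api as sm

from pitchnav.models import (
    BoutTimingModel,
    FinBodyModel,
    FitError,
    RightingModel,
    SteeringModel,
    finbody_variance,
    logistic,
)


class TestBoutTimingModel:
    def test_exact_parabola_recovered(self):
        x = np.linspace(-30, 40, 60)
        y = 0.002 * (x - 10) ** 2 + 1.0
        res = BoutTimingModel(x, y).fit()
        assert res.sensitivity == pytest.approx(0.002)
        assert res.baseline_posture == pytest.approx(10.0)
        assert res.base_rate == pytest.approx(1.0)
        assert res.rsquared == pytest.approx(1.0)

    def test_against_statsmodels_oracle(self, rng):
        x = rng.normal(5, 15, 500)
        y = 0.003 * (x - 8) ** 2 + 1.2 + rng.normal(0, 0.3, 500)
        res = BoutTimingModel(x, y).fit()
        X = sm.add_constant(np.column_stack([x, x**2]))
        ols = sm.OLS(y, X).fit()
        b0, b1, b2 = ols.params
        assert res.sensitivity == pytest.approx(b2, rel=1e-10)
        assert res.baseline_posture == pytest.approx(-b1 / (2 * b2), rel=1e-10)
        assert res.base_rate == pytest.approx(b0 - b1**2 / (4 * b2), rel=1e-10)
        assert res.bse["sensitivity"] == pytest.approx(ols.bse[2], rel=1e-8)
        assert res.rsquared == pytest.approx(ols.rsquared, rel=1e-10)

    def test_degenerate_design_raises(self):
        with pytest.raises(FitError):
            BoutTimingModel(np.full(10, 3.0), np.arange(10.0)).fit()

    def test_parameter_recovery_from_generated_ibis(self, analysis10k, dataset10k):
        res = BoutTimingModel.from_ibis(analysis10k.ibis).fit()
        a_true = dataset10k.ground_truth["sensitivity"]
        lo, hi = res.conf_int().loc["sensitivity"]
        assert lo <= a_true <= hi


class TestSteeringModel:
    def test_exact_line(self):
        x = np.linspace(-40, 40, 30)
        res = SteeringModel(x, 0.5 * x + 2).fit()
        assert res.steering_gain == pytest.approx(0.5)
        assert res.intercept == pytest.approx(2.0)
        assert res.pearson_r == pytest.approx(1.0)

    def test_against_statsmodels_oracle(self, rng):
        x = rng.normal(0, 20, 400)
        y = 0.7 * x + 1 + rng.normal(0, 3, 400)
        res = SteeringModel(x, y).fit()
        ols = sm.OLS(y, sm.add_constant(x)).fit()
        assert res.steering_gain == pytest.approx(ols.params[1], rel=1e-10)
        assert res.bse["steering_gain"] == pytest.approx(ols.bse[1], rel=1e-8)
        assert res.rsquared == pytest.approx(ols.rsquared, rel=1e-10)


class TestFinBodyModel:
    def test_noiseless_sigmoid_ratio_is_kh_over_4(self, rng):
        x = rng.uniform(-6, 6, 300)
        y = logistic(x, a=1.0, b=0.5, h=4.0, k=2.0)
        res = FinBodyModel(x, y).fit()
        assert res.fin_body_ratio == pytest.approx(2.0, rel=1e-6)
        assert res.rsquared == pytest.approx(1.0)

    def test_ratio_equals_numeric_max_slope(self, rng):
        x = rng.uniform(-15, 15, 800)
        y = logistic(x, -1.5, 2.0, 8.0, 0.4) + rng.normal(0, 1.0, 800)
        res = FinBodyModel(x, y).fit()
        a, b, h, k = (res.params[p] for p in ("a", "b", "h", "k"))
        grid = np.linspace(x.min(), x.max(), 20001)
        slope = np.gradient(logistic(grid, a, b, h, k), grid)
        assert res.fin_body_ratio == pytest.approx(slope.max(), rel=1e-4)
        # and the analytic maximum sits at x = -b
        assert grid[np.argmax(slope)] == pytest.approx(-b, abs=0.01)

    def test_selection_filters_counted(self, analysis10k, config):
        model = FinBodyModel.from_features(analysis10k.features, config)
        counts = model.filter_counts
        assert counts["below_speed_floor"] > 0
        n_expected = (
            len(analysis10k.features)
            - counts["below_speed_floor"]
            - counts["neg_attack_high_steer"]
        )
        assert len(model.x) == n_expected


class TestFinBodyVariance:
    def test_zero_variances_give_zero(self):
        assert finbody_variance(2.0, 4.0, 0.0, 0.0) == 0.0

    def test_printed_formula_example(self):
        # 2^2*0.04 + 4^2*0.01 + 0.01*0.04*(1/16)
        assert finbody_variance(2.0, 4.0, 0.01, 0.04) == pytest.approx(0.320025)

    def test_symmetric_under_kh_exchange(self):
        assert finbody_variance(3.0, 3.0, 0.02, 0.02) == finbody_variance(
            3.0, 3.0, 0.02, 0.02
        )
        a = finbody_variance(2.0, 5.0, 0.03, 0.03)
        b = finbody_variance(5.0, 2.0, 0.03, 0.03)
        assert a == pytest.approx(b)

    def test_negative_variance_rejected(self):
        with pytest.raises(ValueError):
            finbody_variance(2.0, 4.0, -0.01, 0.04)

    def test_delta_method_convention(self):
        v = finbody_variance(2.0, 4.0, 0.01, 0.04, convention="delta_method")
        assert v == pytest.approx((4 * 0.04 + 16 * 0.01 + 0.0004) / 16)


class TestRightingModel:
    def test_exact_line(self):
        x = np.linspace(-30, 30, 25)
        res = RightingModel(x, -0.2 * (x - 10)).fit()
        assert res.righting_gain == pytest.approx(0.2)
        assert res.set_point == pytest.approx(10.0)

    def test_zero_slope_flags_undefined_set_point(self):
        x = np.linspace(-5, 5, 11)
        res = RightingModel(x, np.full(11, 2.0)).fit()
        assert not res.extras["set_point_defined"]
        assert np.isnan(res.set_point)

    def test_summary_mentions_key_quantities(self):
        res = RightingModel(np.linspace(-30, 30, 25), -0.2 * (np.linspace(-30, 30, 25) - 10)).fit()
        text = res.summary()
        assert "slope" in text and "R-squared" in text


class TestScaleConsistency:
    """Multiplying all angles by c rescales coefficients per their units."""

    def test_all_four_models(self, rng):
        c = 2.5
        pitch = rng.normal(8, 15, 2000)
        freq = 0.003 * (pitch - 8) ** 2 + 1.2 + rng.normal(0, 0.3, 2000)
        t1 = BoutTimingModel(pitch, freq).fit()
        t2 = BoutTimingModel(c * pitch, freq).fit()
        assert t2.sensitivity == pytest.approx(t1.sensitivity / c**2, rel=1e-8)
        assert t2.baseline_posture == pytest.approx(c * t1.baseline_posture, rel=1e-8)

        traj = rng.normal(10, 20, 2000)
        pp = 0.7 * traj + rng.normal(0, 3, 2000)
        s1 = SteeringModel(traj, pp).fit()
        s2 = SteeringModel(c * traj, c * pp).fit()
        assert s2.steering_gain == pytest.approx(s1.steering_gain, rel=1e-8)

        x = rng.normal(0, 15, 2000)
        y = -0.2 * (x - 10) + rng.normal(0, 1.5, 2000)
        r1 = RightingModel(x, y).fit()
        r2 = RightingModel(c * x, c * y).fit()
        assert r2.righting_gain == pytest.approx(r1.righting_gain, rel=1e-8)
        assert r2.set_point == pytest.approx(c * r1.set_point, rel=1e-8)

        xb = rng.uniform(-12, 12, 2000)
        yb = logistic(xb, -1.5, 2.0, 8.0, 0.4) + rng.normal(0, 1.0, 2000)
        f1 = FinBodyModel(xb, yb).fit()
        f2 = FinBodyModel(c * xb, c * yb).fit()
        # slope dy/dx is scale free when both axes are scaled together
        assert f2.fin_body_ratio == pytest.approx(f1.fin_body_ratio, rel=1e-4)


class TestRecoveryConvergence:
    def test_rmse_decreases_with_sample_size(self, dataset10k, rng):
        """Estimator RMSE vs ground truth shrinks as n grows."""
        import pandas as pd

        truth = pd.concat([t for _, t in dataset10k.repeats], ignore_index=True)
        gain_true = dataset10k.ground_truth["righting_gain"]
        x = truth["pitch_initial"].to_numpy()
        y = truth["righting"].to_numpy()
        rmse = []
        for n in (500, 2000, 10000):
            errs = []
            for _ in range(8):
                idx = rng.integers(0, len(x), n)
                res = RightingModel(x[idx], y[idx]).fit()
                errs.append((res.righting_gain - gain_true) ** 2)
            rmse.append(np.sqrt(np.mean(errs)))
        assert rmse[0] > rmse[1] > rmse[2]
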