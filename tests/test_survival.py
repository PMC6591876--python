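"""Weibull survival curves, calibration and probability conversions."""

import io
import math

import numpy as np
import pytest
from hypothesis import given, settings as hyp_settings, strategies as st

from rectalcea import (
    CalibrationError,
    DigitizedCurve,
    InsufficientDataError,
    WeibullFit,
    fit_weibull,
    monthly_prob_from_fit,
    prob_to_rate,
    rate_to_prob,
    solve_pd_death,
    weibull_survival,
)
from rectalcea.survival import read_curve, write_curve
from rectalcea.synthetic import SyntheticCurveSpec, generate_km_points


def exact_curve(shape, scale, max_time=72, n=72, label=""):
    return generate_km_points(
        SyntheticCurveSpec(shape, scale, n_points=n, max_time=max_time, noise_sd=0.0, label=label)
    )


class TestWeibullSurvival:
    @pytest.mark.parametrize("shape,scale", [(0.7, 20.0), (1.0, 10.0), (2.5, 55.0)])
    def test_anchor_points(self, shape, scale):
        fit = WeibullFit(shape=shape, scale=scale)
        assert weibull_survival(0.0, fit) == 1.0
        assert weibull_survival(scale, fit) == pytest.approx(math.exp(-1))

    def test_exponential_special_case(self):
        fit = WeibullFit(shape=1.0, scale=10.0)
        assert weibull_survival(5.0, fit) == pytest.approx(math.exp(-0.5))

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            weibull_survival(-1.0, WeibullFit(1.0, 10.0))

    def test_non_increasing(self):
        fit = WeibullFit(shape=1.7, scale=30.0)
        t = np.linspace(0, 120, 500)
        s = weibull_survival(t, fit)
        assert np.all(np.diff(s) <= 0)
        assert np.all((0 < s) & (s <= 1))


class TestFitWeibull:
    @pytest.mark.parametrize("shape,scale", [(1.2, 40.0), (0.8, 25.0), (2.0, 60.0)])
    def test_noise_free_recovery(self, shape, scale):
        fit = fit_weibull(exact_curve(shape, scale))
        assert fit.shape == pytest.approx(shape, rel=0.01)
        assert fit.scale == pytest.approx(scale, rel=0.01)
        assert fit.sse < 1e-10

    def test_exponential_self_consistency(self):
        fit = fit_weibull(exact_curve(1.0, 35.0))
        assert fit.shape == pytest.approx(1.0, rel=0.01)

    def test_too_few_points(self):
        curve = DigitizedCurve((1.0, 2.0), (0.9, 0.8))
        with pytest.raises(InsufficientDataError):
            fit_weibull(curve)

    def test_points_outside_horizon_do_not_count(self):
        curve = DigitizedCurve((100.0, 110.0, 120.0), (0.5, 0.4, 0.3))
        with pytest.raises(InsufficientDataError):
            fit_weibull(curve, fit_horizon=72)

    def test_extra_exact_points_do_not_worsen_fit(self):
        base = exact_curve(1.4, 45.0, n=24)
        fit = fit_weibull(base)
        dense = exact_curve(1.4, 45.0, n=72)
        refit = fit_weibull(dense)
        assert refit.sse <= fit.sse + 1e-12

    def test_monotone_repair_applied_to_noisy_input(self):
        rng = np.random.default_rng(5)
        times = np.arange(1.0, 61.0)
        surv = np.clip(
            weibull_survival(times, WeibullFit(1.3, 40.0)) + rng.normal(0, 0.01, 60), 0, 1
        )
        curve = DigitizedCurve(tuple(times), tuple(np.minimum.accumulate(surv)))
        fit = fit_weibull(curve)
        assert fit.shape == pytest.approx(1.3, rel=0.15)
        assert fit.scale == pytest.approx(40.0, rel=0.15)

    def test_parameter_recovery_distribution(self):
        """Median relative error < 5% over 50 random noisy digitized curves."""
        rng = np.random.default_rng(42)
        errors = []
        for i in range(50):
            shape = rng.uniform(0.5, 3.0)
            scale = rng.uniform(10.0, 100.0)
            curve = generate_km_points(
                SyntheticCurveSpec(shape, scale, n_points=72, max_time=72.0,
                                   noise_sd=0.01, seed=1000 + i)
            )
            fit = fit_weibull(curve)
            errors.append(abs(fit.shape - shape) / shape)
            errors.append(abs(fit.scale - scale) / scale)
        assert np.median(errors) < 0.05


class TestRateProbConversion:
    def test_closed_forms(self):
        assert rate_to_prob(0.0) == 0.0
        assert prob_to_rate(0.0348) == pytest.approx(-math.log(0.9652))
        assert prob_to_rate(0.0348) == pytest.approx(0.03542, abs=5e-6)

    def test_certain_event_is_infinite_rate(self):
        with pytest.raises(ValueError, match="infinite"):
            prob_to_rate(1.0)
        with pytest.raises(ValueError):
            rate_to_prob(-0.1)

    @given(p=st.floats(min_value=0.0, max_value=0.999),
           dt=st.floats(min_value=0.1, max_value=12.0))
    @hyp_settings(max_examples=50, derandomize=True)
    def test_round_trip_identity(self, p, dt):
        assert rate_to_prob(prob_to_rate(p, dt), dt) == pytest.approx(p, abs=1e-12)


class TestMonthlyProbFromFit:
    def test_matches_published_three_year_dfs(self):
        # exponential curve anchored at S(36) = 0.53 (trial 3-year DFS, SCRT)
        scale = -36.0 / math.log(0.53)
        q = monthly_prob_from_fit(WeibullFit(1.0, scale), 36.0)
        assert q == pytest.approx(1 - 0.53 ** (1 / 36), abs=1e-12)
        assert q == pytest.approx(0.01748, abs=5e-6)

    def test_exponential_equals_rate_conversion(self):
        fit = WeibullFit(1.0, 50.0)
        for h in (12.0, 36.0, 72.0):
            assert monthly_prob_from_fit(fit, h) == pytest.approx(
                rate_to_prob(1.0 / 50.0), rel=1e-9
            )

    def test_monotone_in_survival(self):
        # lower survival at the matching horizon -> higher monthly probability
        qs = [
            monthly_prob_from_fit(WeibullFit(1.2, scale), 36.0)
            for scale in (80.0, 60.0, 40.0, 20.0)
        ]
        assert qs == sorted(qs)

    def test_invalid_horizon(self):
        with pytest.raises(ValueError):
            monthly_prob_from_fit(WeibullFit(1.0, 10.0), 0.0)


class TestSolvePdDeath:
    @staticmethod
    def _alive(p_dfs_pd, p_dfs_death, p_pd_death, horizon):
        dfs, pd_ = 1.0, 0.0
        for _ in range(horizon):
            dfs, pd_ = dfs * (1 - p_dfs_pd - p_dfs_death), pd_ * (1 - p_pd_death) + dfs * p_dfs_pd
        return dfs + pd_

    def test_recovers_known_pd_mortality(self):
        """OS generated from the model itself gives back the true PD->death."""
        truth = 0.05
        horizon = 36
        alive = self._alive(0.0204, 0.0148, truth, horizon)
        # exponential curve passing exactly through the model's OS point
        os_fit = WeibullFit(1.0, -horizon / math.log(alive))
        rec = solve_pd_death((0.0204, 0.0148), os_fit, horizon)
        assert rec == pytest.approx(truth, abs=1e-6)

    def test_degenerate_no_pd_entry(self):
        assert solve_pd_death((0.0, 0.02), WeibullFit(1.0, 50.0), 36) == 0.0

    def test_infeasible_target(self):
        # OS target far above what DFS attrition alone allows
        with pytest.raises(CalibrationError):
            solve_pd_death((0.0204, 0.0148), WeibullFit(1.0, 1e4), 36)


class TestCurveIO:
    def test_round_trip(self):
        curve = exact_curve(1.2, 40.0, n=10, label="dfs")
        buf = io.StringIO()
        write_curve(curve, buf)
        buf.seek(0)
        again = read_curve(buf, label="dfs")
        assert again.times == pytest.approx(curve.times)
        assert again.survival == pytest.approx(curve.survival)

    def test_duplicate_times_keep_last_reading(self):
        buf = io.StringIO("time_months,survival\n1,0.9\n2,0.85\n2,0.80\n3,0.7\n")
        curve = read_curve(buf)
        assert curve.times == (1.0, 2.0, 3.0)
        assert curve.survival[1] == 0.80

    def test_strictly_increasing_times_enforced(self):
        with pytest.raises(ValueError):
            DigitizedCurve((1.0, 1.0, 2.0), (0.9, 0.8, 0.7))
        with pytest.raises(ValueError):
            DigitizedCurve((1.0, 2.0), (0.9, 1.2))
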