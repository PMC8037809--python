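"""Retention factors, series building and pure-water (logkw) extrapolation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from bbbperm import (
    ConfigurationError,
    InsufficientDataError,
    RetentionMeasurement,
    RetentionSeries,
    RetentionSimSpec,
    SingularDesignError,
    ValidationError,
    build_series,
    extrapolate_logkw,
    fit_logk_series,
    micellized_concentration,
    retention_factor,
    simulate_retention,
)
from bbbperm.retention import _ols_line


class TestRetentionFactor:
    @pytest.mark.parametrize(
        "t_r,t_0,expected",
        [(1.0, 1.0, 0.0), (2.0, 1.0, 1.0), (4.20, 1.05, 3.0)],
    )
    def test_values(self, t_r, t_0, expected):
        assert retention_factor(t_r, t_0) == pytest.approx(expected)

    def test_retention_before_dead_time_is_domain_error(self):
        with pytest.raises(ValidationError):
            retention_factor(0.9, 1.05)

    def test_nonpositive_dead_time_rejected(self):
        with pytest.raises(ValidationError):
            retention_factor(1.0, 0.0)


class TestMicellizedConcentration:
    def test_subtraction(self):
        assert micellized_concentration(0.075, 9.0e-5) == pytest.approx(0.07491)

    def test_boundary_and_zero_cmc(self):
        assert micellized_concentration(0.1, 0.1) == 0.0
        assert micellized_concentration(0.15, 0.0) == 0.15

    def test_below_cmc_is_domain_error(self):
        with pytest.raises(ValidationError):
            micellized_concentration(0.01, 0.02)


class TestBuildSeries:
    def test_replicates_averaged_on_k_scale(self):
        ms = [
            RetentionMeasurement("x", "IAM", 0.3, t_r=1.0 + k, t_0=1.0, replicate=i + 1)
            for i, k in enumerate([2.9, 3.0, 3.1])
        ]
        (series,) = build_series(ms)
        assert series.points == [(0.3, pytest.approx(3.0), 3)]

    def test_single_measurement_kept_with_warning(self):
        ms = [RetentionMeasurement("x", "IAM", 0.3, t_r=4.0, t_0=1.0)]
        with pytest.warns(UserWarning, match="replicate"):
            (series,) = build_series(ms)
        assert len(series.points) == 1

    def test_zero_k_level_excluded_with_warning(self):
        ms = [
            RetentionMeasurement("x", "IAM", lv, t_r=t_r, t_0=1.0, replicate=r)
            for lv, t_r, r in [(0.3, 3.0, 1), (0.3, 3.0, 2), (0.3, 3.0, 3),
                               (0.4, 1.0, 1), (0.4, 1.0, 2), (0.4, 1.0, 3)]
        ]
        with pytest.warns(UserWarning, match="cannot take log"):
            (series,) = build_series(ms)
        assert [p[0] for p in series.points] == [0.3]

    def test_bmc_without_cmc_is_configuration_error(self):
        ms = [
            RetentionMeasurement("x", "BMC", 0.075, t_r=6.1, t_0=1.22, replicate=r)
            for r in (1, 2, 3)
        ]
        with pytest.raises(ConfigurationError, match="CMC"):
            build_series(ms)


class TestFitAndExtrapolate:
    def exact_series(self, intercept=2.0, slope=-4.0, levels=(0.3, 0.4, 0.5, 0.6)):
        points = [(lv, 10 ** (intercept + slope * lv), 3) for lv in levels]
        return RetentionSeries("x", "IAM", points)

    def test_noiseless_line_recovered_exactly(self):
        fit = fit_logk_series(self.exact_series())
        assert fit.slope == pytest.approx(-4.0, abs=1e-12)
        assert fit.intercept == pytest.approx(2.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0)

    def test_two_levels_insufficient(self):
        with pytest.raises(InsufficientDataError):
            fit_logk_series(self.exact_series(levels=(0.3, 0.4)))

    def test_logkw_equals_intercept(self):
        fit = fit_logk_series(self.exact_series())
        res = extrapolate_logkw(fit, "x", "IAM")
        assert res.logkw == fit.intercept

    def test_flat_retention_extrapolates_to_itself(self):
        fit = fit_logk_series(self.exact_series(intercept=0.5, slope=0.0))
        assert extrapolate_logkw(fit, "x", "IAM").logkw == pytest.approx(0.5)
        assert fit.slope == pytest.approx(0.0, abs=1e-12)

    def test_bmc_abscissa_is_micellized_concentration(self):
        cmc = 9.0e-5
        levels = (0.075, 0.1, 0.125, 0.15)
        points = [(lv, 10 ** (1.0 - 5.0 * (lv - cmc)), 3) for lv in levels]
        series = RetentionSeries("x", "BMC", points, cmc=cmc)
        fit = fit_logk_series(series)
        assert fit.intercept == pytest.approx(1.0, abs=1e-9)
        assert fit.slope == pytest.approx(-5.0, abs=1e-6)

    @given(
        x0=st.floats(-5, 5), x1=st.floats(-5, 5),
        y0=st.floats(-5, 5), y1=st.floats(-5, 5),
        x2=st.floats(-5, 5),
    )
    def test_ols_matches_two_point_closed_form_on_collinear_input(self, x0, x1, y0, y1, x2):
        """Any noiseless collinear input reproduces the two-point line exactly."""
        xs = np.array(sorted({x0, x1, x2}))
        if len(xs) < 3 or np.ptp(xs) < 1e-3 or abs(x1 - x0) < 1e-3:
            return
        slope = (y1 - y0) / (x1 - x0)
        ys = y0 + slope * (xs - x0)
        fit = _ols_line(xs, ys)
        assert fit.slope == pytest.approx(slope, abs=1e-7 * max(1, abs(slope)))
        assert fit.intercept == pytest.approx(y0 - slope * x0, abs=1e-6)

    def test_adding_point_on_fitted_line_never_decreases_r_squared(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            x = np.sort(rng.uniform(0, 1, size=5))
            y = 1.0 - 2.0 * x + rng.normal(0, 0.1, size=5)
            fit = _ols_line(x, y)
            x_new = np.append(x, 1.5)
            y_new = np.append(y, fit.intercept + fit.slope * 1.5)
            fit2 = _ols_line(x_new, y_new)
            assert fit2.r_squared >= fit.r_squared - 1e-12


class TestSyntheticRecovery:
    def test_noiseless_simulated_series_round_trips(self, quiet_build_series):
        spec = RetentionSimSpec(logkw_true=1.3, slope_true=-3.5, noise_sd=0.0, n_replicates=1)
        (series,) = quiet_build_series(simulate_retention(spec))
        fit = fit_logk_series(series)
        assert fit.intercept == pytest.approx(1.3, abs=1e-10)
        assert fit.slope == pytest.approx(-3.5, abs=1e-9)

    def test_mean_intercept_unbiased_over_seeds(self, quiet_build_series):
        """Intercept recovery at noise sd 0.01 stays within 3 SE of truth."""
        recovered = []
        for seed in range(500):
            spec = RetentionSimSpec(logkw_true=2.0, slope_true=-4.0, noise_sd=0.01,
                                    n_replicates=1, seed=seed)
            (series,) = quiet_build_series(simulate_retention(spec))
            recovered.append(fit_logk_series(series).intercept)
        recovered = np.array(recovered)
        se = recovered.std(ddof=1) / np.sqrt(len(recovered))
        assert abs(recovered.mean() - 2.0) < 3 * se
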