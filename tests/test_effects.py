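import numpy as np
import pandas as pd
import pytest

import dlnmcc as d
from dlnmcc.ccmodel import FitResult
from dlnmcc.crossbasis import CrossBasisSpec
from dlnmcc.basis import LagSpec, ThresholdSpec
from dlnmcc.effects import (cumulative_effect, lag_slice, predict_surface,
                            temp_slice)


class TestCentering:
    def test_rr_is_one_at_centering_temperature(self, spline_results):
        center = spline_results.spec.center
        surface = spline_results.predict_surface(temp_grid=[center - 5, center,
                                                            center + 5])
        i = 1
        assert np.allclose(surface.log_rr[i], 0.0, atol=1e-12)
        assert np.allclose(surface.se[i], 0.0, atol=1e-12)

    def test_cumulative_effect_at_center_is_zero_with_zero_variance(self, spline_results):
        eff = spline_results.cumulative(
            {"at_temperature": spline_results.spec.center}, (0, 27))
        assert eff.percent_increase == pytest.approx(0.0, abs=1e-12)
        assert eff.se == pytest.approx(0.0, abs=1e-12)

    def test_lag_slice_at_center_is_flat_one(self, spline_results):
        center = spline_results.spec.center
        surface = spline_results.predict_surface(temp_grid=[center])
        assert np.allclose(lag_slice(surface, center)["rr"], 1.0, atol=1e-12)


class TestCumulative:
    def test_percent_scale_round_trip(self):
        """A cumulative log-RR of log(1.0299) reports as a 2.99% increase."""
        spec = CrossBasisSpec(exposure=ThresholdSpec(0.0, 25.0),
                              lag=LagSpec.log_spline(1, 2), center=14.0)
        names = spec.column_names()
        # lag basis at lag 0 is (1, 0): the cold intercept column carries the
        # whole lag-0 effect
        assert np.allclose(spec.lag_values()[0], [1.0, 0.0])
        beta = pd.Series(np.zeros(4), index=names)
        beta.iloc[0] = np.log(1.0299)
        fit = FitResult(params=beta, cov=pd.DataFrame(np.zeros((4, 4)),
                                                      index=names, columns=names),
                        dispersion=1.0, llf=0.0, deviance=0.0, n_used=10,
                        df_model=4, fitted=np.ones(10), converged=True,
                        n_iter=1, method="synthetic")
        eff = cumulative_effect(fit, spec, "per_degree_below_cold", (0, 0))
        assert eff.percent_increase == pytest.approx(2.99, abs=0.005)

    def test_additivity_of_log_rr_over_lag_partition(self, threshold_results):
        r = threshold_results
        full = r.cumulative("per_degree_below_cold", (0, 27))
        head = r.cumulative("per_degree_below_cold", (0, 2))
        tail = r.cumulative("per_degree_below_cold", (3, 27))
        assert full.log_rr == pytest.approx(head.log_rr + tail.log_rr, abs=1e-12)

    def test_single_lag_window_matches_lag_curve(self, threshold_results):
        eff = threshold_results.cumulative("per_degree_above_hot", (0, 0))
        curve = threshold_results.lag_curve("hot")
        assert np.exp(eff.log_rr) == pytest.approx(curve["rr"].iloc[0], rel=1e-12)

    def test_delta_variance_matches_parametric_bootstrap(self, threshold_results, rng):
        """Delta-method variance of the cumulative log-RR agrees with a
        1,000-draw parametric bootstrap from the coefficient covariance."""
        r = threshold_results
        eff = r.cumulative("per_degree_below_cold", (0, 18))
        params, cov = r.fit_result.param_block("cb_")
        draws = rng.multivariate_normal(params.to_numpy(), cov.to_numpy(), size=1000)
        from dlnmcc.crossbasis import exceedance_vector
        w = np.sum([exceedance_vector(r.spec, "cold", l) for l in range(19)], axis=0)
        boot_sd = np.std(draws @ w, ddof=1)
        assert eff.se == pytest.approx(boot_sd, rel=0.05)

    def test_empty_lag_range_rejected(self, threshold_results):
        with pytest.raises(ValueError):
            threshold_results.cumulative("per_degree_above_hot", (5, 2))


class TestSurfacesAndSlices:
    def test_threshold_surface_flat_between_thresholds(self, threshold_results):
        spec = threshold_results.spec
        grid = np.linspace(spec.exposure.cold_threshold + 0.5,
                           spec.exposure.hot_threshold - 0.5, 7)
        surface = threshold_results.predict_surface(temp_grid=grid)
        assert np.allclose(surface.log_rr, 0.0, atol=1e-12)

    def test_temp_slice_at_lag0_piecewise_linear_in_log_rr(self, threshold_results):
        spec = threshold_results.spec
        cold = spec.exposure.cold_threshold
        grid = np.array([cold - 3, cold - 2, cold - 1, cold])
        surface = threshold_results.predict_surface(temp_grid=grid)
        s = temp_slice(surface, 0)
        lr = np.log(s["rr"].to_numpy())
        assert np.allclose(np.diff(lr, 2), 0.0, atol=1e-10)

    def test_off_grid_slice_is_an_error_not_interpolation(self, spline_results):
        surface = spline_results.predict_surface(temp_grid=[0.0, 10.0, 20.0])
        with pytest.raises(ValueError, match="nearest"):
            lag_slice(surface, 10.37)

    def test_indicator_lag_slice_matches_per_lag_glm_oracle(self, rng):
        """With a linear exposure and indicator lag basis the per-lag RRs
        equal exponentiated coefficients of a GLM on explicit lagged copies."""
        import statsmodels.api as sm
        from dlnmcc.basis import SplineSpec
        from dlnmcc.crossbasis import build_crossbasis, prediction_vector

        n, L = 600, 3
        x = rng.normal(10, 5, n)
        lagged = np.column_stack([np.r_[np.full(l, np.nan), x[: n - l]]
                                  for l in range(L + 1)])
        beta_true = np.array([0.02, 0.01, 0.0, -0.01])
        mu = np.exp(2.5 + np.nan_to_num(lagged) @ beta_true)
        y = rng.poisson(mu)

        spec = CrossBasisSpec(
            exposure=SplineSpec.for_range(float(x.min()), float(x.max()), 1),
            lag=LagSpec.indicator(L), center=10.0)
        cb = build_crossbasis(x, spec)
        used = cb.complete
        X = np.column_stack([np.ones(used.sum()), cb.values[used]])
        ours = d.fit_quasipoisson(y[used], X,
                                  names=["intercept", *cb.names])
        ref = sm.GLM(y[used],
                     np.column_stack([np.ones(used.sum()), lagged[used]]),
                     family=sm.families.Poisson()).fit()
        for l in range(L + 1):
            w = prediction_vector(spec, 11.0, l)   # +1 degC above center
            log_rr = float(w @ ours.params.iloc[1:].to_numpy())
            assert log_rr == pytest.approx(ref.params[1 + l], abs=1e-8)
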