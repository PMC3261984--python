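import numpy as np
import pandas as pd
import pytest

import dlnmcc as d
from dlnmcc.basis import LagSpec, SplineSpec
from dlnmcc.ccmodel import (DailySeries, FitResult, StrataSpec, build_design,
                            fit_conditional, fit_quasipoisson, make_strata, qaic,
                            time_spline_design)
from dlnmcc.crossbasis import CrossBasisSpec, build_crossbasis


class TestStrata:
    def test_calendar_month_counts(self):
        dates = pd.date_range("2005-01-01", "2005-12-31")
        assert make_strata(pd.Series(dates), StrataSpec()).nunique() == 12
        dates3 = pd.date_range("2005-01-01", "2007-12-31")
        assert make_strata(pd.Series(dates3), StrataSpec()).nunique() == 36

    def test_fixed_window_counts_with_short_tail(self):
        dates = pd.date_range("2005-01-01", periods=1095)
        labels = make_strata(pd.Series(dates),
                             StrataSpec(scheme="fixed_window", window_days=21))
        assert labels.nunique() == 53          # 52 full windows + one of 3 days
        assert (labels.value_counts() <= 21).all()

    def test_windows_partition_every_date(self):
        dates = pd.Series(pd.date_range("2006-03-01", periods=400))
        for spec in (StrataSpec(), StrataSpec(scheme="fixed_window", window_days=28)):
            labels = make_strata(dates, spec)
            assert len(labels) == 400 and labels.notna().all()

    def test_empty_dates_rejected(self):
        with pytest.raises(ValueError):
            make_strata(pd.Series([], dtype="datetime64[ns]"), StrataSpec())


class TestQuasiPoissonFit:
    def test_intercept_only_closed_form(self, rng):
        y = rng.poisson(20.0, 500)
        fit = fit_quasipoisson(y, np.ones((500, 1)))
        assert np.isclose(fit.params.iloc[0], np.log(y.mean()), atol=1e-8)

    def test_doubling_counts_shifts_only_intercept_by_log2(self, rng):
        n = 400
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = rng.poisson(np.exp(2.0 + 0.3 * X[:, 1]))
        f1 = fit_quasipoisson(y, X)
        f2 = fit_quasipoisson(2 * y, X)
        assert np.isclose(f2.params.iloc[0] - f1.params.iloc[0], np.log(2), atol=1e-7)
        assert np.isclose(f2.params.iloc[1], f1.params.iloc[1], atol=1e-7)

    def test_dispersion_near_one_for_equidispersed_counts(self, rng):
        phis = []
        for _ in range(200):
            y = rng.poisson(15.0, 1000)
            phis.append(fit_quasipoisson(y, np.ones((1000, 1))).dispersion)
        assert abs(np.mean(phis) - 1.0) < 0.1

    def test_matches_statsmodels_quasipoisson(self, rng):
        """Independent oracle: statsmodels GLM with Pearson-scaled covariance."""
        import statsmodels.api as sm
        n = 600
        X = np.column_stack([np.ones(n), rng.normal(size=n),
                             rng.uniform(size=n)])
        y = rng.poisson(np.exp(1.5 + 0.4 * X[:, 1] - 0.6 * X[:, 2]))
        ours = fit_quasipoisson(y, X)
        ref = sm.GLM(y, X, family=sm.families.Poisson()).fit(scale="X2")
        assert np.allclose(ours.params.to_numpy(), ref.params, atol=1e-7)
        assert np.allclose(ours.bse().to_numpy(), ref.bse, rtol=1e-5)
        assert np.isclose(ours.dispersion, ref.scale, rtol=1e-8)
        assert np.isclose(ours.deviance, ref.deviance, rtol=1e-8)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fit_quasipoisson(np.array([1.0, -2.0]), np.ones((2, 1)))

    def test_rank_deficiency_names_aliased_columns(self, rng):
        n = 100
        x = rng.normal(size=n)
        X = np.column_stack([np.ones(n), x, 2 * x])
        with pytest.raises(ValueError, match="aliased"):
            fit_quasipoisson(rng.poisson(5, n), X, names=["c", "x1", "x2"])

    def test_deviance_nonincreasing_with_nested_columns(self, rng):
        n = 500
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = rng.poisson(np.exp(2.0 + 0.2 * X[:, 1]))
        small = fit_quasipoisson(y, X)
        big = fit_quasipoisson(y, np.column_stack([X, rng.normal(size=n)]))
        assert big.deviance <= small.deviance + 1e-9

    def test_dispersion_invariant_under_basis_reparameterization(self, rng):
        n = 400
        S = np.column_stack([rng.normal(size=n) for _ in range(3)])
        X = np.column_stack([np.ones(n), S])
        y = rng.poisson(np.exp(2.0 + 0.1 * S[:, 0]))
        A = np.array([[1.0, 0.5, 0.0], [0.0, 2.0, -1.0], [0.0, 0.0, 1.5]])
        X2 = np.column_stack([np.ones(n), S @ A])
        f1, f2 = fit_quasipoisson(y, X), fit_quasipoisson(y, X2)
        assert np.isclose(f1.dispersion, f2.dispersion, atol=1e-8)
        assert np.isclose(f1.deviance, f2.deviance, atol=1e-8)


class TestConditionalEquivalence:
    def test_conditional_matches_stratified_indicators(self, both_series):
        """The design's central equivalence: eliminating stratum intercepts
        analytically reproduces the indicator fit's slopes and their
        profile covariance."""
        series, _ = both_series
        model = d.TemperatureLagModel(series)
        strat = model.fit(method="stratified")
        cond = model.fit(method="conditional")
        common = list(cond.params.index)
        assert np.allclose(strat.params[common].to_numpy(),
                           cond.params.to_numpy(), atol=1e-6)
        assert np.allclose(strat.cov_params.loc[common, common].to_numpy(),
                           cond.cov_params.to_numpy(), atol=1e-6)
        assert np.isclose(strat.deviance, cond.deviance, atol=1e-5)
        assert np.isclose(strat.dispersion, cond.dispersion, atol=1e-6)

    def test_single_stratum_equals_ordinary_fit(self, rng):
        n = 200
        x = rng.normal(size=n)
        y = rng.poisson(np.exp(2.0 + 0.3 * x))
        cond = fit_conditional(y, x[:, None], np.zeros(n, dtype=int))
        full = fit_quasipoisson(y, np.column_stack([np.ones(n), x]))
        assert np.isclose(cond.params.iloc[0], full.params.iloc[1], atol=1e-7)

    def test_zero_count_strata_carry_no_information(self, rng):
        n = 120
        x = rng.normal(size=n)
        strata = np.repeat(np.arange(4), 30)
        y = rng.poisson(np.exp(1.0 + 0.3 * x))
        y[strata == 3] = 0
        with_zero = fit_conditional(y, x[:, None], strata)
        keep = strata != 3
        without = fit_conditional(y[keep], x[keep, None], strata[keep])
        assert np.isclose(with_zero.params.iloc[0], without.params.iloc[0], atol=1e-10)


class TestDesignAssembly:
    def test_covariate_smooths_and_calendar_columns(self, tianjin_series):
        series, _ = tianjin_series
        x = series.temperature("tmean")
        spec = CrossBasisSpec(exposure=SplineSpec.for_range(x.min(), x.max(), 5),
                              lag=LagSpec.log_spline(27, 4),
                              center=float(np.median(x)))
        cb = build_crossbasis(x, spec)
        strata = make_strata(series.dates, StrataSpec())
        y, X, names, used, _ = build_design(series, cb, strata, "nonaccidental")
        smooth_cols = [n for n in names if n.endswith(("_s0", "_s1", "_s2"))
                       and not n.startswith("time")]
        assert len(smooth_cols) == 12          # 4 covariates x 3 df
        assert sum(n.startswith("dow_") for n in names) == 6
        assert used.sum() == len(series) - 27
        # leading incomplete days knock out no whole stratum here, but the
        # first stratum becomes the reference level
        assert sum(n.startswith("stratum_") for n in names) == 35

    def test_time_spline_dimensions(self):
        dates = pd.Series(pd.date_range("2005-01-01", "2007-12-31"))
        T, names = time_spline_design(dates, 7.0)
        assert T.shape[1] == 21                # 7 df/year x 3 years
        T1, _ = time_spline_design(dates[:365], 1.0)
        assert T1.shape[1] == 1
        # continuity in (continuous) time: evaluating the same spline at
        # day index t and t + epsilon agrees
        from dlnmcc.basis import SplineSpec, ns_basis
        n = len(dates)
        spec = SplineSpec.for_range(0.0, float(n - 1), 21)
        t = np.linspace(0, n - 1, 200)
        assert np.allclose(ns_basis(t, spec), ns_basis(t + 1e-8, spec),
                           rtol=1e-6, atol=1e-4)


class TestQaic:
    def test_formula(self):
        fit = FitResult(params=pd.Series(np.zeros(5)), cov=pd.DataFrame(np.eye(5)),
                        dispersion=1.0, llf=-100.0, deviance=10.0, n_used=50,
                        df_model=5, fitted=np.ones(50), converged=True, n_iter=3,
                        method="test")
        assert qaic(fit) == pytest.approx(210.0)
        fit.dispersion = 2.5
        assert qaic(fit) == pytest.approx(-2 * -100.0 + 2 * 2.5 * 5)


class TestDailySeries:
    def test_gap_in_dates_rejected(self, tianjin_series):
        series, _ = tianjin_series
        df = series.df.drop(columns=["dow"]).drop(index=5)
        with pytest.raises(ValueError, match="consecutive"):
            DailySeries(df)

    def test_negative_counts_rejected(self, tianjin_series):
        series, _ = tianjin_series
        df = series.df.drop(columns=["dow"]).copy()
        df.loc[3, "nonaccidental"] = -1
        with pytest.raises(ValueError, match="non-negative"):
            DailySeries(df)

    def test_csv_round_trip(self, tianjin_series, tmp_path):
        series, _ = tianjin_series
        p = tmp_path / "s.csv"
        series.to_csv(p)
        back = DailySeries.from_csv(p)
        assert np.allclose(back.df["tmean"], series.df["tmean"])
        assert (back.df["nonaccidental"] == series.df["nonaccidental"]).all()
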