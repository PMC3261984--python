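"""Model/Results facade over the case-crossover DLNM machinery.

``TemperatureLagModel`` bundles a daily series, a cross-basis
specification and a referent-strata scheme; ``fit()`` returns a
``TemperatureLagResults`` carrying the coefficient estimates, their
covariance, dispersion and QAIC, with methods for relative-risk surfaces,
lag curves, cumulative effects and a text summary.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .basis import LagSpec, SplineSpec, ThresholdSpec
from .ccmodel import (DailySeries, FitResult, StrataSpec, build_design,
                      fit_conditional, fit_quasipoisson, make_strata)
from .crossbasis import CrossBasisSpec, build_crossbasis
from .effects import (cumulative_effect, exceedance_lag_curve, lag_slice,
                      overall_effect_curve, predict_surface)

__all__ = ["TemperatureLagModel", "TemperatureLagResults"]


class TemperatureLagModel:
    """Case-crossover DLNM for one outcome and one temperature measure.

    Parameters
    ----------
    series : DailySeries
        Daily counts, temperatures and covariates.
    outcome : str
        Death-count column to model (e.g. ``"nonaccidental"``).
    measure : str
        Temperature measure (``"tmax"``, ``"tmean"`` or ``"tmin"``).
    exposure : SplineSpec | ThresholdSpec | None
        Exposure basis; defaults to a 5-df natural spline with equally
        spaced knots over the observed temperature range.
    lag : LagSpec | None
        Lag basis; defaults to a 4-df natural spline with knots equally
        spaced on the log-lag axis up to lag 27.
    strata : StrataSpec
        Referent-window scheme (calendar month by default).
    center : float | None
        Centering temperature; defaults to the observed median.
    """

    def __init__(self, series: DailySeries, outcome: str = "nonaccidental",
                 measure: str = "tmean",
                 exposure: SplineSpec | ThresholdSpec | None = None,
                 lag: LagSpec | None = None,
                 strata: StrataSpec | None = None,
                 center: float | None = None):
        self.series = series
        self.outcome = outcome
        self.measure = measure
        x = series.temperature(measure)
        if exposure is None:
            exposure = SplineSpec.for_range(float(x.min()), float(x.max()), 5)
        if lag is None:
            lag = LagSpec.log_spline(27, 4)
        if center is None:
            center = float(np.median(x))
        self.strata_spec = strata or StrataSpec()
        self.crossbasis_spec = CrossBasisSpec(exposure=exposure, lag=lag,
                                              center=float(center))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "TemperatureLagModel":
        return cls(DailySeries(df), **kwargs)

    @classmethod
    def from_csv(cls, path, columns: dict | None = None, **kwargs) -> "TemperatureLagModel":
        return cls(DailySeries.from_csv(path, columns=columns), **kwargs)

    def fit(self, method: str = "stratified") -> "TemperatureLagResults":
        """Fit by quasi-Poisson IRLS with stratum indicators (``"stratified"``)
        or by the equivalent conditional-Poisson likelihood (``"conditional"``)."""
        x = self.series.temperature(self.measure)
        cb = build_crossbasis(x, self.crossbasis_spec)
        strata = make_strata(self.series.dates, self.strata_spec)
        if method == "stratified":
            y, X, names, used, _ = build_design(
                self.series, cb, strata, self.outcome, include_strata=True)
            fit = fit_quasipoisson(y, X, names=names)
        elif method == "conditional":
            y, X, names, used, strata_used = build_design(
                self.series, cb, strata, self.outcome, include_strata=False)
            fit = fit_conditional(y, X[:, 1:], strata_used, names=names[1:])
        else:
            raise ValueError("method must be 'stratified' or 'conditional'")
        return TemperatureLagResults(self, fit)


class TemperatureLagResults:
    """Fitted case-crossover DLNM."""

    def __init__(self, model: TemperatureLagModel, fit: FitResult):
        self.model = model
        self.fit_result = fit
        self.spec = model.crossbasis_spec

    # -- statsmodels-style accessors -------------------------------------
    @property
    def params(self) -> pd.Series:
        return self.fit_result.params

    @property
    def cov_params(self) -> pd.DataFrame:
        return self.fit_result.cov

    @property
    def bse(self) -> pd.Series:
        return self.fit_result.bse()

    @property
    def dispersion(self) -> float:
        return self.fit_result.dispersion

    @property
    def deviance(self) -> float:
        return self.fit_result.deviance

    @property
    def llf(self) -> float:
        return self.fit_result.llf

    @property
    def qaic(self) -> float:
        return self.fit_result.qaic

    @property
    def n_used(self) -> int:
        return self.fit_result.n_used

    # -- effect summaries -------------------------------------------------
    def predict_surface(self, temp_grid=None, lag_grid=None):
        return predict_surface(self.fit_result, self.spec, temp_grid, lag_grid)

    def overall_effect(self, temp_grid=None) -> pd.DataFrame:
        return overall_effect_curve(self.fit_result, self.spec, temp_grid)

    def cumulative(self, estimand, lag_range: tuple[int, int]):
        return cumulative_effect(self.fit_result, self.spec, estimand, lag_range)

    def lag_curve(self, side: str) -> pd.DataFrame:
        """Per-lag RR for a 1 degC threshold exceedance ('cold' or 'hot')."""
        return exceedance_lag_curve(self.fit_result, self.spec, side)

    def lag_slice(self, at_temperature: float, temp_grid=None) -> pd.DataFrame:
        surface = self.predict_surface(temp_grid=temp_grid)
        return lag_slice(surface, at_temperature)

    def summary(self) -> str:
        """Plain-text fit summary (cross-basis block plus fit statistics)."""
        fr = self.fit_result
        cb_params, _ = fr.param_block("cb_")
        lines = [
            "Case-crossover distributed-lag non-linear model",
            "=" * 58,
            f"outcome: {self.model.outcome:<18} measure: {self.model.measure}",
            f"exposure basis: {type(self.spec.exposure).__name__}, "
            f"lag df: {self.spec.lag.df}, max lag: {self.spec.max_lag}",
            f"strata: {self.model.strata_spec.scheme}   "
            f"centering temperature: {self.spec.center:.1f} °C",
            f"n used: {fr.n_used}   parameters: {fr.df_model}   method: {fr.method}",
            f"dispersion (Pearson): {fr.dispersion:.3f}",
            f"residual deviance: {fr.deviance:.1f}   log-lik: {fr.llf:.1f}   "
            f"QAIC: {fr.qaic:.1f}",
            "-" * 58,
            "cross-basis coefficients:",
        ]
        bse = fr.bse()
        for name, val in cb_params.items():
            lines.append(f"  {name:<14} {val:>10.5f}  (se {bse[name]:.5f})")
        lines.append("=" * 58)
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"<TemperatureLagResults outcome={self.model.outcome!r} "
                f"QAIC={self.qaic:.1f}>")
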