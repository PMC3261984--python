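"""Study-workflow orchestration: descriptive summaries, temperature-measure
comparison, the main spline-DLNM + threshold-search + double-threshold
analysis, design comparison against a time-series spline, and sensitivity
analyses over referent-window length and maximum lag.

Every table produced here carries the configuration hash and the package
version so runs are traceable to their settings.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import spearmanr

from . import __version__
from .basis import LagSpec, SplineSpec, ThresholdSpec
from .ccmodel import CAUSES, MEASURES, DailySeries, StrataSpec
from .effects import exceedance_lag_curve
from .model import TemperatureLagModel
from .thresholds import coarse_to_fine, search_thresholds

__all__ = [
    "AnalysisConfig",
    "summarize_series",
    "compare_measures",
    "run_main_analysis",
    "sensitivity",
    "compare_designs",
]

log = logging.getLogger("dlnmcc")

LAG_WINDOWS = ((0, 2), (0, 18), (0, 27))


@dataclass(frozen=True)
class AnalysisConfig:
    """Settings for a full analysis run."""

    outcomes: tuple[str, ...] = CAUSES
    measures: tuple[str, ...] = MEASURES
    measure: str = "tmean"
    temperature_df: int = 5
    lag_df: int = 4
    max_lag: int = 27
    strata: StrataSpec = field(default_factory=StrataSpec)
    cold_grid: tuple[float, float, float] = (-5.0, 5.0, 0.1)
    hot_grid: tuple[float, float, float] = (19.0, 29.0, 0.1)
    exhaustive_search: bool = False
    sensitivity_windows: tuple[int, ...] = (30, 28, 21)
    sensitivity_max_lags: tuple[int, ...] = (20, 30)
    time_spline_df_per_year: float = 7.0
    seed: int = 0

    def lag_spec(self, max_lag: int | None = None) -> LagSpec:
        return LagSpec.log_spline(max_lag or self.max_lag, self.lag_df)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "strata" in raw:
            raw["strata"] = StrataSpec(**raw["strata"])
        for key in ("outcomes", "measures", "sensitivity_windows",
                    "sensitivity_max_lags"):
            if key in raw:
                raw[key] = tuple(raw[key])
        for key in ("cold_grid", "hot_grid"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["strata"] = {"scheme": self.strata.scheme,
                       "window_days": self.strata.window_days}
        return d

    @property
    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _stamp(df: pd.DataFrame, config: AnalysisConfig) -> pd.DataFrame:
    df = df.copy()
    df.attrs["config_hash"] = config.hash
    df.attrs["package_version"] = __version__
    df["config_hash"] = config.hash
    df["version"] = __version__
    return df


def summarize_series(series: DailySeries) -> dict[str, pd.DataFrame]:
    """Descriptive statistics and Spearman correlations of the weather
    variables (constant columns report sd 0 and missing correlations)."""
    variables = ["tmax", "tmean", "tmin", "humidity", "pm10", "so2", "no2",
                 *series.causes]
    rows = []
    for var in variables:
        x = series.df[var].to_numpy(dtype=float)
        rows.append({
            "variable": var, "minimum": x.min(),
            "p25": np.percentile(x, 25), "median": np.median(x),
            "p75": np.percentile(x, 75), "maximum": x.max(),
            "mean": x.mean(), "sd": x.std(ddof=1),
        })
    summary = pd.DataFrame(rows)

    weather = ["tmax", "tmean", "tmin", "humidity"]
    corr = pd.DataFrame(index=weather, columns=weather, dtype=float)
    pvals = pd.DataFrame(index=weather, columns=weather, dtype=float)
    for a in weather:
        for b in weather:
            xa = series.df[a].to_numpy(dtype=float)
            xb = series.df[b].to_numpy(dtype=float)
            if np.std(xa) == 0 or np.std(xb) == 0:
                corr.loc[a, b] = np.nan
                pvals.loc[a, b] = np.nan
            else:
                rho, p = spearmanr(xa, xb)
                corr.loc[a, b] = rho
                pvals.loc[a, b] = p
    return {"summary": summary, "spearman": corr, "spearman_p": pvals}


def _fit_form(series: DailySeries, config: AnalysisConfig, measure: str,
              outcome: str, form: str, thresholds: ThresholdSpec | None = None,
              strata: StrataSpec | None = None,
              max_lag: int | None = None):
    """Fit either model form for one measure/outcome combination."""
    x = series.temperature(measure)
    lag = config.lag_spec(max_lag)
    if form == "spline":
        exposure = SplineSpec.for_range(float(x.min()), float(x.max()),
                                        config.temperature_df)
    elif form == "double_threshold":
        if thresholds is None:
            raise ValueError("double_threshold form needs thresholds")
        exposure = thresholds
    else:
        raise ValueError("form must be 'spline' or 'double_threshold'")
    model = TemperatureLagModel(series, outcome=outcome, measure=measure,
                                exposure=exposure, lag=lag,
                                strata=strata or config.strata)
    return model.fit()


def _search(series: DailySeries, config: AnalysisConfig, outcome: str,
            measure: str, strata: StrataSpec | None = None,
            max_lag: int | None = None):
    fn = search_thresholds if config.exhaustive_search else coarse_to_fine
    kwargs = dict(lag=config.lag_spec(max_lag), strata=strata or config.strata,
                  measure=measure)
    return fn(series, outcome, config.cold_grid, config.hot_grid, **kwargs)


def compare_measures(series: DailySeries, config: AnalysisConfig) -> pd.DataFrame:
    """QAIC for every temperature measure x cause x model form.

    The double-threshold form uses thresholds from a coarse deviance search
    per measure/cause.  The per-cause QAIC minimum is flagged.
    """
    rows = []
    for measure in config.measures:
        for cause in config.outcomes:
            for form in ("spline", "double_threshold"):
                try:
                    thr = None
                    if form == "double_threshold":
                        coarse = replace(config, exhaustive_search=False)
                        thr = _search(series, coarse, cause, measure).best
                    res = _fit_form(series, config, measure, cause, form,
                                    thresholds=thr)
                    rows.append({"measure": measure, "cause": cause,
                                 "form": form, "qaic": res.qaic,
                                 "converged": True})
                except Exception as exc:  # noqa: BLE001 - recorded, not fatal
                    log.warning("fit failed (%s, %s, %s): %s", measure, cause, form, exc)
                    rows.append({"measure": measure, "cause": cause,
                                 "form": form, "qaic": np.nan,
                                 "converged": False})
    table = pd.DataFrame(rows)
    table["best_for_cause"] = False
    for cause, sub in table.groupby("cause"):
        ok = sub.dropna(subset=["qaic"])
        if len(ok):
            table.loc[ok["qaic"].idxmin(), "best_for_cause"] = True
    return _stamp(table, config)


def _cumulative_table(series: DailySeries, config: AnalysisConfig,
                      fits: dict) -> pd.DataFrame:
    """Table-shaped cumulative cold/hot effects (per 1 degC exceedance) over
    the standard lag windows, with two-sided significance at p < 0.05."""
    rows = []
    for cause, res in fits.items():
        for side, estimand in (("cold", "per_degree_below_cold"),
                               ("hot", "per_degree_above_hot")):
            for window in LAG_WINDOWS:
                w = (window[0], min(window[1], res.spec.max_lag))
                eff = res.cumulative(estimand, w)
                rows.append({
                    "cause": cause, "effect": side,
                    "lag_window": f"{w[0]}-{w[1]}",
                    "percent_increase": round(eff.percent_increase, 2),
                    "ci95_lo": round(eff.ci95[0], 2),
                    "ci95_hi": round(eff.ci95[1], 2),
                    "p_value": eff.p_value,
                    "significant": eff.significant,
                })
    return pd.DataFrame(rows)


def run_main_analysis(series: DailySeries, config: AnalysisConfig,
                      out_dir=None) -> dict:
    """The full study workflow for the configured temperature measure.

    Stages per cause: spline-DLNM fit -> overall-effect curve -> threshold
    search -> double-threshold fit -> per-degree lag curves -> cumulative
    table over lag windows 0-2, 0-18 and 0-27.  Stage failures raise with
    the stage name; partial outputs are retained in the returned bundle.
    """
    bundle: dict = {"config": config.to_dict(), "config_hash": config.hash,
                    "version": __version__}
    stage = "summaries"
    try:
        bundle["summaries"] = summarize_series(series)
        stage = "spline_fit"
        spline_fits, curves, surfaces = {}, {}, {}
        for cause in config.outcomes:
            res = _fit_form(series, config, config.measure, cause, "spline")
            spline_fits[cause] = res
            curves[cause] = res.overall_effect()
            surfaces[cause] = res.predict_surface().to_frame()
        bundle["spline_fits"] = spline_fits
        bundle["overall_effect_curves"] = curves
        bundle["surfaces"] = surfaces

        stage = "threshold_search"
        searches = {c: _search(series, config, c, config.measure)
                    for c in config.outcomes}
        bundle["threshold_searches"] = searches

        stage = "double_threshold_fit"
        thr_fits = {c: _fit_form(series, config, config.measure, c,
                                 "double_threshold", thresholds=searches[c].best)
                    for c in config.outcomes}
        bundle["threshold_fits"] = thr_fits

        stage = "lag_curves"
        bundle["lag_curves"] = {
            c: {side: exceedance_lag_curve(r.fit_result, r.spec, side)
                for side in ("cold", "hot")}
            for c, r in thr_fits.items()}

        stage = "cumulative_table"
        bundle["cumulative_table"] = _stamp(
            _cumulative_table(series, config, thr_fits), config)
    except Exception as exc:
        raise RuntimeError(f"main analysis failed at stage '{stage}': {exc}") from exc

    if out_dir is not None:
        _write_bundle(bundle, Path(out_dir), config)
    return bundle


def _write_bundle(bundle: dict, out: Path, config: AnalysisConfig) -> None:
    out.mkdir(parents=True, exist_ok=True)
    bundle["cumulative_table"].to_csv(out / "cumulative_effects.csv", index=False)
    for cause, curve in bundle["overall_effect_curves"].items():
        _stamp(curve, config).to_csv(out / f"overall_effect_{cause}.csv", index=False)
    for cause, surf in bundle["surfaces"].items():
        _stamp(surf, config).to_csv(out / f"surface_{cause}.csv", index=False)
    for cause, res in bundle["threshold_searches"].items():
        _stamp(res.deviance_grid, config).to_csv(
            out / f"deviance_grid_{cause}.csv", index=False)
    thr = {c: {"cold": r.best.cold_threshold, "hot": r.best.hot_threshold,
               "n_fits": r.n_fits}
           for c, r in bundle["threshold_searches"].items()}
    fits = {c: r.fit_result.to_dict() for c, r in bundle["threshold_fits"].items()}
    (out / "run.json").write_text(json.dumps(
        {"config": bundle["config"], "config_hash": bundle["config_hash"],
         "version": bundle["version"], "thresholds": thr,
         "threshold_fits": fits}, indent=2, default=str))


def sensitivity(series: DailySeries, config: AnalysisConfig,
                outcome: str = "nonaccidental") -> pd.DataFrame:
    """Cumulative cold (0-18) and hot (0-2) effects under the baseline
    settings and each alternative referent window / maximum lag.

    Thresholds are re-searched per setting; "similar results" is reported
    as overlap of each setting's 95% CI with the baseline's.
    """
    settings = [("baseline", config.strata, config.max_lag)]
    for w in config.sensitivity_windows:
        settings.append((f"window_{w}d",
                         StrataSpec(scheme="fixed_window", window_days=w),
                         config.max_lag))
    for L in config.sensitivity_max_lags:
        settings.append((f"max_lag_{L}", config.strata, L))

    rows = []
    for name, strata, max_lag in settings:
        best = _search(series, config, outcome, config.measure,
                       strata=strata, max_lag=max_lag).best
        res = _fit_form(series, config, config.measure, outcome,
                        "double_threshold", thresholds=best,
                        strata=strata, max_lag=max_lag)
        for side, estimand, window in (
                ("cold", "per_degree_below_cold", (0, 18)),
                ("hot", "per_degree_above_hot", (0, 2))):
            eff = res.cumulative(estimand, (window[0], min(window[1], max_lag)))
            rows.append({
                "setting": name, "effect": side,
                "strata_scheme": strata.scheme,
                "window_days": strata.window_days if strata.scheme == "fixed_window" else np.nan,
                "max_lag": max_lag,
                "cold_threshold": best.cold_threshold,
                "hot_threshold": best.hot_threshold,
                "percent_increase": eff.percent_increase,
                "ci95_lo": eff.ci95[0], "ci95_hi": eff.ci95[1],
            })
    table = pd.DataFrame(rows)
    # CI overlap with the baseline estimate of the same effect
    overlap = []
    for _, row in table.iterrows():
        base = table[(table["setting"] == "baseline")
                     & (table["effect"] == row["effect"])].iloc[0]
        overlap.append(not (row["ci95_hi"] < base["ci95_lo"]
                            or row["ci95_lo"] > base["ci95_hi"]))
    table["ci_overlaps_baseline"] = overlap
    return _stamp(table, config)


def compare_designs(series: DailySeries, config: AnalysisConfig) -> pd.DataFrame:
    """Case-crossover (stratum indicators) vs time-series (smooth time
    spline, 7 df/year by default): QAIC and mean absolute deviance residual
    per cause, both designs fitted on the same rows."""
    rows = []
    for cause in config.outcomes:
        cc = _fit_form(series, config, config.measure, cause, "spline")
        ts = _fit_time_spline(series, config, cause)
        for design, res in (("case_crossover", cc), ("time_spline", ts)):
            fr = res.fit_result
            mad = _mean_abs_deviance_residual(fr)
            rows.append({"cause": cause, "design": design, "qaic": fr.qaic,
                         "mean_abs_dev_resid": mad, "n_used": fr.n_used,
                         "lag1_resid_autocorr": _resid_autocorr(fr)})
    return _stamp(pd.DataFrame(rows), config)


def _mean_abs_deviance_residual(fr) -> float:
    y, mu = fr.response, fr.fitted
    with np.errstate(divide="ignore", invalid="ignore"):
        ylogy = np.where(y > 0, y * np.log(y / mu), 0.0)
    d = 2.0 * (ylogy - (y - mu))
    return float(np.mean(np.sqrt(np.maximum(d, 0.0))))


def _resid_autocorr(fr) -> float:
    y, mu = fr.response, fr.fitted
    r = (y - mu) / np.sqrt(mu)
    r = r - r.mean()
    return float(np.sum(r[1:] * r[:-1]) / np.sum(r * r))


def _fit_time_spline(series: DailySeries, config: AnalysisConfig, cause: str):
    """Time-series comparison fit: Eq.-style covariates with a smooth time
    spline instead of referent strata."""
    from .ccmodel import (build_design, fit_quasipoisson, make_strata,
                          time_spline_design)
    from .crossbasis import build_crossbasis
    from .model import TemperatureLagResults

    x = series.temperature(config.measure)
    exposure = SplineSpec.for_range(float(x.min()), float(x.max()),
                                    config.temperature_df)
    model = TemperatureLagModel(series, outcome=cause, measure=config.measure,
                                exposure=exposure, lag=config.lag_spec(),
                                strata=config.strata)
    cb = build_crossbasis(x, model.crossbasis_spec)
    strata = make_strata(series.dates, model.strata_spec)
    T, tnames = time_spline_design(series.dates, config.time_spline_df_per_year)
    y, X, names, used, _ = build_design(series, cb, strata, cause,
                                        include_strata=False,
                                        time_spline=T, time_spline_names=tnames)
    fit = fit_quasipoisson(y, X, names=names)
    return TemperatureLagResults(model, fit)
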