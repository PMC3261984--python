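"""Relative-risk summaries of a fitted cross-basis: exposure-lag surfaces,
lag and temperature slices, and cumulative effects over lag windows.

All effects are reported against the centering temperature of the
cross-basis, so RR = 1 at the centering value by construction.  Cumulative
effects sum the per-lag log relative risks over an inclusive lag window;
variances come from the delta method (the quadratic form of the summed
weight vector with the cross-basis coefficient covariance), and 95%
confidence intervals are normal on the log-RR scale, then transformed to
the percent-increase scale: ``100 * (exp(log RR) - 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .basis import ThresholdSpec
from .ccmodel import FitResult
from .crossbasis import CrossBasisSpec, exceedance_vector, prediction_vector

__all__ = [
    "EffectSurface",
    "CumulativeEffect",
    "predict_surface",
    "lag_slice",
    "temp_slice",
    "cumulative_effect",
    "overall_effect_curve",
]


def _cb_block(fit: FitResult) -> tuple[np.ndarray, np.ndarray]:
    params, cov = fit.param_block("cb_")
    return params.to_numpy(), cov.to_numpy()


@dataclass
class EffectSurface:
    """Log-RR grid over (temperature, lag) with pointwise standard errors."""

    temperatures: np.ndarray
    lags: np.ndarray
    log_rr: np.ndarray          # n_temps x n_lags
    se: np.ndarray
    center: float
    extrapolated: np.ndarray    # bool per temperature, outside basis boundary

    @property
    def rr(self) -> np.ndarray:
        return np.exp(self.log_rr)

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: one row per (temperature, lag) with RR and 95% CI."""
        t, l = np.meshgrid(self.temperatures, self.lags, indexing="ij")
        z = norm.ppf(0.975)
        return pd.DataFrame({
            "temperature": t.ravel(),
            "lag": l.ravel(),
            "rr": np.exp(self.log_rr).ravel(),
            "rr_lo95": np.exp(self.log_rr - z * self.se).ravel(),
            "rr_hi95": np.exp(self.log_rr + z * self.se).ravel(),
            "extrapolated": np.repeat(self.extrapolated, len(self.lags)),
        })


@dataclass
class CumulativeEffect:
    """Percent increase in mortality summed over a lag window, with 95% CI."""

    lag_range: tuple[int, int]
    estimand: dict | str
    log_rr: float
    se: float
    percent_increase: float
    ci95: tuple[float, float]
    z: float
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05

    def to_dict(self) -> dict:
        return {
            "lag_range": f"{self.lag_range[0]}-{self.lag_range[1]}",
            "estimand": str(self.estimand),
            "percent_increase": round(self.percent_increase, 2),
            "ci95_lo": round(self.ci95[0], 2),
            "ci95_hi": round(self.ci95[1], 2),
            "p_value": self.p_value,
            "significant": self.significant,
        }


def predict_surface(fit: FitResult, spec: CrossBasisSpec,
                    temp_grid=None, lag_grid=None) -> EffectSurface:
    """Predicted log-RR surface over a temperature grid and integer lags.

    Temperatures beyond the basis boundary knots are computed by the basis'
    linear extrapolation and flagged in ``extrapolated``.
    """
    if temp_grid is None:
        lo, hi = _exposure_range(spec)
        temp_grid = np.round(np.arange(lo, hi + 1e-9, 0.1), 6)
    temp_grid = np.asarray(temp_grid, dtype=float)
    if lag_grid is None:
        lag_grid = np.arange(spec.max_lag + 1)
    lag_grid = np.asarray(lag_grid, dtype=int)

    beta, cov = _cb_block(fit)
    E = spec.exposure_values(temp_grid) - spec.exposure_values(np.array([spec.center]))
    B = spec.lag_values()[lag_grid]      # L x K
    J = spec.exposure.n_columns
    K = spec.lag.n_columns
    bmat = beta.reshape(J, K)
    log_rr = E @ bmat @ B.T              # T x L
    C4 = cov.reshape(J, K, J, K)
    var = np.einsum("aj,bk,jkmn,am,bn->ab", E, B, C4, E, B)
    se = np.sqrt(np.maximum(var, 0.0))

    lo_b, hi_b = _exposure_range(spec)
    extrapolated = (temp_grid < lo_b) | (temp_grid > hi_b)
    return EffectSurface(temperatures=temp_grid, lags=lag_grid,
                         log_rr=log_rr, se=se, center=spec.center,
                         extrapolated=extrapolated)


def _exposure_range(spec: CrossBasisSpec) -> tuple[float, float]:
    exp_spec = spec.exposure
    if isinstance(exp_spec, ThresholdSpec):
        return exp_spec.cold_threshold - 10.0, exp_spec.hot_threshold + 10.0
    return exp_spec.boundary_knots


def _nearest_index(grid: np.ndarray, value: float, what: str) -> int:
    i = int(np.argmin(np.abs(grid - value)))
    if abs(grid[i] - value) > 1e-9:
        raise ValueError(
            f"{what}={value} is not on the grid; nearest grid value is {grid[i]} "
            "(no silent interpolation)"
        )
    return i


def lag_slice(surface: EffectSurface, at_temperature: float) -> pd.DataFrame:
    """Per-lag RR curve at one temperature (must lie on the surface grid)."""
    i = _nearest_index(surface.temperatures, at_temperature, "temperature")
    z = norm.ppf(0.975)
    lr, se = surface.log_rr[i], surface.se[i]
    return pd.DataFrame({"lag": surface.lags, "rr": np.exp(lr),
                         "rr_lo95": np.exp(lr - z * se),
                         "rr_hi95": np.exp(lr + z * se)})


def temp_slice(surface: EffectSurface, at_lag: int) -> pd.DataFrame:
    """Per-temperature RR curve at one lag (must lie on the surface lag grid)."""
    j = _nearest_index(surface.lags.astype(float), float(at_lag), "lag")
    z = norm.ppf(0.975)
    lr, se = surface.log_rr[:, j], surface.se[:, j]
    return pd.DataFrame({"temperature": surface.temperatures, "rr": np.exp(lr),
                         "rr_lo95": np.exp(lr - z * se),
                         "rr_hi95": np.exp(lr + z * se)})


def exceedance_lag_curve(fit: FitResult, spec: CrossBasisSpec, side: str) -> pd.DataFrame:
    """Per-lag RR for a 1 degC threshold exceedance (threshold models only)."""
    beta, cov = _cb_block(fit)
    rows = []
    z = norm.ppf(0.975)
    for l in range(spec.max_lag + 1):
        w = exceedance_vector(spec, side, l)
        lr = float(w @ beta)
        se = float(np.sqrt(max(w @ cov @ w, 0.0)))
        rows.append((l, np.exp(lr), np.exp(lr - z * se), np.exp(lr + z * se)))
    return pd.DataFrame(rows, columns=["lag", "rr", "rr_lo95", "rr_hi95"])


def cumulative_effect(fit: FitResult, spec: CrossBasisSpec,
                      estimand, lag_range: tuple[int, int]) -> CumulativeEffect:
    """Cumulative effect over an inclusive lag window.

    ``estimand`` is ``{"at_temperature": x}`` for spline models, or
    ``"per_degree_below_cold"`` / ``"per_degree_above_hot"`` for threshold
    models (percent change per 1 degC beyond the threshold).
    """
    l0, l1 = lag_range
    if l0 > l1:
        raise ValueError("empty lag range")
    if l0 < 0 or l1 > spec.max_lag:
        raise ValueError(f"lag range {lag_range} outside 0..{spec.max_lag}")

    if isinstance(estimand, dict) and "at_temperature" in estimand:
        per_lag = lambda l: prediction_vector(spec, estimand["at_temperature"], l)
    elif estimand == "per_degree_below_cold":
        per_lag = lambda l: exceedance_vector(spec, "cold", l)
    elif estimand == "per_degree_above_hot":
        per_lag = lambda l: exceedance_vector(spec, "hot", l)
    else:
        raise ValueError(f"unknown estimand: {estimand!r}")

    w = np.sum([per_lag(l) for l in range(l0, l1 + 1)], axis=0)
    beta, cov = _cb_block(fit)
    lr = float(w @ beta)
    var = float(w @ cov @ w)
    se = float(np.sqrt(max(var, 0.0)))
    zq = norm.ppf(0.975)
    ci = (100.0 * (np.exp(lr - zq * se) - 1.0), 100.0 * (np.exp(lr + zq * se) - 1.0))
    z = lr / se if se > 0 else (0.0 if lr == 0 else np.inf * np.sign(lr))
    p = 2.0 * norm.sf(abs(z)) if np.isfinite(z) else 0.0
    if se == 0 and lr == 0:
        p = 1.0
    return CumulativeEffect(lag_range=(l0, l1), estimand=estimand,
                            log_rr=lr, se=se,
                            percent_increase=100.0 * (np.exp(lr) - 1.0),
                            ci95=ci, z=z, p_value=p)


def overall_effect_curve(fit: FitResult, spec: CrossBasisSpec,
                         temp_grid=None) -> pd.DataFrame:
    """Overall (lag-cumulated) RR by temperature: the U-shaped curve summing
    log-RRs over all lags 0..max_lag at each temperature."""
    if temp_grid is None:
        lo, hi = _exposure_range(spec)
        temp_grid = np.round(np.arange(lo, hi + 1e-9, 0.1), 6)
    rows = []
    for x in np.asarray(temp_grid, dtype=float):
        eff = cumulative_effect(fit, spec, {"at_temperature": float(x)},
                                (0, spec.max_lag))
        z = norm.ppf(0.975)
        rows.append((x, np.exp(eff.log_rr),
                     np.exp(eff.log_rr - z * eff.se),
                     np.exp(eff.log_rr + z * eff.se)))
    return pd.DataFrame(rows, columns=["temperature", "rr", "rr_lo95", "rr_hi95"])


def plot_overall_effect(curve: pd.DataFrame, ax=None, title: str | None = None):
    """Plot the overall-effect RR curve with its 95% band."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.fill_between(curve["temperature"], curve["rr_lo95"], curve["rr_hi95"],
                    alpha=0.3, color="tab:blue")
    ax.plot(curve["temperature"], curve["rr"], color="black")
    ax.axhline(1.0, lw=0.5, color="grey")
    ax.set_xlabel("temperature (°C)")
    ax.set_ylabel("relative risk")
    if title:
        ax.set_title(title)
    return ax


def plot_lag_curve(curve: pd.DataFrame, ax=None, title: str | None = None):
    """Plot a per-lag RR curve (e.g. per 1 degC threshold exceedance)."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.fill_between(curve["lag"], curve["rr_lo95"], curve["rr_hi95"],
                    alpha=0.3, color="tab:blue")
    ax.plot(curve["lag"], curve["rr"], color="black")
    ax.axhline(1.0, lw=0.5, color="grey")
    ax.set_xlabel("lag (days)")
    ax.set_ylabel("relative risk")
    if title:
        ax.set_title(title)
    return ax
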