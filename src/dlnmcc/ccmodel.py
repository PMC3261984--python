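"""Time-stratified case-crossover model: strata construction, covariate
design, overdispersed (quasi-)Poisson fitting, and QAIC.

The design follows the standard log-linear formulation of the
time-stratified case-crossover: daily death counts are modelled as
overdispersed Poisson with a log link,

    log mu_t = alpha + cross-basis block
               + ns(humidity, 3) + ns(PM10, 3) + ns(SO2, 3) + ns(NO2, 3)
               + day-of-week + holiday + influenza + stratum indicators,

where the strata are disjoint calendar months (or fixed-length windows),
so season and trend are controlled by design.  Two equivalent fitting
routes are provided: quasi-Poisson IRLS with explicit stratum indicators,
and a conditional Poisson likelihood that eliminates the stratum
intercepts analytically (identical slope estimates and profile
covariance — the model equivalence that makes the case-crossover a
special case of time-series regression).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import qr as _qr
from scipy.special import gammaln

from .basis import SplineSpec, ns_basis
from .crossbasis import CrossBasisMatrix

__all__ = [
    "DailySeries",
    "StrataSpec",
    "FitResult",
    "make_strata",
    "build_design",
    "fit_quasipoisson",
    "fit_conditional",
    "qaic",
    "time_spline_design",
    "CAUSES",
]

CAUSES = ("nonaccidental", "cardiopulmonary", "cardiovascular", "respiratory")
MEASURES = ("tmax", "tmean", "tmin")

_REQUIRED = ("date", "tmax", "tmean", "tmin", "humidity",
             "pm10", "so2", "no2", "holiday", "influenza")

DEFAULT_COLUMNS = {c: c for c in _REQUIRED} | {c: c for c in CAUSES}


class DailySeries:
    """Validated daily table of death counts, temperatures and covariates.

    Wraps a DataFrame with columns ``date``, one count column per cause,
    ``tmax/tmean/tmin`` (degC), ``humidity`` (%), ``pm10/so2/no2``,
    ``holiday`` and ``influenza`` (0/1).  Dates must be consecutive days;
    day-of-week is derived from the date.
    """

    def __init__(self, df: pd.DataFrame):
        df = df.copy()
        df["date"] = pd.to_datetime(df["date"])
        missing = [c for c in _REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"missing required columns: {missing}")
        causes = [c for c in CAUSES if c in df.columns]
        if not causes:
            raise ValueError("no death-count columns found")
        deltas = df["date"].diff().dropna()
        if (deltas != pd.Timedelta(days=1)).any():
            raise ValueError("dates must be consecutive days without duplicates or gaps")
        for c in causes:
            col = df[c].to_numpy()
            if (col < 0).any() or not np.allclose(col, np.round(col)):
                raise ValueError(f"death counts in '{c}' must be non-negative integers")
        for c in ("holiday", "influenza"):
            if not df[c].isin([0, 1]).all():
                raise ValueError(f"'{c}' must be binary 0/1")
        df["dow"] = df["date"].dt.dayofweek
        self.df = df
        self.causes = tuple(causes)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def dates(self) -> pd.Series:
        return self.df["date"]

    def counts(self, cause: str) -> np.ndarray:
        if cause not in self.causes:
            raise KeyError(f"unknown cause '{cause}' (have {self.causes})")
        return self.df[cause].to_numpy(dtype=float)

    def temperature(self, measure: str) -> np.ndarray:
        if measure not in MEASURES:
            raise KeyError(f"unknown temperature measure '{measure}'")
        return self.df[measure].to_numpy(dtype=float)

    @classmethod
    def from_csv(cls, path, columns: dict | None = None) -> "DailySeries":
        """Read a CSV with ISO-8601 dates; ``columns`` maps standard names to
        the file's column names."""
        df = pd.read_csv(path)
        if columns:
            df = df.rename(columns={v: k for k, v in columns.items()})
        return cls(df)

    def to_csv(self, path) -> None:
        out = self.df.drop(columns=["dow"])
        out.to_csv(path, index=False)


@dataclass(frozen=True)
class StrataSpec:
    """Referent-window scheme: calendar month, or fixed disjoint windows."""

    scheme: str = "calendar_month"
    window_days: int = 28

    def __post_init__(self) -> None:
        if self.scheme not in ("calendar_month", "fixed_window"):
            raise ValueError("scheme must be 'calendar_month' or 'fixed_window'")
        if self.scheme == "fixed_window" and self.window_days < 2:
            raise ValueError("window_days must be >= 2")


def make_strata(dates: pd.Series, spec: StrataSpec) -> pd.Series:
    """Assign each day to a disjoint referent stratum.

    ``calendar_month`` labels by (year, month); ``fixed_window`` cuts
    consecutive blocks of ``window_days`` anchored at the first date (the
    last block may be short).  The labels partition the series.
    """
    dates = pd.to_datetime(pd.Series(dates).reset_index(drop=True))
    if dates.empty:
        raise ValueError("empty date vector")
    if spec.scheme == "calendar_month":
        labels = dates.dt.strftime("%Y-%m")
    else:
        idx = np.arange(len(dates)) // spec.window_days
        labels = pd.Series([f"w{int(i):04d}" for i in idx])
    return labels.rename("stratum")


@dataclass
class FitResult:
    """Coefficients, covariance and fit statistics from one model fit.

    ``dispersion`` is the Pearson-based quasi-Poisson scale; ``llf`` is the
    Poisson log-likelihood at the fitted means (used by QAIC); covariance
    is already scaled by the dispersion.
    """

    params: pd.Series
    cov: pd.DataFrame
    dispersion: float
    llf: float
    deviance: float
    n_used: int
    df_model: int
    fitted: np.ndarray
    converged: bool
    n_iter: int
    method: str
    meta: dict = field(default_factory=dict)
    response: np.ndarray | None = None

    @property
    def qaic(self) -> float:
        return qaic(self)

    def param_block(self, prefix: str) -> tuple[pd.Series, pd.DataFrame]:
        """Coefficient sub-vector and covariance block for names starting with prefix."""
        names = [n for n in self.params.index if n.startswith(prefix)]
        return self.params.loc[names], self.cov.loc[names, names]

    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov.to_numpy())), index=self.params.index)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "coefficients": self.params.to_dict(),
            "dispersion": self.dispersion,
            "loglik": self.llf,
            "residual_deviance": self.deviance,
            "qaic": self.qaic,
            "n_used": self.n_used,
            "df_model": self.df_model,
            "converged": self.converged,
            **self.meta,
        }


def qaic(fit: FitResult) -> float:
    """Quasi-AIC: ``-2 loglik + 2 * dispersion * n_params``."""
    return -2.0 * fit.llf + 2.0 * fit.dispersion * fit.df_model


def _poisson_llf(y: np.ndarray, mu: np.ndarray) -> float:
    return float(np.sum(y * np.log(mu) - mu - gammaln(y + 1.0)))


def _poisson_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        ylogy = np.where(y > 0, y * np.log(y / mu), 0.0)
    return float(2.0 * np.sum(ylogy - (y - mu)))


def _find_aliased(X: np.ndarray, names: Sequence[str]) -> list[str]:
    _, R, piv = _qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    return [names[piv[i]] for i in range(len(diag)) if diag[i] < tol]


def fit_quasipoisson(y, X, names: Sequence[str] | None = None,
                     tol: float = 1e-9, max_iter: int = 100) -> FitResult:
    """Poisson log-link fit by IRLS with Pearson-based dispersion.

    Convergence: relative change in deviance below ``tol`` (default 1e-9,
    at most 100 iterations).  The covariance is ``dispersion * (X'WX)^-1``.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if (y < 0).any():
        raise ValueError("negative counts")
    n, p = X.shape
    if names is None:
        names = [f"x{i}" for i in range(p)]
    names = list(names)
    # column scaling: spline columns of large covariates are cubic in the
    # raw values and wreck the conditioning of the normal equations
    scale = np.maximum(np.max(np.abs(X), axis=0), 1e-12)
    Xs = X / scale
    if np.linalg.matrix_rank(Xs) < p:
        raise ValueError(f"design matrix is rank deficient; aliased columns: {_find_aliased(Xs, names)}")
    X = Xs

    mu = np.clip(y, 0.5, None)
    eta = np.log(mu)
    dev = _poisson_deviance(y, mu)
    beta = np.zeros(p)
    converged = False
    trace = []
    for it in range(1, max_iter + 1):
        W = mu
        z = eta + (y - mu) / mu
        XtW = X.T * W
        beta = np.linalg.solve(XtW @ X, XtW @ z)
        eta = X @ beta
        eta = np.clip(eta, -30.0, 30.0)
        mu = np.exp(eta)
        new_dev = _poisson_deviance(y, mu)
        trace.append(new_dev)
        if abs(new_dev - dev) < tol * (abs(dev) + 0.1):
            dev = new_dev
            converged = True
            break
        dev = new_dev
    if not converged:
        raise RuntimeError(f"IRLS did not converge in {max_iter} iterations; deviance trace: {trace[-5:]}")

    pearson = float(np.sum((y - mu) ** 2 / mu))
    df_resid = n - p
    phi = pearson / df_resid if df_resid > 0 else np.nan
    XtWX = (X.T * mu) @ X
    cov = phi * np.linalg.inv(XtWX)
    beta = beta / scale
    cov = cov / np.outer(scale, scale)
    return FitResult(
        params=pd.Series(beta, index=names),
        cov=pd.DataFrame(cov, index=names, columns=names),
        dispersion=phi,
        llf=_poisson_llf(y, mu),
        deviance=dev,
        n_used=n,
        df_model=p,
        fitted=mu,
        converged=True,
        n_iter=it,
        method="quasipoisson_irls",
        meta={"qaic_formula": "-2*loglik + 2*dispersion*n_params",
              "dispersion_estimator": "pearson"},
        response=y,
    )


def fit_conditional(y, X, strata, names: Sequence[str] | None = None,
                    tol: float = 1e-10, max_iter: int = 60) -> FitResult:
    """Conditional Poisson fit eliminating the stratum intercepts.

    Maximizes ``sum_t y_t eta_t - sum_s Y_s log sum_{t in s} exp(eta_t)`` by
    Newton's method; the slope estimates and their profile covariance match
    the stratified-indicator quasi-Poisson fit exactly.  Strata with zero
    total count carry no information and are dropped.  The reported
    dispersion, log-likelihood and deviance use the profiled fitted means
    ``mu_t = Y_s * softmax(eta)_t`` and the same residual degrees of freedom
    as the indicator fit.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if (y < 0).any():
        raise ValueError("negative counts")
    n, p = X.shape
    if names is None:
        names = [f"x{i}" for i in range(p)]
    names = list(names)

    codes, uniques = pd.factorize(np.asarray(strata))
    Ys = np.bincount(codes, weights=y, minlength=len(uniques))
    keep = Ys[codes] > 0
    yk, Xk, ck = y[keep], X[keep], codes[keep]
    ck = pd.factorize(ck)[0]
    S = ck.max() + 1
    Ysk = np.bincount(ck, weights=yk, minlength=S)

    # centre columns within stratum (invariant for the conditional
    # likelihood) and rescale: spline columns of large covariates are cubic
    # in the raw values and ruin the Hessian conditioning otherwise
    col_means = np.zeros((S, p))
    np.add.at(col_means, ck, Xk)
    col_means /= np.bincount(ck, minlength=S)[:, None]
    Xc = Xk - col_means[ck]
    scale = np.maximum(np.max(np.abs(Xc), axis=0), 1e-12)
    Xc = Xc / scale

    def cond_ll(eta):
        m = np.full(S, -np.inf)
        np.maximum.at(m, ck, eta)
        e = np.exp(eta - m[ck])
        denom = np.zeros(S)
        np.add.at(denom, ck, e)
        ll = float(yk @ eta - Ysk @ (np.log(denom) + m))
        logp = eta - m[ck] - np.log(denom)[ck]
        mu = Ysk[ck] * np.exp(logp)
        return ll, mu

    beta = np.zeros(p)
    eta = Xc @ beta
    ll, mu = cond_ll(eta)
    converged = False
    for it in range(1, max_iter + 1):
        score = Xc.T @ (yk - mu)
        A = np.zeros((S, p))
        np.add.at(A, ck, Xc * mu[:, None])
        H = (Xc.T * mu) @ Xc - (A.T / Ysk) @ A
        H_reg = H + np.eye(p) * 1e-10 * max(np.trace(H) / p, 1.0)
        step = np.linalg.solve(H_reg, score)
        # step-halving safeguard
        for _ in range(30):
            beta_new = beta + step
            ll_new, mu_new = cond_ll(Xc @ beta_new)
            if ll_new >= ll - 1e-12:
                break
            step *= 0.5
        moved = abs(ll_new - ll)
        beta, ll, mu = beta_new, ll_new, mu_new
        if moved < tol * (abs(ll) + 0.1) and np.max(np.abs(score)) < 1e-6 * (1.0 + Ysk.sum()):
            converged = True
            break
    if not converged:
        raise RuntimeError(f"conditional Newton did not converge in {max_iter} iterations")

    score = Xc.T @ (yk - mu)
    A = np.zeros((S, p))
    np.add.at(A, ck, Xc * mu[:, None])
    H = (Xc.T * mu) @ Xc - (A.T / Ysk) @ A
    n_params = p + S  # slopes + profiled stratum intercepts
    df_resid = len(yk) - n_params
    pearson = float(np.sum((yk - mu) ** 2 / mu))
    phi = pearson / df_resid if df_resid > 0 else np.nan
    cov = phi * np.linalg.inv(H)
    beta = beta / scale
    cov = cov / np.outer(scale, scale)
    return FitResult(
        params=pd.Series(beta, index=names),
        cov=pd.DataFrame(cov, index=names, columns=names),
        dispersion=phi,
        llf=_poisson_llf(yk, mu),
        deviance=_poisson_deviance(yk, mu),
        n_used=len(yk),
        df_model=n_params,
        fitted=mu,
        converged=True,
        n_iter=it,
        method="conditional_poisson",
        meta={"qaic_formula": "-2*loglik + 2*dispersion*n_params",
              "dispersion_estimator": "pearson",
              "n_strata": int(S)},
        response=yk,
    )


def covariate_smooths(series: DailySeries, used: np.ndarray,
                      df: int = 3) -> tuple[np.ndarray, list[str]]:
    """Natural-spline smooths (default 3 df) of humidity and the three
    pollutants, knots at equal quantiles of each covariate on the used rows."""
    blocks, names = [], []
    for var in ("humidity", "pm10", "so2", "no2"):
        x = series.df[var].to_numpy(dtype=float)
        spec = SplineSpec.from_quantiles(x[used], df)
        blocks.append(ns_basis(x, spec))
        names.extend(f"{var}_s{i}" for i in range(df))
    return np.column_stack(blocks), names


def _calendar_columns(series: DailySeries) -> tuple[np.ndarray, list[str]]:
    dow = series.df["dow"].to_numpy()
    cols = [(dow == d).astype(float) for d in range(1, 7)]  # Monday is reference
    names = [f"dow_{d}" for d in range(1, 7)]
    cols.append(series.df["holiday"].to_numpy(dtype=float))
    names.append("holiday")
    cols.append(series.df["influenza"].to_numpy(dtype=float))
    names.append("influenza")
    return np.column_stack(cols), names


def build_design(series: DailySeries, crossbasis: CrossBasisMatrix,
                 strata: pd.Series, outcome: str,
                 include_strata: bool = True,
                 time_spline: np.ndarray | None = None,
                 time_spline_names: Sequence[str] | None = None):
    """Assemble response and design on the rows with complete lag history.

    Columns: intercept, cross-basis block, four 3-df confounder smooths,
    six day-of-week indicators, holiday, influenza, and either
    reference-coded stratum indicators (case-crossover) or a smooth
    time spline (time-series comparison design).

    Returns ``(y, X, names, used, strata_used)``.
    """
    if len(series) != crossbasis.values.shape[0]:
        raise ValueError("series and cross-basis have different lengths")
    used = crossbasis.complete
    y = series.counts(outcome)[used]

    cov_block, cov_names = covariate_smooths(series, used)
    cal_block, cal_names = _calendar_columns(series)

    cols = [np.ones(len(series)), crossbasis.values, cov_block, cal_block]
    names = ["intercept", *crossbasis.names, *cov_names, *cal_names]

    if include_strata:
        labels = pd.Series(strata).reset_index(drop=True)
        used_levels = list(pd.unique(labels[used]))
        ind = np.column_stack([(labels == lev).to_numpy(dtype=float)
                               for lev in used_levels[1:]]) if len(used_levels) > 1 \
            else np.empty((len(series), 0))
        cols.append(ind)
        names.extend(f"stratum_{lev}" for lev in used_levels[1:])
    if time_spline is not None:
        cols.append(time_spline)
        names.extend(time_spline_names or
                     [f"time_s{i}" for i in range(time_spline.shape[1])])

    X = np.column_stack([c if c.ndim == 2 else c[:, None] for c in cols])[used]
    strata_used = pd.Series(strata).reset_index(drop=True)[used].to_numpy()
    return y, X, names, used, strata_used


def time_spline_design(dates: pd.Series, df_per_year: float) -> tuple[np.ndarray, list[str]]:
    """Natural cubic spline of the day index with ``round(df_per_year * years)``
    df, for the time-series comparison design."""
    if df_per_year <= 0:
        raise ValueError("df_per_year must be positive")
    n = len(dates)
    n_years = n / 365.25
    df = max(1, round(df_per_year * n_years))
    t = np.arange(n, dtype=float)
    spec = SplineSpec.for_range(0.0, float(n - 1), df)
    return ns_basis(t, spec), [f"time_s{i}" for i in range(df)]
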