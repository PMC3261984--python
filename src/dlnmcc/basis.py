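"""One-dimensional bases for the temperature and lag dimensions.

Three building blocks are provided:

* natural cubic splines with explicit knots (used for the non-linear
  temperature-response, the lag-response, and the confounder smooths),
* linear-threshold ("hockey-stick") transforms for the double-threshold
  exposure-response, and
* the knot-placement rules used throughout: equally spaced knots over the
  exposure range, and knots equally spaced on the log-lag axis so that
  short delays get more flexibility than long ones.

The natural cubic spline uses the truncated-power parameterization
(columns ``x`` and ``d_k(x) - d_{K-1}(x)``), which is linear beyond the
boundary knots by construction and spans the usual natural-spline space:
``df`` columns for ``df - 1`` interior knots, no intercept column.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SplineSpec",
    "ThresholdSpec",
    "LagSpec",
    "equally_spaced_knots",
    "log_spaced_lag_knots",
    "ns_basis",
    "threshold_basis",
    "lag_basis",
]


def _check_finite(x: np.ndarray, what: str = "x") -> None:
    bad = ~np.isfinite(x)
    if bad.any():
        idx = int(np.flatnonzero(bad)[0])
        raise ValueError(f"non-finite value in {what} at index {idx}")


def equally_spaced_knots(lo: float, hi: float, df: int) -> list[float]:
    """Interior knots splitting ``[lo, hi]`` into ``df`` equal sub-intervals.

    Returns ``df - 1`` knots, excluding the endpoints.  ``df < 2`` yields an
    empty list (a linear basis needs no interior knots).
    """
    if not (lo < hi):
        raise ValueError(f"invalid range: lo={lo} must be < hi={hi}")
    if df < 2:
        return []
    step = (hi - lo) / df
    return [lo + step * i for i in range(1, df)]


def log_spaced_lag_knots(max_lag: int, df: int) -> list[float]:
    """Lag knots equally spaced on the log scale between lag 1 and ``max_lag``.

    The lag basis carries an intercept column, so a ``df``-column lag basis
    needs ``df - 2`` interior knots.  Knots are placed at
    ``exp(equally spaced values of log-lag)``; lag 0 is covered by the basis
    itself, not by a knot.
    """
    if max_lag < 1:
        raise ValueError(f"invalid range: max_lag={max_lag} must be >= 1")
    if df < 3:
        return []
    n_knots = df - 2
    # equally spaced in log between log(1)=0 and log(max_lag)
    pts = np.linspace(0.0, np.log(max_lag), n_knots + 2)[1:-1]
    return list(np.exp(pts))


@dataclass(frozen=True)
class SplineSpec:
    """Natural cubic spline with explicit interior and boundary knots.

    ``df`` equals the number of basis columns; for a natural cubic spline
    without intercept this is (number of interior knots) + 1.  ``scale``
    records the axis on which the knots were placed (informational).
    """

    df: int
    interior_knots: tuple[float, ...]
    boundary_knots: tuple[float, float]
    scale: str = "natural"

    def __post_init__(self) -> None:
        if self.df < 1:
            raise ValueError("df must be a positive integer")
        ik = tuple(float(k) for k in self.interior_knots)
        object.__setattr__(self, "interior_knots", ik)
        lo, hi = self.boundary_knots
        if not lo < hi:
            raise ValueError("boundary knots must satisfy lo < hi")
        if any(k2 <= k1 for k1, k2 in zip(ik, ik[1:])):
            raise ValueError("interior knots must be strictly increasing")
        if ik and not (lo < ik[0] and ik[-1] < hi):
            raise ValueError("interior knots must lie strictly inside the boundary knots")
        if self.df != len(ik) + 1:
            raise ValueError(
                f"df={self.df} inconsistent with {len(ik)} interior knots "
                "(natural spline: df = interior knots + 1)"
            )
        if self.scale not in ("natural", "log"):
            raise ValueError("scale must be 'natural' or 'log'")

    @classmethod
    def for_range(cls, lo: float, hi: float, df: int) -> "SplineSpec":
        """Spec with ``df - 1`` equally spaced interior knots over ``[lo, hi]``."""
        return cls(df=df, interior_knots=tuple(equally_spaced_knots(lo, hi, df)),
                   boundary_knots=(float(lo), float(hi)))

    @classmethod
    def from_quantiles(cls, x, df: int) -> "SplineSpec":
        """Spec with interior knots at equal quantiles of ``x`` (confounder smooths)."""
        x = np.asarray(x, dtype=float)
        qs = np.linspace(0, 1, df + 1)[1:-1]
        knots = tuple(float(q) for q in np.quantile(x, qs))
        return cls(df=df, interior_knots=knots,
                   boundary_knots=(float(x.min()), float(x.max())))

    @property
    def n_columns(self) -> int:
        return self.df


@dataclass(frozen=True)
class ThresholdSpec:
    """Double linear-threshold exposure: linear below cold, linear above hot."""

    cold_threshold: float
    hot_threshold: float

    def __post_init__(self) -> None:
        if not self.cold_threshold < self.hot_threshold:
            raise ValueError(
                f"cold threshold ({self.cold_threshold}) must be below "
                f"hot threshold ({self.hot_threshold})"
            )

    @property
    def n_columns(self) -> int:
        return 2


@dataclass(frozen=True)
class LagSpec:
    """Basis over lags 0..max_lag.

    ``ns_log``: intercept + natural cubic spline of lag with knots on the
    log-lag axis (``df`` total columns, ``df - 2`` interior knots).
    ``indicator``: one column per lag (testing oracle only).
    """

    max_lag: int
    df: int
    knots: tuple[float, ...] = field(default=())
    kind: str = "ns_log"

    def __post_init__(self) -> None:
        if self.max_lag < 0:
            raise ValueError("max_lag must be non-negative")
        if self.df < 1:
            raise ValueError("df must be a positive integer")
        if self.kind not in ("ns_log", "indicator"):
            raise ValueError("kind must be 'ns_log' or 'indicator'")
        object.__setattr__(self, "knots", tuple(float(k) for k in self.knots))
        if self.kind == "indicator":
            if self.df != self.max_lag + 1:
                raise ValueError("indicator lag basis needs df = max_lag + 1")
        else:
            if any(not (0.0 < k < self.max_lag) for k in self.knots):
                raise ValueError("lag knots must lie in (0, max_lag)")
            if self.df >= 3 and len(self.knots) != self.df - 2:
                raise ValueError(
                    f"df={self.df} lag basis needs {self.df - 2} knots, got {len(self.knots)}"
                )

    @classmethod
    def log_spline(cls, max_lag: int, df: int) -> "LagSpec":
        """The standard lag spec: log-equispaced knots, intercept included."""
        return cls(max_lag=max_lag, df=df,
                   knots=tuple(log_spaced_lag_knots(max_lag, df)), kind="ns_log")

    @classmethod
    def indicator(cls, max_lag: int) -> "LagSpec":
        return cls(max_lag=max_lag, df=max_lag + 1, kind="indicator")

    @property
    def n_columns(self) -> int:
        return self.df


def ns_basis(x, spec: SplineSpec) -> np.ndarray:
    """Natural cubic spline basis, ``len(x) x spec.df``.

    Continuous with continuous first and second derivatives at the knots and
    linear (zero second derivative) outside the boundary knots; values beyond
    the boundary knots are therefore linear extrapolations.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        return np.empty((0, spec.df))
    _check_finite(x)
    lo, hi = spec.boundary_knots
    knots = np.array([lo, *spec.interior_knots, hi])  # K = df + 1 knots
    K = len(knots)
    cols = [x]
    if K >= 3:
        def d(k_idx: int) -> np.ndarray:
            num = (np.maximum(x - knots[k_idx], 0.0) ** 3
                   - np.maximum(x - knots[K - 1], 0.0) ** 3)
            return num / (knots[K - 1] - knots[k_idx])

        d_last = d(K - 2)
        for k_idx in range(K - 2):
            cols.append(d(k_idx) - d_last)
    return np.column_stack(cols)


def threshold_basis(x, spec: ThresholdSpec) -> np.ndarray:
    """Two hinge columns: ``max(cold - x, 0)`` and ``max(x - hot, 0)``.

    A coefficient on the first column is the log-RR per 1 degC *decrease*
    below the cold threshold; on the second, per 1 degC increase above the
    hot threshold.  Both columns vanish in the comfort band between them.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        return np.empty((0, 2))
    _check_finite(x)
    cold = np.maximum(spec.cold_threshold - x, 0.0)
    hot = np.maximum(x - spec.hot_threshold, 0.0)
    return np.column_stack([cold, hot])


def exposure_basis(x, spec) -> np.ndarray:
    """Dispatch on the exposure spec type (spline or double threshold)."""
    if isinstance(spec, SplineSpec):
        return ns_basis(x, spec)
    if isinstance(spec, ThresholdSpec):
        return threshold_basis(x, spec)
    raise TypeError(f"unsupported exposure spec: {type(spec).__name__}")


def lag_basis(spec: LagSpec) -> np.ndarray:
    """Lag basis evaluated at integer lags 0..max_lag, ``(max_lag+1) x df``."""
    lags = np.arange(spec.max_lag + 1, dtype=float)
    if spec.kind == "indicator":
        return np.eye(spec.max_lag + 1)
    if spec.df == 1:
        return np.ones((spec.max_lag + 1, 1))
    sub = SplineSpec(df=spec.df - 1, interior_knots=spec.knots,
                     boundary_knots=(0.0, float(spec.max_lag)), scale="log")
    return np.column_stack([np.ones_like(lags), ns_basis(lags, sub)])
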