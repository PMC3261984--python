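"""Cross-basis construction: the bilinear tensor of an exposure basis and a
lag basis that encodes a two-dimensional exposure-lag-response surface.

For day ``t`` the cross-basis entry in column ``(j, k)`` is

    sum_{l=0..L} R_j(x_{t-l}) * B_k(l)

where ``R_j`` are the exposure-basis columns (natural spline or double
threshold), ``B_k`` the lag-basis columns and ``L`` the maximum lag.  The
first ``L`` rows of a series have incomplete exposure history and are
excluded from fitting.

Relative risks are always reported against a centering temperature: the
weight vector for the effect at temperature ``x`` and lag ``l`` is
``(R_j(x) - R_j(center)) * B_k(l)``, so the fitted log-RR at the centering
value is identically zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .basis import LagSpec, SplineSpec, ThresholdSpec, exposure_basis, lag_basis

__all__ = [
    "CrossBasisSpec",
    "CrossBasisMatrix",
    "build_crossbasis",
    "prediction_vector",
    "cumulative_weight",
]


@dataclass(frozen=True)
class CrossBasisSpec:
    """Recipe for a cross-basis: exposure basis x lag basis + centering value."""

    exposure: SplineSpec | ThresholdSpec
    lag: LagSpec
    center: float

    @property
    def n_columns(self) -> int:
        return self.exposure.n_columns * self.lag.n_columns

    @property
    def max_lag(self) -> int:
        return self.lag.max_lag

    def column_names(self) -> list[str]:
        if isinstance(self.exposure, ThresholdSpec):
            enames = ["cold", "hot"]
        else:
            enames = [f"e{j}" for j in range(self.exposure.n_columns)]
        return [f"cb_{e}_l{k}" for e in enames for k in range(self.lag.n_columns)]

    def exposure_values(self, x) -> np.ndarray:
        return exposure_basis(x, self.exposure)

    def lag_values(self) -> np.ndarray:
        return lag_basis(self.lag)


@dataclass(frozen=True)
class CrossBasisMatrix:
    """Realized cross-basis design block.

    ``values`` has one row per day; rows before ``valid_from`` (= max_lag)
    lack complete exposure history and must be excluded from the likelihood.
    Column ordering is exposure-major: all lag columns of exposure column 0
    first.
    """

    values: np.ndarray
    valid_from: int
    spec: CrossBasisSpec

    @property
    def names(self) -> list[str]:
        return self.spec.column_names()

    @property
    def complete(self) -> np.ndarray:
        mask = np.ones(self.values.shape[0], dtype=bool)
        mask[: self.valid_from] = False
        return mask


def build_crossbasis(x, spec: CrossBasisSpec) -> CrossBasisMatrix:
    """Apply the cross-basis to a daily exposure series."""
    x = np.asarray(x, dtype=float)
    L = spec.max_lag
    n = x.size
    if n <= L:
        raise ValueError(f"series of length {n} shorter than max_lag+1 = {L + 1}")
    bad = ~np.isfinite(x)
    if bad.any():
        raise ValueError(f"non-finite exposure at index {int(np.flatnonzero(bad)[0])}")

    R = spec.exposure_values(x)          # n x J
    B = spec.lag_values()                # (L+1) x K
    J, K = R.shape[1], B.shape[1]
    V = np.zeros((n, J * K))
    for l in range(L + 1):
        # contribution of exposure l days ago to rows l..n-1
        contrib = R[: n - l, :, None] * B[l][None, None, :]   # (n-l) x J x K
        V[l:] += contrib.reshape(n - l, J * K)
    return CrossBasisMatrix(values=V, valid_from=L, spec=spec)


def prediction_vector(spec: CrossBasisSpec, at_temperature: float, lag: int) -> np.ndarray:
    """Weight vector ``w(x, l)`` such that the fitted log-RR at (x, l) is w . beta.

    Components are ``(R_j(x) - R_j(center)) * B_k(l)`` in exposure-major
    order; the variance of the log-RR is the quadratic form of ``w`` with the
    cross-basis coefficient covariance block.
    """
    if not (0 <= lag <= spec.max_lag):
        raise ValueError(f"lag {lag} outside 0..{spec.max_lag}")
    Rx = spec.exposure_values(np.array([at_temperature]))[0]
    Rc = spec.exposure_values(np.array([spec.center]))[0]
    Bl = spec.lag_values()[lag]
    return np.outer(Rx - Rc, Bl).ravel()


def exceedance_vector(spec: CrossBasisSpec, side: str, lag: int) -> np.ndarray:
    """Weight vector for a 1 degC exceedance of a threshold at a given lag.

    ``side='cold'``: 1 degC decrease below the cold threshold;
    ``side='hot'``: 1 degC increase above the hot threshold.  Only defined
    for double-threshold exposures, where the hinge columns are linear in
    the exceedance.
    """
    if not isinstance(spec.exposure, ThresholdSpec):
        raise TypeError("per-degree exceedance effects require a threshold exposure")
    if not (0 <= lag <= spec.max_lag):
        raise ValueError(f"lag {lag} outside 0..{spec.max_lag}")
    B = spec.lag_values()
    K = B.shape[1]
    w = np.zeros(2 * K)
    block = {"cold": 0, "hot": 1}[side]
    w[block * K : (block + 1) * K] = B[lag]
    return w


def cumulative_weight(spec: CrossBasisSpec, weight_at_lag, lag_range: tuple[int, int]) -> np.ndarray:
    """Sum per-lag weight vectors over an inclusive lag window."""
    l0, l1 = lag_range
    if l0 > l1:
        raise ValueError("empty lag range")
    if l0 < 0 or l1 > spec.max_lag:
        raise ValueError(f"lag range {lag_range} outside 0..{spec.max_lag}")
    return np.sum([weight_at_lag(l) for l in range(l0, l1 + 1)], axis=0)
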