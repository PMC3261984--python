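"""Grid search for the cold/hot threshold pair of the double-threshold
distributed-lag model, minimizing residual deviance.

At every candidate pair the full model — double-threshold cross-basis,
confounder smooths, calendar terms and referent strata — is refitted and
its residual deviance recorded.  Stratum intercepts are eliminated by the
conditional-Poisson reformulation by default, which yields exactly the
same slopes and residual deviance as the stratified-indicator fit (the
case-crossover equivalence) at a fraction of the cost; ``engine=
"indicator"`` runs the literal indicator IRLS instead.  Ties are broken
deterministically toward the smallest cold, then smallest hot threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .basis import LagSpec, ThresholdSpec
from .ccmodel import (DailySeries, StrataSpec, build_design, fit_conditional,
                      fit_quasipoisson, make_strata)
from .crossbasis import CrossBasisSpec, build_crossbasis

__all__ = ["ThresholdSearchResult", "make_grid", "search_thresholds", "coarse_to_fine"]


def make_grid(lo: float, hi: float, step: float) -> np.ndarray:
    """Inclusive grid from lo to hi in the given step (rounded to avoid
    float drift; the reference 0.1-degC grids contain 101 points each)."""
    if step <= 0:
        raise ValueError("step must be positive")
    if lo > hi:
        raise ValueError("grid lo must be <= hi")
    n = int(round((hi - lo) / step)) + 1
    return np.round(lo + step * np.arange(n), 10)


@dataclass
class ThresholdSearchResult:
    """Best pair, the full deviance grid, and bookkeeping."""

    best: ThresholdSpec
    deviance_grid: pd.DataFrame     # columns: cold, hot, residual_deviance, ok
    n_fits: int
    engine: str
    notes: list

    @property
    def best_deviance(self) -> float:
        ok = self.deviance_grid[self.deviance_grid["ok"]]
        return float(ok["residual_deviance"].min())


class _SearchContext:
    """Fixed parts of the design shared across grid cells."""

    def __init__(self, series: DailySeries, outcome: str, lag: LagSpec,
                 strata_spec: StrataSpec, engine: str, measure: str = "tmean"):
        self.series = series
        self.outcome = outcome
        self.lag = lag
        self.engine = engine
        self.strata = make_strata(series.dates, strata_spec)
        self.x = series.temperature(measure)
        self.center = float(np.median(self.x))

    def fit_at(self, cold: float, hot: float):
        spec = CrossBasisSpec(
            exposure=ThresholdSpec(float(cold), float(hot)),
            lag=self.lag, center=self.center)
        cb = build_crossbasis(self.x, spec)
        if self.engine == "conditional":
            y, X, names, used, strata_used = build_design(
                self.series, cb, self.strata, self.outcome, include_strata=False)
            # drop the global intercept: absorbed by the stratum terms
            fit = fit_conditional(y, X[:, 1:], strata_used, names=names[1:])
        else:
            y, X, names, used, _ = build_design(
                self.series, cb, self.strata, self.outcome, include_strata=True)
            fit = fit_quasipoisson(y, X, names=names)
        return fit, spec


def search_thresholds(series: DailySeries, outcome: str,
                      cold_grid: tuple[float, float, float],
                      hot_grid: tuple[float, float, float],
                      lag: LagSpec | None = None,
                      strata: StrataSpec | None = None,
                      engine: str = "conditional",
                      measure: str = "tmean") -> ThresholdSearchResult:
    """Exhaustive deviance minimization over all (cold, hot) pairs.

    ``cold_grid``/``hot_grid`` are (lo, hi, step); the cold grid must lie
    entirely below the hot grid.  Failed cells are flagged and excluded
    from the argmin rather than aborting the search.
    """
    if lag is None:
        lag = LagSpec.log_spline(27, 4)
    if strata is None:
        strata = StrataSpec()
    colds = make_grid(*cold_grid)
    hots = make_grid(*hot_grid)
    if colds[-1] >= hots[0]:
        raise ValueError("cold grid must lie entirely below the hot grid")

    ctx = _SearchContext(series, outcome, lag, strata, engine, measure)
    rows, notes = [], []
    best = None
    best_dev = np.inf
    for c in colds:             # ascending: first strict minimum wins ties
        for h in hots:
            try:
                fit, _ = ctx.fit_at(c, h)
                dev = fit.deviance
                ok = True
            except Exception as exc:   # noqa: BLE001 - per-cell failure is data
                dev, ok = np.nan, False
                notes.append(f"fit failed at cold={c}, hot={h}: {exc}")
            rows.append((c, h, dev, ok))
            if ok and dev < best_dev - 1e-12:
                best_dev = dev
                best = ThresholdSpec(float(c), float(h))
    grid = pd.DataFrame(rows, columns=["cold", "hot", "residual_deviance", "ok"])
    if best is None:
        raise RuntimeError("threshold search failed at every grid cell")
    if notes:
        warnings.warn(f"{len(notes)} grid cells failed and were excluded", stacklevel=2)
    return ThresholdSearchResult(best=best, deviance_grid=grid,
                                 n_fits=len(rows), engine=engine, notes=notes)


def coarse_to_fine(series: DailySeries, outcome: str,
                   cold_grid: tuple[float, float, float] = (-5.0, 5.0, 0.1),
                   hot_grid: tuple[float, float, float] = (19.0, 29.0, 0.1),
                   coarse_step: float = 1.0,
                   lag: LagSpec | None = None,
                   strata: StrataSpec | None = None,
                   engine: str = "conditional",
                   measure: str = "tmean") -> ThresholdSearchResult:
    """Two-stage search: a coarse pass over the full ranges, then the target
    step within +/- one coarse step of the coarse optimum.

    Matches the exhaustive search whenever the deviance surface is unimodal;
    on multi-minimum surfaces it may return a local optimum, which is noted
    in the result.  The exhaustive search remains the reference.
    """
    c_lo, c_hi, c_step = cold_grid
    h_lo, h_hi, h_step = hot_grid
    coarse = search_thresholds(series, outcome,
                               (c_lo, c_hi, coarse_step),
                               (h_lo, h_hi, coarse_step),
                               lag=lag, strata=strata, engine=engine, measure=measure)
    bc, bh = coarse.best.cold_threshold, coarse.best.hot_threshold
    fine = search_thresholds(
        series, outcome,
        (max(c_lo, bc - coarse_step), min(c_hi, bc + coarse_step), c_step),
        (max(h_lo, bh - coarse_step), min(h_hi, bh + coarse_step), h_step),
        lag=lag, strata=strata, engine=engine, measure=measure)
    grid = pd.concat([coarse.deviance_grid, fine.deviance_grid], ignore_index=True)
    notes = coarse.notes + fine.notes + [
        "coarse-to-fine search: may miss secondary minima on multimodal surfaces"]
    return ThresholdSearchResult(best=fine.best, deviance_grid=grid,
                                 n_fits=coarse.n_fits + fine.n_fits,
                                 engine=engine, notes=notes)
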