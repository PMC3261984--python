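# dlnmcc

Distributed-lag non-linear models (DLNMs) inside a time-stratified
case-crossover design, for daily temperature–mortality analysis.

## The problem

Daily mortality responds to ambient temperature non-linearly (a U-shaped
exposure–response with a "comfort band" between a cold and a hot
threshold) and with delay: cold effects typically emerge after a few days
and persist for a week or more, while heat effects are acute and may be
followed by compensatory deficits (mortality displacement, "harvesting").
Estimating this two-dimensional temperature × lag surface from daily
death counts requires simultaneously (i) a flexible exposure–lag basis
and (ii) tight control of season and secular trend, which otherwise
confound the association.

`dlnmcc` combines the two standard tools for this:

* **DLNM cross-basis.** The effect of temperature `x` at lag `l` is
  modelled as a bilinear tensor ("cross-basis") of an exposure basis
  (natural cubic spline, or a double linear-threshold "hockey-stick")
  and a lag basis (natural cubic spline with knots equally spaced on the
  log-lag axis). For day *t* the design entry in column *(j,k)* is
  `Σ_l R_j(x_{t−l}) B_k(l)`.
* **Time-stratified case-crossover.** Daily counts `Y_t` are modelled as
  overdispersed Poisson,

  ```
  log μ_t = α + β·CB_t + ns(RH_t,3) + ns(PM10_t,3) + ns(SO2_t,3) + ns(NO2_t,3)
            + DOW_t + Holiday_t + Influenza_t + Strata_t
  ```

  where `Strata_t` are disjoint calendar-month (or fixed-window) referent
  strata, so season and trend are controlled by design. The stratified
  fit is exactly equivalent to a conditional Poisson likelihood that
  eliminates the stratum intercepts; both routes are implemented and
  agree to numerical precision.

From a fitted model the package computes relative-risk surfaces
`RR(x, l)` against a centering temperature (the observed median),
per-lag curves for a 1 °C threshold exceedance, and **cumulative
effects**—the summed log-RR over a lag window, reported as a percent
increase per 1 °C beyond a threshold with delta-method 95% CIs. The
cold/hot threshold pair itself is chosen by a residual-deviance grid
search; model and temperature-measure selection use QAIC
(`−2·loglik + 2·φ̂·p` with Pearson dispersion `φ̂`).

Because suitable real daily mortality series are rarely redistributable,
the package ships a first-class synthetic generator that emulates a
three-year northern-Chinese urban series (seasonal AR(1) temperature,
three highly correlated temperature measures, season-linked pollutants,
overdispersed counts) with configurable, known embedded temperature–lag
effects — so every stage is testable by parameter recovery.

## Worked example

```python
import dlnmcc as d

# a 3-year synthetic series with known cold (delayed) and hot (acute)
# effects around thresholds 0.0 / 25.0 degC
series, truth = d.generate(d.scenario("both-effects", n_days=1095, seed=5))

model = d.TemperatureLagModel(
    series, outcome="nonaccidental", measure="tmean",
    exposure=d.ThresholdSpec(0.0, 25.0))   # double-threshold DLNM
results = model.fit()

cold = results.cumulative("per_degree_below_cold", (0, 18))
hot = results.cumulative("per_degree_above_hot", (0, 2))
print(f"cold 0-18: {cold.percent_increase:.2f}% "
      f"(95% CI {cold.ci95[0]:.2f}, {cold.ci95[1]:.2f})")
print(f"hot  0-2 : {hot.percent_increase:.2f}% "
      f"(95% CI {hot.ci95[0]:.2f}, {hot.ci95[1]:.2f})")
```

prints

```
cold 0-18: 5.33% (95% CI 3.43, 7.27)
hot  0-2 : 4.66% (95% CI 3.81, 5.50)
```

i.e. a 1 °C fall below the cold threshold is associated with a 5.33%
increase in nonaccidental deaths cumulated over lags 0–18 (the embedded
truth is 4.16%), and a 1 °C rise above the hot threshold with a 4.66%
increase over lags 0–2 (truth 4.65%); both CIs cover the truth.

The threshold pair can itself be estimated:

```python
search = d.coarse_to_fine(series, "nonaccidental")   # deviance grid search
print(search.best)        # ThresholdSpec(cold_threshold=..., hot_threshold=...)
```

and the full study workflow (descriptives, measure comparison via QAIC,
spline-DLNM surfaces, threshold search, double-threshold fit, cumulative
tables, sensitivity analyses) is available through
`dlnmcc.run_main_analysis` or the CLI:

```bash
dlnmcc simulate --scenario tianjin_like --out data.csv
dlnmcc fit data.csv --out results/
dlnmcc thresholds data.csv --outcome nonaccidental
dlnmcc sensitivity data.csv
```

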