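# ozonewarn

Surface-ozone diagnostics and next-day exceedance early warning for urban
monitoring stations.

Summertime ozone in polluted industrial cities is a secondary pollutant: its
hourly level is set jointly by a regional oxidant background, local NOx
emissions, and the daylight photochemistry that cycles O3, NO and NO2.  This
package takes hourly station records of O3, NO, NO2 (μg/m³) and surface
meteorology and produces the standard analysis chain an air-quality group
would run on such data:

* **Daily metrics and exceedance accounting** — daily mean ozone
  (O3_mean), daily 1-h maximum (O3_1h-max) and daily maximum 8-h running
  mean (O3_8h-max, windows confined to the calendar day), compared against
  level-II ambient limits (defaults: 200 μg/m³ for the 1-h mean, 160 μg/m³
  for the 8-h mean) with per-period exceed-standard days and rates.
* **Photostationary-state diagnostics** — during daylight the null cycle
  NO + O3 → NO2 and NO2 + hν → NO + O3 equilibrates so that
  [O3][NO]/[NO2] = J2/K1 (the ratio of the NO2 photolysis rate to the
  NO + O3 rate coefficient, expressed in concentration units).  The package
  estimates the diurnal J2/K1 profile, the NO2 share of total oxidant
  OX = O3 + NO2 as a function of NOx (split day/night), and the NOx levels
  at which the fitted daylight O3 curve crosses the NO and NO2 curves.
* **Oxidant partition** — ordinary least squares of daily OX on daily NOx,
  separately for day and night windows: the intercept is the
  NOx-independent *regional* oxidant contribution, the slope the *local*
  contribution per unit NOx (`OxidantPartition` → `fit()` →
  results with intercept/slope, standard errors, R², `summary()`).
* **Next-day early warning** — fifteen same-day factors are screened by
  two-tailed Pearson correlation against the next day's ozone metrics; the
  two dominant predictors, X1 = O3_mean (μg/m³) and X2 = T_max (°C), enter
  a full bivariate quadratic

  Y = b₁X1² + b₂X2² + b₃X1X2 + b₄X1 + b₅X2 + b₆

  fitted by OLS (`NextDayOzoneModel` → `fit()`).  Empirical tail-conditioned
  exceedance-rate curves (fraction of days with the predictor ≥ c whose next
  day exceeded the standard), smoothed isotonically, are inverted into
  graded warning thresholds: level 1/2/3 at a 50/80/100 % conditional
  exceedance rate, plus a no-risk ceiling at 0 %.  A warning fires only when
  both the ozone and the temperature condition hold.

Because raw station records of this kind are generally not redistributable,
the package ships a seeded synthetic generator (`simulate_hourly`) that
reproduces the structure the analyses assume — photostationary coupling with
nighttime titration, a regional OX background near 100 μg/m³, rush-hour NOx,
a 14:00 ozone maximum, J2/K1 between 3 and 15 μg/m³ peaking at 11:00 — so
every stage is testable end to end.

## Worked example

```python
from ozonewarn import (SimConfig, simulate_hourly, summarize,
                       exceedance_report, OxidantPartition,
                       build_lagged_table, fit_quadratic_model,
                       exceedance_rate_curve, warning_thresholds)

series = simulate_hourly(SimConfig(seed=42, n_days=120))
daily = summarize(series)

print(exceedance_report(daily).round(3).to_string())
print(OxidantPartition.from_daily(daily, "day").fit().summary())

table = build_lagged_table(daily)
print(fit_quadratic_model(table, "8h").summary())
curves = {v: exceedance_rate_curve(table, v) for v in ("o3_mean", "t_max")}
print(warning_thresholds(curves["o3_mean"], curves["t_max"]).to_dict())
```

prints

```
        n_valid_days_1h  n_valid_days_8h  n_exceed_1h  n_exceed_8h  rate_1h  rate_8h
period
all                 120              120           18           30     0.15     0.25
pooled              120              120           18           30     0.15     0.25

Oxidant partition (day), n=120
  regional (intercept):    96.18 ug/m3  (se 14.45)
  local (slope):           1.211 per unit NOx  (se 0.263)
  R^2: 0.153

Next-day ozone quadratic model (target: 8h metric), n=119, R^2=0.471
  term        coef          se
  b_x1sq        0.0076      0.0052
  b_x2sq        0.7937      0.5807
  ...
```

Reading this: of 120 simulated summer days, 15 % exceeded the 1-h limit and
25 % the 8-h limit on the next day's books; the daytime OX~NOx regression
recovers a regional oxidant background of 96 ± 14 μg/m³ (the generator's
true value is 100); and the fitted quadratic explains R² ≈ 0.47 of next-day
8-h-maximum variance on this run.  The warning inversion on the same run
places the level-1 (50 %) thresholds at O3_mean = 114 μg/m³ and
T_max = 35 °C.

The same chain is available from the shell:

```sh
ozonewarn simulate --seed 42 --days 120 --out hourly.csv
ozonewarn summarize --in hourly.csv --out daily.csv
ozonewarn warn --in daily.csv --target 8h --out warn-report/
ozonewarn run-all --seed 42 --out bundle/        # everything + manifest
```

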