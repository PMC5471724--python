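# movescale

Cross-scale analysis of animal movement capacity from GPS telemetry, built
for collaborative datasets that pool many studies with different collars,
fix schedules, and monitoring spans (the motivating case is wild pig,
*Sus scrofa*, telemetry across the southern U.S.).  The package answers a
deceptively simple question: which meteorological, landscape, geographic,
temporal, and individual-level factors drive how far an animal moves — and
does the answer change with the temporal scale (daily, monthly, overall) at
which movement is measured?

## What it does

1. **Screening** (`movescale.telemetry`) — parse telemetry CSVs; drop fixes
   with DOP > 10; keep only nocturnal fixes (the 18:00–08:00 "biological
   day"); drop days with < 2 fixes and animals with < 20 monitored days;
   flag months with < 15 days as ineligible for monthly aggregation.  Every
   rule's removal count lands in an audit report.
2. **Movement metrics** (`movescale.metrics`) — per biological day, MxD
   (maximum pairwise great-circle distance between any two fixes) and MHD
   (mean of distances between fix pairs approximately 1 h apart: for each
   origin fix, the subsequent fix whose separation in [50, 70] min is
   closest to 60 min).  Daily values are averaged per animal at the monthly
   and overall scales, with the mean fixes/day as a precision weight and
   the mean lat/lon as the record centroid.
3. **Home ranges** (`movescale.homerange`) — 95% minimum convex polygons
   (retain the ceil(0.95 n) fixes nearest the centroid, convex hull in a
   local equal-area projection); pooled semivariograms
   γ(l) = E‖Δr‖²/4 with a weighted Ornstein–Uhlenbeck fit
   γ̂(l) = σ²(1 − e^(−l/τ)); and a simplified autocorrelation-aware KDE
   (sAKDE) whose bandwidth H = Σ̂ · N_eff^(−1/3) inflates as the effective
   sample size N_eff = duration/τ shrinks.
4. **Covariates** (`movescale.covariates`) — the five predictor categories:
   individual (sex–age class, management indicator), meteorological
   (temperature, humidity, Tetens saturation-deficit, precipitation,
   pressure, wind, growing degree days over 10 °C), temporal (month, year,
   1–12-month temperature/precipitation lags), geographic (ecoregion), and
   landscape (distances to water, streams, agriculture, forest, and three
   road classes).
5. **Variable screening** (`movescale.screening`) — out-of-bag permutation
   importance from a bagged tree ensemble, a greedy |r| < 0.5
   de-correlation filter, and a cross-validated accuracy plateau rule.
6. **Models** (`movescale.gamm`) — one additive mixed model per
   response × scale × category:

   y_i = α + Σ_j f_j(x_ij) + x_i′β + b_animal(i) + b_study(i) + ε_i

   with penalized cubic regression splines (equally spaced knots, shrinkage
   towards zero), linear terms for distances, latitude/longitude smooths in
   every model, fix-count weights, REML smoothing selection, and a
   Cochrane–Orcutt AR(1) residual term ρ at the daily scale.
7. **Synthetic truth** (`movescale.synthetic`) — a multi-study telemetry
   generator (OU movement around a home-range centre, log-linear covariate
   effects on step scale, DOP noise, fix failure) whose coefficients are
   exported alongside the data, so every stage above is testable against
   known ground truth.

`movescale.pipeline.run` orchestrates the full grid — 5 categories ×
(MxD, MHD at 3 scales + home-range area at 2) = 40 models — and a `click`
CLI (`movescale simulate|screen|metrics|homerange|covariates|run-all|...`)
wraps the stages.

## Worked example

```python
from movescale import synthetic, telemetry, metrics

cfg = synthetic.small_config(seed=1, n_studies=2, animals_per_study=5, n_days=40)
ds = synthetic.simulate_dataset(cfg)
fixes = telemetry.assign_biological_day(ds.telemetry)
res = telemetry.screen(fixes)
print(res.audit)
daily = metrics.build_daily_records(res.fixes)
print(daily[["mxd_km", "mhd_km"]].mean())
```

prints

```
{'input_fixes': 8670, 'removed_dop': 463, 'removed_diurnal': 3410,
 'removed_sparse_days': 0, 'removed_short_animals': 0, 'animals_removed': 0,
 'retained_fixes': 4797, 'retained_animals': 10, 'ineligible_months': 10}
mxd_km    1.554854
mhd_km    0.374310
```

— about 5% of fixes fail the DOP filter, the daytime fixes are excluded,
and the retained nocturnal days give a mean maximum daily distance of
~1.55 km and a mean hourly distance of ~0.37 km.  Fitting the daily-scale
meteorological model on the 100-animal recovery scenario
(`scripts/acceptance.py`) then returns a concave temperature reaction norm
peaking at 20.2 °C against a generative optimum of 20 °C, with the monthly
fit of the same data showing a far weaker effect — the cross-scale
attenuation that motivates analysing all scales in one framework.

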