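# Methods

This note records the modelling choices, defaults, and limitations behind
`movescale`, in the spirit of a statistical-software methods appendix.

## Screening and the biological day

Wild pig activity in the study region is predominantly nocturnal, so the
analysis day is the 18:00–08:00 clock window: fixes at or after 18:00 take
their own calendar date, fixes before 08:00 take the previous date, and
everything in [08:00, 18:00) is labelled diurnal and excluded.  Timestamps
are treated as local study clock time with no DST arithmetic — the simplest
defensible reading for collar data logged in local time.  Screening order
is DOP → nocturnal window → 2-fix/day minimum → 20-day animal minimum →
15-day monthly eligibility; the 2-fix rule is evaluated on the surviving
nocturnal fixes because the analyses only ever use those.  Two boundary
conventions are explicit and configurable: "DOP greater than 10" is read
strictly (a fix at exactly 10.0 is kept), and "monitored for at least 20
days" counts retained biological days, the same unit as the 15-day monthly
rule (`ScreenThresholds.min_days_unit="span"` switches to calendar span).

## Movement metrics

MxD is the maximum great-circle (haversine, sphere radius 6371.0088 km)
distance between any two of a day's fixes; the time separation of the
arg-max pair is kept as a diagnostic.  MHD averages distances between fix
pairs "approximately one hour apart": for each origin fix, among subsequent
fixes with Δt ∈ [50, 70] minutes, the one closest to 60 minutes is taken
(ties to the earlier fix).  A fix may be the origin of one pair and the
target of others, so overlapping pairs are allowed — this is the rule that
makes a 30-minute schedule from 8:00 to 10:30 yield exactly four pairs.
The window is a parameter because no canonical tolerance exists; distances
are averaged without Δt normalisation.  The overall-scale mean is taken
over daily values directly (all values combined), not as a mean of monthly
means.  A haversine sphere rather than an ellipsoid is used: at the ≤ 10 km
distances involved the discrepancy is far below GPS noise.

## Home ranges

**Percent-MCP.**  The trimming convention is stated because implementations
differ: the centroid is the arithmetic mean of the projected coordinates,
the ceil(percent/100 · n) nearest points are retained (distance ties keep
the earlier fix), and the hull (Andrew's monotone chain) is taken in a
Lambert azimuthal equal-area projection centred on the centroid, so the
shoelace area is an area on the sphere in km².

**Variogram and OU fit.**  The semivariance convention is
γ(l) = E‖Δr‖²/4, which makes γ the per-axis positional variance scale: an
Ornstein–Uhlenbeck (range-resident) animal has
γ(l) = σ²(1 − e^(−l/τ)).  Pooling is within-study (fix schedules and
behaviour are most consistent there).  The fit is weighted least squares
with pair counts as weights, σ² profiled out in closed form, and a
log-spaced multistart over τ to avoid local minima.  A variogram that is
already flat at the first lag bin sets an independence flag (τ is not
identified below the sampling interval).

**Simplified autocorrelated KDE (sAKDE).**  This is deliberately *not* a
continuous-time-model AKDE: there is no OUF model, no likelihood fitting,
and no bias-corrected bandwidth.  It preserves the one mechanism that
matters for the MCP-vs-AKDE comparison — autocorrelation reduces the
effective number of independent locations, N_eff = duration/τ (floored at
2, capped at n), and the Gaussian-reference bandwidth
H = Σ̂ · N_eff^(−2/(d+4)) with d = 2 therefore inflates.  The area is the
smallest highest-density region containing the requested mass, by sorting
grid densities (grid 160², bounds data ± 3 bandwidth sd; halving the cell
size moves the area by well under 1%).  τ of the order of the monitoring
duration flags the estimate unreliable — the non-stationary (dispersal)
regime in which autocorrelation-aware estimators anticipate future
long-range movement and exceed the MCP, sometimes enormously.  Numerical
reproduction of any specific published AKDE value is out of scope.

## Covariates

Meteorology is aggregated over the same 18:00–08:00 window as the responses
(max/min/mean temperature, mean RH, pressure and wind, total
precipitation); days with > 20% of window hours missing become missing
values, never imputations.  Saturation vapour-pressure deficit uses the
Tetens formula 610.78·exp(17.27 T/(T + 237.3)) Pa converted to mm Hg —
the variable is standard, the formula had to be chosen.  Growing degree
days are max(0, (tmax + tmin)/2 − 10 °C).  Monthly lag series (mean
temperature, total precipitation, lags 1–12) come from calendar-month
aggregates of the full weather history; the generator guarantees 12 months
of burn-in.  Weather attaches at the record's study series (nearest series,
no spatial interpolation) — this keeps the synthetic path exact; bilinear
interpolation would only matter with gridded inputs.  Landscape distances
project centroid and features into the study's local equal-area plane and
take shapely minimum distances (0 inside polygons); ecoregion lookup is ray
casting on lon/lat with boundary points assigned to the first polygon in
file order.

## Predictor screening

Multicollinearity is concentrated in the meteorological and temporal-lag
sets, so screening defaults to those categories.  Importance is
out-of-bag *permutation* importance (mean OOB-MSE increase) from a bagged
regression-tree ensemble — permutation rather than impurity importance
because it is robust to scale and cardinality.  The de-correlation filter
walks the ranking greedily and keeps a predictor only if |Pearson r| < 0.5
against every kept predictor (categoricals exempt; Spearman available).
The plateau rule adds predictors in rank order and stops when
cross-validated R² improves by less than ε = 0.01 — an explicit,
configurable operationalisation of "no longer significantly improves
accuracy".

## The additive mixed model

Each smooth is a cubic B-spline basis (k = 10, equally spaced knots over
the observed range; cyclic basis for month over (0.5, 12.5)) with a
second-order difference penalty plus a small identity shrinkage penalty
(10⁻⁴ · I) so that uninformative smooths shrink entirely to zero rather
than to their linear null space.  The shrinkage multiple trades off two
behaviours: large values let the smoothing parameter suppress genuinely
linear signal, tiny values stop pure-noise smooths from vanishing; 10⁻⁴
keeps a clean linear effect near 2 effective df while pure noise drops
below 0.5.  Each smooth carries a sum-to-zero constraint over the data for
identifiability, absorbed by a null-space reparameterisation.  Random
intercepts (animal and study at the daily and monthly scales, study only
at the overall scale) are indicator blocks with a ridge penalty — the
standard mixed-model representation; the variance component is
σ̂/√λ.  Distances enter linearly; latitude and longitude enter as two
separate univariate smooths in every model (a deliberate, simple control
for broad spatial correlation, not a full spatial covariance model).

Smoothing parameters minimise the Gaussian REML criterion
(n − M₀)·log(RSS_pen) + log|XᵀWX + S_λ| − log|S_λ| over log λ
(L-BFGS-B, bounds e^±12-ish), with GCV as the fallback when REML fails to
converge; with fixed λ the fit is exactly the closed-form penalized
weighted least squares (XᵀWX + Σλ_jS_j)⁻¹XᵀWy, which the tests verify
against an independent dense solve.  Weights are normalised to mean 1, so
fits are invariant to the overall weight scale.  Responses are modelled on
the km scale with an identity link, matching how the movement metrics are
reported; a log transform is a caller-side option.  Adjusted R² is
1 − (RSS/df_res)/(TSS/(n − 1)) with df_res = n − total edf.  Term
significance uses approximate Wald statistics on the Bayesian posterior
covariance at α = 0.05, with no multiplicity correction — matching common
reporting practice; p-values should be read as indicative.

Daily-scale serial correlation is handled by Cochrane–Orcutt iteration:
fit, estimate ρ as the pooled lag-1 autocorrelation of within-animal
residuals over consecutive-day pairs (gaps break runs; single-day runs
contribute nothing), quasi-difference response and design within runs
(Prais–Winsten √(1 − ρ²) scaling of each run's first row), refit, iterate
to |Δρ| < 10⁻³ (max 20 iterations; ρ̂ clipped to ±0.99 with a warning).
The AR term is placed on the residuals rather than the lagged response —
the residual formulation keeps the covariate effects interpretable as
marginal reaction norms.

Reaction norms are centred partial-effect curves with ±2 SE bands.  The
concavity indicator fits a quadratic to the central 50% of the curve and
reports "concave"/"convex" only when the quadratic component contributes at
least 10% of the curve's amplitude — this keeps near-linear fits classified
as "none" without a formal test.

## Synthetic data: what it emulates and what it does not

The generator reproduces the *structure* of a pooled multi-study dataset:
several studies with distinct locations, ecoregions, fix intervals (15 min
to 12 h), monitoring spans, and sex–age mixes; seasonal + diurnal weather
with AR(1) daily anomalies around realistic southern-US values; lognormal
DOP with ~5% of mass above the filter threshold; Bernoulli fix failure;
and movement as a discrete-time OU attraction to a home-range centre whose
per-step displacement scale is log-linear in covariates — ecoregion
intercept, a quadratic temperature term peaking at 20 °C, a pressure
slope, sex–age offsets, and animal/study/daily-anomaly random effects.
The log-linear link guarantees positivity and makes "concave on the
natural scale" a well-defined recoverable target.  The Euler step is the
default (adequate for testing estimators); an exact OU transition is
available for variogram work, and a linear centre drift generates the
non-stationary scenario that biases autocorrelation-aware home-range
estimators upward.  Default effect sizes were set once to values a
movement ecologist would call realistic (e.g. adult males ~50% larger step
scale than adult females; animal-level intercept sd 0.3 on the log scale).

What it does *not* emulate: habitat selection, behavioural states,
dispersal as a behaviour (only as a drift flag), collar-specific error
models, irregular duty cycles, or interactions between covariates.
Passing recovery tests on these data therefore demonstrates that the
estimators recover the stated generative structure — not that real pig
movement follows an OU process.

## Problem sizes

The recovery scenario used by the tests and the acceptance script is 100
animals (5 studies × 20), 60 days of hourly fixes starting in late winter
(~130,000 simulated positions, ~6,100 daily records after screening) — the
temperature range then straddles the 20 °C optimum.  Correlation-structure
recovery uses 100 × 50 and 100 × 60 direct simulations; the home-range
direction-of-effect comparison uses 15 exact-OU animals over 45 days with
and without drift.  These sizes give stable recovery (peak within ±3 °C,
ρ within ±0.1, variance components within ±50%) while keeping a full run
in tens of seconds.

## Known limitations

- Wald p-values for penalized smooths use a rounded-edf χ² reference —
  adequate for screening significance, not for fine-grained inference.
- The lat/lon smooths and a per-study factor (ecoregion) are confounded
  when each study occupies one location; only the combined regional
  prediction is estimable, and the tests compare that quantity.
- The sAKDE is a mechanism-preserving stand-in, not a substitute for a
  fitted continuous-time movement model.
- REML here treats the smoothing-parameter search as a plain optimisation;
  extremely flat criteria fall back to GCV and are flagged rather than
  polished.
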