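# Methods

## The model

`pollenlag` fits a Poisson generalized additive model with a log link to a
daily count series. The linear predictor adds five blocks:

1. an intercept;
2. the DLNM **cross-basis** of the exposure series — for exposure basis
   `b(.)` (columns `j`) and lag basis `c(.)` (columns `k`), design entry
   `(t, jk)` is `sum_{l=0..L} b_j(X_{t-l}) c_k(l)`;
3. a natural cubic spline in the day index (the seasonal/long-term trend);
4. a df-3 natural cubic spline per meteorological covariate;
5. day-of-week contrasts (Monday reference) and a holiday indicator.

All smooths have fixed, explicit df; there is no penalized smoothness
selection. Estimation is iteratively reweighted least squares (Newton
scoring, which is the exact Newton method for the canonical log link):
weighted normal equations solved by Cholesky factorisation, with an
`lstsq` fallback on ill-conditioned steps. Convergence requires both a
relative deviance change below 1e-10 and a score vector below 1e-6 in
absolute value, within 100 iterations; non-convergence is flagged on the
results object and warned about, never silently returned. The coefficient
covariance is the inverse Fisher information at the optimum (observed =
expected for this link). The log-likelihood includes the `log y!` term, so
the AIC (`-2 llf + 2 p`) is comparable across software. Linear predictors
are clipped at ±30 (rate ~1e13) to survive separation; a clipped fit is
marked non-converged.

### Spline bases

Natural cubic splines are represented by their cardinal basis on the knot
set: column `j` is the natural interpolant of the `j`-th indicator vector,
so each column is itself a natural cubic spline and the span is exactly the
natural-spline space. The cardinal columns sum to one; dropping the first
column removes the constant (exposure and confounder bases, df = interior
knots + 1), while lag bases keep it (df = interior knots + 2's worth of
knots, i.e. df columns including the constant) so that an effect flat in
lag is representable. Outside the boundary knots every column continues
linearly (zero curvature), which is what makes prediction at the reference
exposure 0 well defined even when the observed minimum is slightly above 0.
Auto-placed knots sit at equally spaced quantiles of the data; tied
quantiles (heavily discrete covariates such as mostly-zero rainfall)
collapse and the df is reduced rather than erroring. Default lag knots are
equally spaced on the `log(1+lag)` scale, concentrating resolution at the
short lags where acute effects live.

### Cross-basis defaults and history padding

Defaults: exposure df 3 (quantile knots, boundary `(min(0, x_min), x_max)`),
lag df 4, maximum lag 30 days. The exposure history before the first
observed day is padded with the day-0 value, keeping all 183 rows of a
season usable with a 30-day lag span; an `incomplete="drop"` switch
discards the first `L` rows instead for sensitivity analysis. The lower
exposure boundary is anchored at 0 (not the observed minimum) because
pollen concentration has a physical floor there and 0 is the conventional
RR reference.

### Time-smoother df selection

For each candidate df (default 3–15) the **base model** — everything except
the cross-basis — is fitted and `S(df) = sum_{k=1..30} |PACF_k|` of its
deviance residuals computed, PACF by the regression definition (coefficient
of the lag-k regressor among lags 1..k, OLS with intercept). The smallest
`S` wins; ties within 1e-12 go to the smaller df. Selection deliberately
precedes the introduction of the exposure block: a cross-basis built from a
smooth seasonal exposure spans much of the trend space, and selecting with
it present makes the rule insensitive to the trend's actual roughness.
Deviance residuals are the default diagnostic series, standard for Poisson
regression; the residual type matters little at counts of ~8/day.

### Effects

All relative risks are contrasts against a reference exposure (default 0):
`a(x, l) = [b(x) - b(ref)] ⊗ c(l)`, `log RR = a'beta`, `SE² = a'Va` over
the cross-basis block. Cumulative effects use the summed contrast
`sum_{l'<=l} a(x, l')`, which keeps the lag-to-lag coefficient covariances
in the interval — summing per-lag variances would understate it. The 95%
multiplier is fixed at z = 1.96 to match the conventional reporting formula
(other levels are accepted via `zcrit`). Exposure quantiles use the linear
interpolation rule between order statistics. A curve's summary takes
`peak_lag = argmax RR` (ties to the smallest lag) and
`lag_time = first lag >= peak_lag whose CI contains 1`, censored at `L+1`
when the curve never loses significance; the CI-based disappearance rule is
this package's operational definition of an effect "lag time".

## The synthetic-data generator

The generator emulates a single-city warm season (183 days from April 1,
configurable down to 60): Poisson counts around 8/day; bimodal pollen built
from a steady background floor (5 grains/1000 mm²) plus two Gaussian
seasonal bumps (spring: day 30, width 16, height 300; autumn: day 160,
width 10, height 220) under multiplicative lognormal noise (log-SD 0.55) —
the resulting P5/P25/P50/P75/P95 land near 5/6/50/140/340 grains/1000 mm²,
matching the skew of real pollen series; seasonal meteorology whose phases
give the field-typical correlation signs (temperature, dew point and
humidity peak mid-summer and correlate negatively with pollen; wind and
pressure trough mid-summer and correlate positively; rain is concentrated
in summer); weekday/weekend visit factors (1, 1, 1, 1, 1, 0.7, 0.6) and a
0.5 holiday factor on the 2019 public holidays in season; a gentle smooth
trend (sinusoid, amplitude 0.08, 1.5 cycles); and small log-linear
covariate effects. The default truth surface is linear in exposure with an
exponential lag decay, `log RR(x, l) = 0.001 x exp(-l/4)` up to lag 30 —
lag-0 RR ≈ 1.4 at high pollen, effects negligible past ~20 lags. The
baseline log rate 1.72 puts the realized daily mean near 8 once the
exposure term's average contribution is included.

What the generator does **not** emulate: real weather dynamics
(day-to-day autocorrelation of meteorology beyond its seasonal cycle),
pollen-type composition, overdispersion or outbreak clusters, reporting
artifacts, or measurement error in the exposure. Passing the recovery and
calibration tests therefore shows the estimator is correct *under the
model's own assumptions* (Poisson counts, additive log-linear structure,
smooth confounding), not that those assumptions hold for any particular
hospital series.

## Simulation study sizes

Test-suite experiments use: 100 seeds for the null-surface CI calibration
(183-day series, fixed time df 4, coverage of log-RR = 0 required at ≥ 90%
of grid points); 200 replicates for coverage of the true cumulative log-RR
at the P75 exposure over lags 0–5 (required within [90%, 98%]); one
2000-day series for large-sample surface recovery (mean absolute log-RR
error < 0.05 over the default 50 × 31 grid); and 100 seeds for the
df-selection roughness check. These sizes give stable pass/fail behaviour
while keeping the whole suite under a minute of simulation work.

## Numerical and design notes

* Rank deficiency is detected before fitting by pivoted QR and reported
  with the offending column names.
* `compare_aic` refuses to rank fits whose response vectors differ
  (checksum comparison) — AIC is only comparable on identical data.
* Spearman rho/p go through `scipy.stats.spearmanr` (mid-rank ties,
  two-sided t approximation on n−2 df, adequate for n ≈ 183); no
  multiple-testing adjustment is applied across the matrix, matching common
  reporting practice for these tables.
* The reporting formula `RR = exp(beta * dc)` is the multiplicative reading
  of the conventional RR/CI pair; an additive `exp(beta + dc)` would be
  dimensionally incoherent with its own interval formula.
* Pipeline artifacts contain no wall-clock timestamps, so reruns with the
  same config are byte-identical (PNG figures aside, which are compared for
  existence and size, not bytes).
* Known limitations: Poisson only (no quasi-likelihood or negative
  binomial dispersion), fixed-df smooths only, single exposure series, no
  missing-data handling (gap-free calendars are enforced at load).
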