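# Methods

`streamtemp` implements a daily stream-temperature analysis for small stream
networks in three stages: (1) detect, per site and year, the window of the
year in which daily water and air temperatures are synchronized; (2) fit a
hierarchical Bayesian linear model with AR(1) residual adjustment to the
synchronized-period data; (3) quantify how missing data degrade predictions
through refit-and-score experiments.  A synthetic-data generator built on the
same model provides ground truth for every stage.

## Synchronization windows

Water in temperate headwater streams is bounded near 0 °C in winter while air
is not, so the two series decouple.  The dimensionless index

    tempIndex = (waterT − airT) / waterT        (defined only for waterT > 0)

is near 0 while the series track each other and flattens over the
synchronized season.  Per site-year the analysis:

1. computes the raw daily index (days with missing data or waterT ≤ 0 are
   invalid);
2. bounds the flat period by a two-sided 99.9% empirical percentile interval
   of the raw index over the middle 150 days of the year (days 125–274);
3. smooths the index with a centered 10-day moving average (an even window is
   taken left-heavy: 5 days before through 4 after; at least 5 valid days are
   required, windows truncate at the edges);
4. scans day 1 → 150 for the first run of 10 consecutive smoothed values
   inside the interval (spring breakpoint) and from the year's end back
   toward day 150 for the fall breakpoint.  Invalid smoothed days break a
   run; a side with no qualifying run is flagged not-found.

Knobs and defaults: CI level 0.999 (0.99 selectable), mid-days (125, 274),
window and run length 10 d, minimum 30 valid mid-days.  `flat_period_ci`
also offers a normal reference range (mean ± z·sd) because an empirical
0.05% quantile estimated from ~150 days is essentially that year's minimum;
the percentile interval remains the default.

Trends in breakpoint days across years are assessed with three nested OLS
models (day ~ year, + site, × site); the simplest model within 2 AIC of the
minimum is selected, and rates are reported per decade.  The window-widening
rate is (fall slope − spring slope) × 10.

## The hierarchical AR(1) model

Within each site-year window, observed daily mean water temperature
t[s,d,y] is modeled as

    t[s,d,y] ~ N(mu[s,d,y], sd)
    mu[s,d,y] = omega[s,d,y] + delta_s (t[s,d−1,y] − omega[s,d−1,y])

with mu = omega at the start of a series or after any gap (the AR term looks
back exactly one day).  The linear predictor is

    omega = alpha + b1 T + b2 T(−1) + b3 T(−2) + b4 F + b5 T·F
            + site offsets + site×T + alpha_y + b12,y D + b13,y D² + b14,y D³

where T is air temperature, F flow, and D a standardized day-of-year
covariate.  The year-level coefficient vectors B_y = (alpha_y, b12..b14,y)
are pooled as B_y ~ MVN(M, Sigma), which lets sparse years borrow strength
from the rest of the record (and lets entirely unobserved years be predicted
from the hyperdistribution).

Priors: alpha, b1..b11 and the free components of M are N(0, 100);
delta_s ~ N(mu_delta, sd_delta) truncated to (−1, 1) with mu_delta ~ U(−1, 1)
and sd_delta ~ U(0, 2); sd ~ U(0, 10); Sigma ~ inverse-Wishart(I₄, df = 5).
M[0] is fixed at 0: a free hyper-mean for the yearly intercept would be
redundant with alpha.  The inverse-Wishart notation is read as
(scale = I, df = l + 1); both parameters are module constants and easy to
change.

**Covariate standardization.** Air temperature and log flow are centered and
scaled over the training rows; day of year is mapped linearly to [−1, 1] over
the union of windows before the cubic is built (a cubic in raw day-of-year is
numerically hostile, and N(0,100) priors are only weakly informative on
standardized scales).  The constants are stored on the fitted object and all
reported curves are back-transformed.  Flow is log-transformed by default
(positive, right-skewed); both choices are switchable.

**Sampling.** The sampler is a Metropolis-within-Gibbs scheme written for
this model.  Conditional on delta, quasi-differencing (y~ = y − delta·y_prev
on rows with an observed previous day) makes every regression block
conjugate: normal updates for the fixed effects and each B_y, a normal
update for M, inverse-Wishart for Sigma, inverse-gamma for sd² (respecting
the U(0,10) truncation), and truncated-normal updates for each delta_s.
mu_delta and sd_delta take univariate slice-sampling steps because the
truncated-normal normalizer breaks conjugacy.  Chains start overdispersed
(ridge solution plus noise; delta ~ U(−0.2, 0.9)) and are seeded
deterministically per (seed, chain).  The default geometry mirrors the
original field analysis — 3 chains, 1,000 burn-in, 2,500 iterations thinned by 5 —
and experiment batteries default to 2 chains × 500 retained draws so that
dozens of refits stay desk-scale.  Convergence is monitored with the classic
Gelman–Rubin potential scale reduction factor; a fit is flagged converged
when all values are below 1.01.

**Posterior products.** Predictions are posterior summaries of mu: one-step
mode uses the AR adjustment wherever the previous day's water temperature is
available to the model, free-running mode never does.  Yearly seasonal
curves alpha + B_y·(1, u, u², u³) are evaluated on the day grid; their peak
and peak day are found analytically from the derivative's roots (clipped to
the window, edge-maxima flagged) and trends in the yearly peaks are ordinary
least-squares slopes reported per decade with an F test.

## Missing-data experiments

Every experiment masks part of the observed water record, refits the model
on the remainder, predicts the masked rows and reports train/test RMSE and
the difference from the all-data base fit.  Masked rows whose previous day
is also masked are predicted with the free-running mean, so no information
leaks through the AR term.  Train and test rows partition the observed rows
exactly (asserted per scenario).

* **leave-p-out** — mask a uniformly random proportion p of observed rows,
  for p in {0, .05, .1, .2, .3, .4, .5, .6, .7, .8}, 10 replicates each
  (configurable).
* **quantity** — trim 15·d observed days from both ends of every site-year
  series (d = 1..9); site-years shorter than the trim are left out entirely.
  A line of RMSE-difference against the retained fraction summarizes the
  value of additional days.
* **timing** — retain only one 30-day window of the target stream's data,
  with 13 starts from day 70 to day 310.  Thirteen non-overlapping 30-day
  windows cannot fit in that range, so the default uses evenly spaced starts
  (spacing 20, 10-day overlaps); a strictly non-overlapping 9-window mode is
  available.  Companion mode keeps the other streams' full records;
  lone mode restricts every stream to the window.
* **holdout** — mask one full year of the target (the mainstem, or all
  streams), per year; held-out years are predicted through the partial
  pooling path.

## The synthetic-data generator

The generator emulates a four-stream network observed for 15 years
(1999–2013): one shared regional air series, per-site flow, and water
produced by the model above inside each site-year's true window.

* **Air**: annual sinusoid (mean 9 °C, amplitude 14 °C, peak in late July)
  plus AR(1) anomalies (lag-1 correlation 0.6) whose marginal sd is
  seasonally modulated — about 4.5 °C midwinter and 2.5 °C midsummer around
  a 3.5 °C mean — matching the winter-amplified variability of daily mean
  air temperature in the region.
* **Flow**: log-normal relative discharge with a spring-peaked seasonal
  log-mean (amplitude 0.4), marginal log-sd 0.5, and AR(1) persistence 0.95
  (streamflow recession makes discharge strongly autocorrelated).
* **True windows**: spring near day 105 drifting −1.61 d/yr, fall near day
  290 drifting +1.33 d/yr, with 5-day site-year jitter — the drifting
  phenology the analysis is meant to detect.
* **Water, inside windows**: the model run generatively at true parameter
  values mirroring the field study's posterior means (air effects 1.52 / 0.20 /
  0.15, flow 0.36, site offsets −0.50 / +0.59 / −0.54, AR mean 0.79,
  residual sd 0.77).  The cubic hyper-means are derived, not hand-picked:
  they solve omega(d) = max(seasonal air mean, 6 °C) across the window span,
  so the generated series actually satisfy the synchronization premise
  (index ≈ 0 in-window) that the breakpoint detector relies on.  On the
  generation-side covariate scale, the air coefficients sum to a
  steady-state coupling of 0.75 °C of water per °C of air.  Yearly intercepts
  drift upward at 0.063 °C/yr (0.63 °C/decade), the study-scale warming
  signal.  Day 1 of each window takes the no-AR path; air lags always come
  from the year-round air series.
* **Water, outside windows**: first-order relaxation (rate 0.15/day) toward
  max(0 °C, 0.2·air) with small noise, clipped at 0 °C — flat, near-freezing
  winter water whose index is invalid on the coldest days, as in real logger
  records.  A 12-day ramp blends the winter target into the window-start
  predictor so the spring transition is continuous.  The model itself
  covers only the synchronized period, so this winter behaviour is a
  stand-in; nothing downstream fits it.
* **Missingness**: whole missing site-years (tributaries absent in early
  years, two mainstem years), within-year gaps, and random-fraction masks;
  the mask record allows exact inversion.  Air and flow are never masked.

One master seed is split deterministically per component, so identical
configurations are bit-reproducible.

**What passing tests on these data do and do not show.** The generator is
the fitted model plus stylized winter behaviour; recovery and coverage
results therefore validate the implementation (the estimator matches its own
generative model), not the model's adequacy for any real stream.  Real
records differ in ways the generator ignores: sub-daily structure aggregated
to daily means, heteroscedastic residuals (calmer at cold temperatures),
snowmelt events, sensor error and drift, and spatial covariance beyond
shared air.

## Numerical and scale choices

* Analyses in this repository run at reduced problem sizes chosen as the
  package's own defaults: the analysis scripts fit 2 chains × 500 retained
  draws (thin 2) on ~8,800 observed days, and experiment batteries use
  2 chains × 500 retained; the full-length geometry is one flag away.
* sd² draws are rejected (and redrawn) in the rare event they exceed the
  U(0, 10) truncation; slice steps are bounded to their supports.
* Quantile intervals use linear interpolation (type-7); AIC ties break to
  the simplest model; even-window centering is left-heavy.
* The breakpoint detector carries an intrinsic lag of a few days: the
  10-day moving average near a window edge mixes pre-window index values,
  so the first clean run typically starts ~5 days inside the true window.
  With the field-estimated residual parameters (sd 0.77, AR 0.79) the smoothed
  index near cold window edges also wanders outside the mid-season interval
  for runs of days at a time, so occasional detection errors beyond 10 days
  are inherent to the runs-analysis method on this class of data — a
  limitation worth knowing when interpreting breakpoint phenology.
* Day-of-year is 1-based and leap days are kept (day 366 allowed).

## Known limitations

* No explicit spatial covariance between streams (site terms only), no
  landscape covariates, and no physical heat-budget processes.
* The winter decoupling law is a visual stand-in, not a calibrated model.
* The quantity/timing experiment designs count observed in-window days, not
  calendar days, where the two differ.
* Whether the original coefficients were estimated on standardized
  covariates is not documented; recovery experiments therefore compare
  estimates on the synthetic truth's own scale.
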