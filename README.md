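# streamtemp

Daily stream-temperature analysis for small stream networks: find the part of
each year when water and air temperatures are synchronized, model daily water
temperature within it, and quantify what missing data cost you.

Stream ecologists and watershed managers need daily water-temperature
estimates from logger networks that are invariably incomplete — loggers fail,
deployments start late, winters are unusable.  `streamtemp` implements a
three-stage analysis for that setting:

1. **Synchronization windows.**  The index `(waterT − airT)/waterT`
   (defined for waterT > 0) is near 0 while water tracks air and explodes in
   winter.  Per site-year, a centered 10-day moving average of the index is
   scanned for the first and last run of 10 consecutive days inside the
   99.9% flat-period interval, giving spring and fall breakpoints — a
   data-driven alternative to fixed calendar cutoffs, and itself a phenology
   signal (is the window widening across years?).
2. **A hierarchical Bayesian model** of daily water temperature t within the
   window:

       t[s,d,y] ~ N(mu[s,d,y], sd)
       mu[s,d,y] = omega[s,d,y] + delta_s (t[s,d-1,y] - omega[s,d-1,y])
       omega = alpha + b1*T + b2*T(-1) + b3*T(-2) + b4*F + b5*T*F
               + site + site*T + alpha_y + b12,y*D + b13,y*D^2 + b14,y*D^3

   with air temperature T at lags 0–2, flow F, site fixed effects, an AR(1)
   adjustment delta_s on yesterday's residual (thermal inertia), and a
   random cubic in day-of-year D per year, pooled as B_y ~ MVN(M, Sigma) —
   the pooling is what lets years or streams with little data borrow
   strength from the rest of the network.  Sampling is a mostly conjugate
   Metropolis-within-Gibbs scheme (see `docs/methods.md`); convergence is
   checked with the Gelman–Rubin R-hat.
3. **Missing-data experiments.**  Leave-p-out cross-validation plus
   structured designs (trim days from the season's ends, keep only one
   30-day window, hold out whole site-years), each a full refit scored on
   the held-out rows as RMSE.

A synthetic-data generator (`streamtemp.synthetic`) produces multi-site
multi-year daily records from the model's own generative process — seasonal
air with AR(1) anomalies, persistent log-normal flow, winter decoupling with
water bounded at 0 °C, drifting true windows, deployment-style missingness —
so every stage can be validated against known truth.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic data
(seed 1) and write tables under `results/`:

```
$ python analysis/01_simulate.py
simulated 21916 site-days over 4 sites, 15 years; 16581 observed water days (24% missing by design)

$ python analysis/02_breakpoints.py
detected windows for 44/60 site-years
spring breakpoint trend -1.02 d/yr (p=0.002, model 'year'); fall +1.24 d/yr (p=0.000)
synchronized window widening: +22.6 d/decade

$ python analysis/03_fit_model.py
air-T effect 3.29 (standardized; 0.60 degC water per degC air), AR mean 0.79, residual sd 0.79; max R-hat 1.006
one-step fit: RMSE 0.79 degC; observed~predicted slope 1.00, intercept 0.01, R2 0.98
yearly peak temperature trend +0.27 degC/decade (F=0.94, p=0.351); day-of-peak trend +2.0 d/decade (p=0.21)

$ python analysis/04_assess.py
base (all data) RMSE 0.79 degC
leave-10%-out: test RMSE 0.85 (diff +0.06)
leave-30%-out: test RMSE 0.96 (diff +0.17)
leave-50%-out: test RMSE 1.05 (diff +0.26)
year holdout: mainstem only +0.50 degC vs all streams +0.56 degC (partial pooling softens the single-stream case)

$ python analysis/05_describe.py
cumulative residuals: warmest site-year OS 2013 (+359 degC-days), coolest OL 2003 (-243)
between-site daily water correlations 0.983..0.987
```

Reading the output: the detector recovers the generator's drifting windows
(truth: spring −1.61 d/yr, fall +1.33 d/yr, attenuated here because missing
site-years thin the early record); the fit recovers the true AR coefficient
(0.79) and residual sd (0.77) and an air–water sensitivity of 0.60 °C/°C;
the yearly-peak trend estimate is consistent with the planted 0.63 °C/decade
warming given only 15 years of year-level noise; and the experiments show
the partial-pooling signature — masking 30% of days costs +0.17 °C of test
RMSE, losing one stream's whole year +0.50 °C, and losing the entire
network's year slightly more (+0.56 °C).

The same stages are available as a CLI (`streamtemp simulate | breakpoints |
fit | assess | describe | run`) and as library calls; see `docs/methods.md`
for the model, priors, sampler and design choices.

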