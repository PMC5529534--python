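# Methods

This document records the statistical methods, parameter defaults, numerical
choices and known limitations of `cariestrend`. The package models a short
annual prevalence series (percent of children with at least one carious
primary tooth) obtained by pooling repeated cross-sectional surveys, and
produces short-horizon forecasts from two complementary models.

## 1. Data model

A `PrevalenceSeries` is a contiguous run of calendar years with one percent
value per year, each strictly inside (0, 100). The bundled benchmark is a
pooled national series for 5-year-olds, 1988–2010 (23 values, 81.2% → 55.1%),
with holdout actuals for 2011–2013 (63.5, 56.1, 60.3). Contiguity is
enforced at construction: time-series methods below assume equally spaced
observations, and silently skipping missing years would corrupt every lag.

## 2. Per-year meta-analytic pooling (`pooling`)

Each year's surveys are pooled on the **logit scale** by default: effects
y_i = log(x_i/(n_i − x_i)) with variance v_i = 1/x_i + 1/(n_i − x_i). The
logit scale stabilises variances and keeps back-transformed confidence
limits inside (0, 100); a raw-proportion scale is retained for comparison
with older practice. Boundary counts (0 or n) get a 0.5 continuity
correction.

- **Heterogeneity**: Cochran's Q (chi-square, k−1 df), I² = max(0,
  100·(Q−(k−1))/Q), and the DerSimonian–Laird moment estimator of tau².
- **Model choice rule**: random effects whenever I² > 50% **or** the Q-test
  p-value is below 0.1; otherwise fixed-effect inverse-variance. The
  thresholds are the conventional screening values in the applied
  meta-analysis literature; both are module constants (`I2_THRESHOLD`,
  `Q_PVALUE_THRESHOLD`).
- **Single-study years** use the study estimate with a Wilson score
  interval (better coverage than Wald at moderate n and extreme p).
- **Publication bias**: Begg's rank-correlation test — Kendall's tau between
  standardized deviates t_i = (y_i − ȳ)/√(v_i − 1/Σw) and the variances,
  exact p by enumeration for k ≤ 8 without ties, normal approximation
  otherwise.

Years with no studies make the pooled series non-contiguous and raise an
error naming the gap year rather than interpolating silently.

## 3. Stationarity and specification diagnostics (`diagnostics`)

- **ADF**: OLS on Δx_t = α + ρ·x_{t−1} + Σ γ_j Δx_{t−j} + ε; lag order
  chosen by AIC over 0..max_lag on a common estimation sample, then refitted
  at the chosen lag. P-values use the MacKinnon (1994) response-surface
  polynomials (constant and constant+trend cases), hand-entered and verified
  against an independent implementation to 4 decimals. Default max_lag is
  the conventional ⌊12·(n/100)^{1/4}⌋ cap bounded by sample size.
- **KPSS**: level-stationarity statistic with Bartlett-kernel (Newey–West)
  long-run variance; p-values interpolated in the published critical-value
  table [0.347, 0.463, 0.574, 0.739] ↔ p [0.10, 0.05, 0.025, 0.01] and
  truncated to [0.01, 0.10] outside it, as is standard.
- **ACF/PACF**: biased (1/n) autocovariance normalisation; PACF by
  Durbin–Levinson; correlogram bands ±1.96/√n.
- **Ljung–Box**: Q = n(n+2)·Σ_{k≤h} ρ_k²/(n−k), chi-square with h − (p+q)
  df when applied to ARMA residuals. Default h = min(10, n/4).
- **Chow breakpoint**: F-test comparing pooled vs split OLS of prevalence on
  an intercept + linear year term (k = 2), used to ask whether the trend
  breaks at the train/holdout boundary.

Known finite-sample behaviour, verified by the test suite: ADF with AIC
autolag has empirical size slightly above nominal (≈7% at n=250); KPSS
power against a pure random walk at n=500 is high (≈90%) but not 1 because
the Newey–West bandwidth grows with n.

## 4. ARIMA by conditional least squares (`arima`)

ARIMA(p, d, q) is fitted to the d-times differenced series by **conditional
sum of squares** (CSS): presample shocks set to zero, conditioning on the
first p differenced observations, residuals computed by linear filtering.
This matches the nonlinear least-squares estimator of classic econometric
packages rather than exact maximum likelihood.

- **Constraint handling**: stationarity of the AR part and invertibility of
  the MA part are enforced through the partial-autocorrelation
  reparametrisation (unconstrained ℝ → (−1,1) via x/√(1+x²) → coefficients
  via Durbin–Levinson). Unconstrained CSS on very short series is
  degenerate: on the 23-point benchmark it drives the MA roots inside the
  unit circle and chases noise (R² ≈ 0.98 with non-invertible roots), so the
  constrained estimator is the only one offered.
- **Optimisation**: Hannan–Rissanen start plus six fixed-seed random
  restarts; Nelder–Mead followed by a BFGS polish. The restart seeds are
  fixed constants so fits are deterministic.
- **Reported statistics**: sigma² = CSS/n_eff, Gaussian log-likelihood, AIC
  (total and per-observation), R² on the differenced scale, coefficient
  t-statistics from the numerical Hessian, regression F.
- **Order selection**: d is increased (max 2) until ADF rejects a unit
  root (KPSS recorded as a cross-check); (p, q) minimises AIC over a grid,
  restricted to fits whose residuals pass Ljung–Box; ties prefer fewer
  parameters, then lower q. Because CSS conditions on p observations, each
  fit's own AIC is computed on a different sample size; candidates are
  therefore ranked on an AIC recomputed over a **common sample** (first
  max_p observations dropped for every candidate) — without this, larger p
  is spuriously favoured whenever sigma² > 1.
- **Forecasts**: the ARMA recursion with future shocks at zero, integrated
  d times; 95% intervals from psi-weight cumulative variances.

On the benchmark series, ARIMA(2,1,3) attains R² ≈ 0.64 on the differenced
scale with white residuals; one-step fitted values begin in year d + p + 1.

## 5. GM(1,1) grey model (`grey`)

For short, scarce series the grey model imposes a rigid but very
parsimonious structure. With original series x⁰(k), k = 1..n (n ≥ 4, all
positive):

1. **AGO**: x¹(k) = Σ_{i≤k} x⁰(i), the accumulated series.
2. **Background values**: z¹(k) = (x¹(k) + x¹(k−1))/2, k = 2..n.
3. **Least squares** on the grey equation x⁰(k) = −a·z¹(k) + b gives the
   development coefficient a and grey input b.
4. **Time response** of the whitened ODE dy/dt + a·y = b:
   ŷ¹(k+1) = (x⁰(1) − b/a)·e^(−a·k) + b/a.
5. **Restore** fitted values by first differences of ŷ¹; forecasts extend
   the same recursion, each successive year scaled by e^(−a).

Exact properties (all asserted in the tests): inverse accumulation is an
identity; restored increments are geometric with ratio exactly e^(−a); for
exactly geometric input x⁰(k) = c·q^{k−1} the grey regression has zero
residual with closed-form a = 2(1−q)/(1+q), b = 2c/(1+q) — note e^(−a) ≠ q,
so restored values approximate (not reproduce) a geometric input, with error
vanishing as q → 1; scaling the data by c scales b and all fitted values by
c and leaves a unchanged; a → 0 (constant data) is handled by the analytic
limit with a 1e−12 guard.

On the benchmark: a = 0.01587, b/a = 5069.39, in-sample MAE 4.81 points and
MAPE 7.34% over 1989–2010, forecasts 55.4, 54.5, 53.7 (2011–2013; absolute
errors 8.1, 1.6, 6.6 against the holdout) and 52.8, 52.0, 51.2, 50.4, 49.6
(2014–2018).

## 6. Accuracy evaluation (`evaluation`)

MAE is in percentage points, MAPE in percent of the actual. Accuracy tables
follow the reporting convention of the surveillance literature: **per-year
table cells are computed from fitted values rounded to one decimal** (the
precision at which they are displayed), while the **averages are computed at
full precision**; both displayed-cell averages and full-precision averages
are reported. Warm-up years without a fitted value (year 1 for the grey
model, years 1..d+p for ARIMA) are excluded from that model's averages, so
the two models may average over different denominators. Model comparison
declares a preferred model only under weak dominance in all four averages
(fitting and prediction MAE and MAPE) with strict improvement somewhere;
otherwise it is reported as inconclusive.

## 7. Synthetic data (`synthetic`)

The study-table generator emulates the sampling situation the pooling stage
is meant for: each year carries `studies_per_year` binomial surveys with
sizes uniform in [200, 1000]; true study-level prevalences follow a
logit-linear secular trend (default intercept 1.4, slope −0.05 per year on
the log-odds scale — roughly the bundled benchmark's decline) plus
normal random effects of scale tau (default 0.2) on the logit scale. It
deliberately does **not** emulate: publication bias or small-study effects,
regional clustering, age-structure differences between surveys, diagnostic
criteria drift, or overdispersion beyond the logit-normal random effect.
The ARMA generator simulates stationary Gaussian ARMA processes with a
burn-in of 10·max(p, q) + 50 and rejects non-stationary coefficient sets.
All randomness flows from an explicit integer seed through NumPy's PCG64.

## 8. Numerical and design choices

- All estimators are deterministic given their inputs (ARIMA restart seeds
  are fixed constants); the pipeline writes no timestamps, so reruns are
  byte-identical.
- The pooling, diagnostics and estimation code is implemented directly on
  NumPy/SciPy primitives; an independent reference implementation
  (statsmodels) is used **in the tests only** to cross-check ADF, KPSS,
  Ljung–Box, ACF/PACF and the ARIMA estimator on simulated series.
- Benchmark problem sizes (23 training years, 3 holdout years, 8-year
  forecast horizon, order grids up to p, q ≤ 3) are the package's own
  defaults, chosen to exercise the short-series regime the methods target;
  all are configurable.

## 9. Limitations

- CSS, not exact ML: coefficient estimates differ slightly from
  full-likelihood implementations, increasingly so for short series and
  near-unit MA roots; order selection on 20 usable differenced observations
  is inherently unstable, which is why the selection report exposes the full
  grid rather than a single answer.
- The GM(1,1) forecast is a pure geometric decay; it cannot represent
  level shifts, rebounds, or any non-monotone future, and its prediction
  interval theory is not implemented.
- Pooling treats surveys within a year as exchangeable given the random
  effect; no meta-regression on covariates (region, survey method) is
  available.
- MAPE is asymmetric and undefined at zero actuals; with prevalences well
  inside (0, 100) this is harmless here, but both MAE and MAPE are always
  reported together.
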