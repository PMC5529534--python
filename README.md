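# cariestrend

Trend modelling and short-horizon forecasting of early-childhood-caries (ECC)
prevalence from repeated cross-sectional surveys.

National oral-health surveillance rarely produces one clean annual time
series: each calendar year is covered by a handful of regional surveys of
different sizes, and policy questions ("is prevalence declining, and where
will it be in five years?") require first pooling those surveys into an
annual series and then fitting time-series models to it. `cariestrend`
implements that pipeline end to end:

1. **Per-year meta-analytic pooling** — inverse-variance pooling of survey
   prevalences on the logit scale, Cochran's Q / I² heterogeneity statistics,
   DerSimonian–Laird random effects when heterogeneity is material
   (I² > 50% or Q-test p < 0.1), and Begg's rank-correlation screen for
   publication bias.
2. **Stationarity diagnostics** — augmented Dickey–Fuller and KPSS tests
   (with MacKinnon response-surface p-values), ACF/PACF correlograms,
   Ljung–Box whiteness tests, and a Chow breakpoint test for structural
   change.
3. **ARIMA(p, d, q)** fitted by conditional least squares under enforced
   stationarity/invertibility, with AIC-based order selection and
   psi-weight forecast intervals.
4. **GM(1,1) grey model** — the single-variable first-order grey model,
   suited to short, scarce series. The original series x⁰ is accumulated to
   x¹, the whitened equation

       dy(t)/dt + a·y(t) = b

   is fitted by least squares on the background sequence
   z¹(k) = (x¹(k) + x¹(k−1))/2, and fitted/forecast values are restored by
   inverse accumulation of the time response
   ŷ¹(t) = (x⁰(1) − b/a)·e^(−a(t−1)) + b/a. The development coefficient `a`
   is the per-year geometric decay rate of the restored series.
5. **Model comparison** — MAE/MAPE accuracy tables over a fitting window and
   a holdout prediction window.
6. **Synthetic data** — a generator of study tables (binomial surveys around
   a logit-linear trend with log-odds-scale random effects) and of ARMA
   series, used throughout the test suite for parameter-recovery and
   test-calibration checks.

A small benchmark dataset is bundled: a pooled national ECC-prevalence
series for 5-year-olds, 1988–2010 (23 annual values, declining from 81.2% to
55.1%), plus holdout actuals for 2011–2013.

## Worked example

```python
from cariestrend import ago, fit_gm11, gm_forecast, gm_restore, \
    load_benchmark_series, mae, mape

series = load_benchmark_series()      # 1988-2010, percent prevalence
seq = ago(series)
fit = fit_gm11(seq)
print(fit.a, fit.b_over_a)            # 0.015872...  5069.39...

restored = gm_restore(fit, seq)       # fitted values, 1989-2010
print(mae(series.values, restored))   # 4.81
print(mape(series.values, restored))  # 7.34

fc = gm_forecast(fit, 8)              # 2011-2018
print(dict(zip(fc.years, fc.values.round(1))))
```

Output:

```
0.01587200048943579 5069.393844498252
4.813014400808888
7.338910852617536
{2011: 55.4, 2012: 54.5, 2013: 53.7, 2014: 52.8,
 2015: 52.0, 2016: 51.2, 2017: 50.4, 2018: 49.6}
```

Longer narrative walk-throughs live in `examples/`:

- `examples/grey_model_benchmark.py` — GM(1,1) on the benchmark series.
- `examples/arima_workflow.py` — full Box–Jenkins workflow (ADF/KPSS,
  correlogram, ARIMA(2,1,3), residual whiteness, interval forecasts).
- `examples/pool_synthetic_surveys.py` — simulate surveys and pool them.
- `examples/compare_models_holdout.py` — ARIMA vs GM(1,1) head-to-head on
  the train/holdout split.

## Command line

A thin `click` wrapper exposes the same pipeline:

```bash
cariestrend run --input series.csv --input-kind series --out results/run1
cariestrend simulate --seed 7 --out studies.csv
cariestrend pool --input studies.csv --out pooled.csv
cariestrend diagnose --input series.csv
cariestrend fit --input series.csv --order 2,1,3
cariestrend forecast --input series.csv --order 2,1,3 --horizon 8
```

`cariestrend run` writes a self-contained artifact directory (pooled series,
diagnostics JSON, both model fits, forecasts, comparison tables, and a
manifest); reruns with the same inputs are byte-identical.

## Layout

```
src/cariestrend/
  series.py        PrevalenceSeries container + bundled benchmark loaders
  synthetic.py     study-table and ARMA series generators
  pooling.py       per-year meta-analysis (DL random effects, Begg's test)
  diagnostics.py   ADF, KPSS, ACF/PACF, Ljung-Box, Chow
  arima.py         CSS ARIMA fitting, order selection, forecasting
  grey.py          GM(1,1): AGO, fit, restore, forecast
  evaluation.py    MAE/MAPE accuracy reports and model comparison
  pipeline.py      end-to-end run with on-disk artifacts
  cli.py           click command group
docs/methods.md    modelling and numerical choices, assumptions, limitations
```
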