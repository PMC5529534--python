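"""Head-to-head model comparison on the benchmark train/holdout split.

Trains ARIMA(2,1,3) and GM(1,1) on 1988-2010, forecasts 2011-2013, and scores
both windows with MAE (percentage points) and MAPE (%). Warm-up years without
a fitted value (1988 for the grey model, 1988-1990 for ARIMA) are excluded
from that model's averages.
"""

import numpy as np

from cariestrend import (
    ArimaSpec, PrevalenceSeries, ago, compare_models, fit_arima, fit_gm11,
    fitted_values, forecast, gm_forecast, gm_restore,
    load_benchmark_series, load_holdout_actuals,
)

train = load_benchmark_series()
full = train.concat(load_holdout_actuals())

afit = fit_arima(train, ArimaSpec(2, 1, 3))
seq = ago(train)
gfit = fit_gm11(seq)

comparison = compare_models(
    full,
    fitted={"arima": fitted_values(afit), "gm11": gm_restore(gfit, seq)},
    predicted={"arima": PrevalenceSeries(np.arange(2011, 2019), forecast(afit, 8).point),
               "gm11": gm_forecast(gfit, 8)},
    split_year=2010,
)

for window in ("fitting", "prediction"):
    print(f"\n{window} window:")
    for name, rep in getattr(comparison, window).items():
        print(f"  {name:6s} MAE = {rep.average_mae:5.2f} pp   "
              f"MAPE = {rep.average_mape:5.2f}%   ({rep.n_years} years)")

print(f"\npreferred model (lower errors in both windows): {comparison.preferred}")
print("\nholdout detail for the grey model:")
print(comparison.prediction["gm11"].table.to_string(index=False))
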