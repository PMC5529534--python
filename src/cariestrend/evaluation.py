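"""MAE / MAPE accuracy indices and the two-model comparison report.

MAE = mean |y_t - yhat_t| (percentage points); MAPE = mean |y_t - yhat_t| /
y_t, reported in percent. Years where a model has no fitted value (its
warm-up: the first year for the grey model, the first d + p years for ARIMA)
are excluded from that model's averages — never zero-filled — so the two
models are averaged over different denominators in the fitting window.

The per-year columns of the rendered report follow the display convention of
the field's comparison tables: fitted values are rounded to one decimal
before the error columns are derived from them. Averages are always computed
from full-precision errors; the average over the rounded per-year cells is
emitted alongside for completeness.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping

import numpy as np
import pandas as pd

from .series import PrevalenceSeries

__all__ = ["AccuracyReport", "mae", "mape", "compare_models", "ModelComparison"]


def _aligned(actual, predicted) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(actual, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if a.shape != p.shape:
        raise ValueError("actual and predicted must have equal length")
    ok = np.isfinite(a) & np.isfinite(p)
    if not ok.any():
        raise ValueError("no overlapping non-missing pairs to score")
    return a[ok], p[ok]


def mae(actual, predicted) -> float:
    """Mean absolute error over aligned non-missing pairs, in percentage points."""
    a, p = _aligned(actual, predicted)
    return float(np.mean(np.abs(a - p)))


def mape(actual, predicted) -> float:
    """Mean absolute percentage error over aligned non-missing pairs, in percent."""
    a, p = _aligned(actual, predicted)
    if np.any(a == 0):
        raise ValueError("MAPE undefined when an actual value is zero")
    return float(np.mean(np.abs(a - p) / np.abs(a)) * 100.0)


@dataclass(frozen=True)
class AccuracyReport:
    model_name: str
    window: Literal["fitting", "prediction"]
    table: pd.DataFrame  # year, actual, predicted, abs_error, abs_pct_error
    average_mae: float   # from full-precision errors
    average_mape: float
    average_mae_displayed: float   # mean of the rounded per-year cells
    average_mape_displayed: float

    @property
    def n_years(self) -> int:
        return int(self.table["abs_error"].notna().sum())


def _report(name: str, window: str, years, actual, predicted) -> AccuracyReport:
    actual = np.asarray(actual, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    # display convention: error cells derive from 1-decimal fitted values
    shown = np.round(predicted, 1)
    abs_err = np.abs(actual - shown)
    pct_err = np.round(abs_err, 1) / actual * 100.0
    tab = pd.DataFrame(
        {
            "year": np.asarray(years, dtype=int),
            "actual": actual,
            "predicted": shown,
            "abs_error": np.round(abs_err, 1),
            "abs_pct_error": np.round(pct_err, 1),
        }
    )
    ok = np.isfinite(predicted)
    return AccuracyReport(
        model_name=name,
        window=window,  # type: ignore[arg-type]
        table=tab,
        average_mae=mae(actual, predicted),
        average_mape=mape(actual, predicted),
        average_mae_displayed=float(np.nanmean(np.round(abs_err[ok], 1))),
        average_mape_displayed=float(np.nanmean(np.round(pct_err[ok], 1))),
    )


@dataclass(frozen=True)
class ModelComparison:
    fitting: dict[str, AccuracyReport]
    prediction: dict[str, AccuracyReport]
    preferred: str | None  # model dominating both windows on MAE and MAPE; None on a tie

    def to_frame(self) -> pd.DataFrame:
        """Long-format frame mirroring the side-by-side comparison tables."""
        frames = []
        for window, reports in (("fitting", self.fitting), ("prediction", self.prediction)):
            for name, rep in reports.items():
                t = rep.table.copy()
                t.insert(0, "model", name)
                t.insert(1, "window", window)
                frames.append(t)
        return pd.concat(frames, ignore_index=True)


def compare_models(
    actual: PrevalenceSeries,
    fitted: Mapping[str, np.ndarray],
    predicted: Mapping[str, PrevalenceSeries],
    split_year: int,
) -> ModelComparison:
    """Score each model's in-sample fit (through ``split_year``) and its
    out-of-sample forecasts against the holdout years after it.

    ``fitted`` maps model name to per-year fitted values aligned with
    ``actual``'s years up to split_year (NaN for warm-up years); ``predicted``
    maps model name to a forecast series covering the holdout years.
    """
    if not (actual.start_year < split_year < actual.end_year):
        raise ValueError("split_year must fall strictly inside the actual series span")
    train = actual.slice_years(actual.start_year, split_year)
    hold = actual.slice_years(split_year + 1, actual.end_year)

    fitting = {}
    for name, values in fitted.items():
        v = np.asarray(values, dtype=float)
        if len(v) != len(train):
            raise ValueError(f"fitted values for {name!r} do not align with the fitting window")
        fitting[name] = _report(name, "fitting", train.years, train.values, v)

    prediction = {}
    for name, fc in predicted.items():
        try:
            sub = fc.slice_years(hold.start_year, hold.end_year)
        except KeyError as exc:
            raise ValueError(f"forecast for {name!r} does not cover the holdout window") from exc
        prediction[name] = _report(name, "prediction", hold.years, hold.values, sub.values)

    preferred = None
    names = sorted(set(fitting) & set(prediction))
    for cand in names:
        others = [n for n in names if n != cand]
        if others and all(
            fitting[cand].average_mae <= fitting[o].average_mae
            and fitting[cand].average_mape <= fitting[o].average_mape
            and prediction[cand].average_mae <= prediction[o].average_mae
            and prediction[cand].average_mape <= prediction[o].average_mape
            for o in others
        ):
            strictly = any(
                fitting[cand].average_mae < fitting[o].average_mae
                or prediction[cand].average_mae < prediction[o].average_mae
                for o in others
            )
            if strictly:
                preferred = cand
                break
    return ModelComparison(fitting=fitting, prediction=prediction, preferred=preferred)
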