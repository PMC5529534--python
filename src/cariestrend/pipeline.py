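"""End-to-end driver: pool -> diagnose -> fit (ARIMA + GM) -> forecast -> evaluate.

Reproduces the full benchmark workflow from either a study-level CSV (pooled
per year first) or a pre-pooled series CSV. Every artifact is written to the
output directory together with a manifest recording the configuration, so a
run can be re-executed from the manifest alone.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .arima import ArimaSpec, fit_arima, fitted_values, forecast, select_order
from .diagnostics import adf_test, chow_breakpoint_test, kpss_test, ljung_box
from .evaluation import ModelComparison, compare_models
from .grey import ago, fit_gm11, gm_forecast, gm_restore
from .pooling import build_series, load_study_csv
from .series import PrevalenceSeries

__all__ = ["RunConfig", "run_pipeline"]


@dataclass(frozen=True)
class RunConfig:
    input_path: str
    output_dir: str
    input_kind: str = "series"        # "series" (pre-pooled) or "studies"
    split_year: int = 2010
    forecast_end_year: int = 2018
    arima_order: tuple[int, int, int] | None = (2, 1, 3)  # None = auto-select
    significance: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.split_year >= self.forecast_end_year:
            raise ValueError("split_year must precede forecast_end_year")
        if not 0 < self.significance < 1:
            raise ValueError("significance level must lie in (0, 1)")
        if self.input_kind not in ("series", "studies"):
            raise ValueError("input_kind must be 'series' or 'studies'")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _load(config: RunConfig) -> tuple[PrevalenceSeries, pd.DataFrame | None]:
    if config.input_kind == "studies":
        studies = load_study_csv(config.input_path)
        return build_series(studies)
    return PrevalenceSeries.from_csv(config.input_path), None


def run_pipeline(config: RunConfig) -> ModelComparison | None:
    """Execute the full pipeline; returns the model comparison when the data
    extend beyond the split year, else None (fit-and-forecast only)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    alpha = config.significance

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except Exception as exc:  # noqa: BLE001 - annotate and rethrow
                raise StageError(name, exc) from exc
        return deco

    series, pooled_frame = stage("load")(lambda: _load(config))
    if not series.start_year < config.split_year <= series.end_year:
        raise StageError("load", ValueError(
            f"split_year {config.split_year} outside data span "
            f"{series.start_year}-{series.end_year}"))
    series.to_csv(out / "series.csv")
    if pooled_frame is not None:
        pooled_frame.to_csv(out / "pooled_by_year.csv", index=False)

    train = series.slice_years(series.start_year, config.split_year)
    has_holdout = series.end_year > config.split_year

    def diagnose():
        d: dict = {
            "adf_level": adf_test(train, alpha=alpha).to_dict(),
            "adf_diff1": adf_test(np.diff(train.values), alpha=alpha).to_dict(),
            "kpss_level": kpss_test(train, alpha=alpha).to_dict(),
        }
        if has_holdout and (config.split_year - series.start_year >= 2
                            and series.end_year - config.split_year >= 3):
            d["chow"] = chow_breakpoint_test(series, config.split_year, alpha=alpha).to_dict()
        return d

    diagnostics = stage("diagnose")(diagnose)

    def fit_models():
        if config.arima_order is None:
            spec, selection = select_order(train, alpha=alpha)
        else:
            spec, selection = ArimaSpec(*config.arima_order), None
        afit = fit_arima(train, spec)
        gfit = fit_gm11(ago(train))
        return afit, gfit, selection

    arima_fit, grey_fit, selection = stage("fit")(fit_models)
    n_resid = len(arima_fit.residuals)
    lb_h = min(max(arima_fit.spec.n_arma + 2, 8), n_resid - 1)
    lb = ljung_box(arima_fit.residuals, h=lb_h,
                   fitted_params=arima_fit.spec.n_arma,
                   alpha=alpha) if n_resid > arima_fit.spec.n_arma + 2 else None
    diagnostics["ljung_box_arima_residuals"] = lb.to_dict() if lb else None
    if selection is not None:
        diagnostics["order_selection"] = selection
    (out / "diagnostics.json").write_text(json.dumps(diagnostics, indent=2, default=float))
    (out / "arima_fit.json").write_text(json.dumps(arima_fit.to_dict(), indent=2, default=float))
    (out / "gm_fit.json").write_text(json.dumps(grey_fit.to_dict(), indent=2, default=float))

    horizon = config.forecast_end_year - config.split_year

    def do_forecasts():
        afc = forecast(arima_fit, horizon, alpha=alpha)
        gfc = gm_forecast(grey_fit, horizon)
        return afc, gfc

    arima_fc, grey_fc = stage("forecast")(do_forecasts)
    pd.DataFrame({"year": arima_fc.years, "point": arima_fc.point,
                  "low": arima_fc.interval_low, "high": arima_fc.interval_high}
                 ).to_csv(out / "forecast_arima.csv", index=False)
    pd.DataFrame({"year": grey_fc.years, "value": grey_fc.values}
                 ).to_csv(out / "forecast_gm.csv", index=False)

    comparison = None
    if has_holdout:
        def evaluate():
            fitted = {
                "arima": fitted_values(arima_fit),
                "gm11": gm_restore(grey_fit, ago(train)),
            }
            predicted = {"arima": PrevalenceSeries(arima_fc.years, arima_fc.point),
                         "gm11": grey_fc}
            return compare_models(
                series.slice_years(series.start_year,
                                   min(series.end_year, config.forecast_end_year)),
                fitted, predicted, config.split_year)
        comparison = stage("evaluate")(evaluate)
        comparison.to_frame().to_csv(out / "comparison.csv", index=False)
        summary = {
            w: {name: {"mae": rep.average_mae, "mape": rep.average_mape,
                       "n_years": rep.n_years}
                for name, rep in getattr(comparison, w).items()}
            for w in ("fitting", "prediction")
        }
        summary["preferred"] = comparison.preferred
        (out / "comparison_summary.json").write_text(json.dumps(summary, indent=2))

    manifest = {
        "package": "cariestrend",
        "version": __version__,
        # output_dir is omitted: it is the manifest's own directory, and
        # recording it would make otherwise-identical runs differ byte-wise
        "config": {k: v for k, v in asdict(config).items() if k != "output_dir"},
        "series_span": [series.start_year, series.end_year],
        "artifacts": sorted(p.name for p in out.iterdir() if p.is_file()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return comparison
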