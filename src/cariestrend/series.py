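"""Year-indexed prevalence series container and bundled benchmark data.

Prevalence is always handled on the 0-100 percent scale. A series covers a
contiguous span of calendar years; gaps are a hard error everywhere in the
pipeline because both forecasting models assume an evenly spaced annual
sequence.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PrevalenceSeries",
    "load_benchmark_series",
    "load_holdout_actuals",
]


@dataclass(frozen=True)
class PrevalenceSeries:
    """Annual prevalence (percent) over a contiguous span of years."""

    years: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        years = np.asarray(self.years, dtype=int)
        values = np.asarray(self.values, dtype=float)
        if years.ndim != 1 or values.ndim != 1 or len(years) != len(values):
            raise ValueError("years and values must be 1-D and equally long")
        if len(years) == 0:
            raise ValueError("series must not be empty")
        if not np.all(np.diff(years) == 1):
            raise ValueError("years must be contiguous and strictly increasing")
        if np.any(~np.isfinite(values)) or np.any(values <= 0) or np.any(values >= 100):
            raise ValueError("prevalence values must lie strictly inside (0, 100)")
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return len(self.years)

    @property
    def start_year(self) -> int:
        return int(self.years[0])

    @property
    def end_year(self) -> int:
        return int(self.years[-1])

    def value_for(self, year: int) -> float:
        if not self.start_year <= year <= self.end_year:
            raise KeyError(f"year {year} outside span {self.start_year}-{self.end_year}")
        return float(self.values[year - self.start_year])

    def slice_years(self, first: int, last: int) -> "PrevalenceSeries":
        """Sub-series covering [first, last] inclusive."""
        if first > last:
            raise ValueError("first year must not exceed last year")
        if first < self.start_year or last > self.end_year:
            raise KeyError(f"span {first}-{last} outside {self.start_year}-{self.end_year}")
        i, j = first - self.start_year, last - self.start_year + 1
        return PrevalenceSeries(self.years[i:j], self.values[i:j])

    def concat(self, other: "PrevalenceSeries") -> "PrevalenceSeries":
        if other.start_year != self.end_year + 1:
            raise ValueError("series to append must start the year after this one ends")
        return PrevalenceSeries(
            np.concatenate([self.years, other.years]),
            np.concatenate([self.values, other.values]),
        )

    def to_pandas(self) -> pd.Series:
        return pd.Series(self.values, index=pd.Index(self.years, name="year"), name="prevalence")

    def to_csv(self, path) -> None:
        self.to_pandas().to_frame().to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "PrevalenceSeries":
        df = pd.read_csv(path)
        if not {"year", "prevalence"}.issubset(df.columns):
            raise ValueError("series CSV needs columns 'year' and 'prevalence'")
        df = df.sort_values("year")
        return cls(df["year"].to_numpy(int), df["prevalence"].to_numpy(float))


def _fixture(name: str) -> PrevalenceSeries:
    ref = importlib.resources.files("cariestrend") / "fixtures" / name
    with importlib.resources.as_file(ref) as path:
        return PrevalenceSeries.from_csv(path)


def load_benchmark_series() -> PrevalenceSeries:
    """The pooled national ECC prevalence series 1988-2010 (23 annual values).

    This is the training window of the benchmark analysis: pooled prevalence of
    early childhood caries among Chinese 5-year-olds, in percent.
    """
    return _fixture("table1_series.csv")


def load_holdout_actuals() -> PrevalenceSeries:
    """Pooled prevalence actuals for the 2011-2013 validation window."""
    return _fixture("holdout_2011_2013.csv")
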