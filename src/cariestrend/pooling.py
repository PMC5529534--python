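"""Per-year meta-analytic pooling of study-level prevalence.

Each calendar year may be covered by several cross-sectional surveys; this
module pools them into a single annual estimate. Effects are pooled on the
logit scale by default (variances stabilise and back-transformed confidence
limits stay inside (0, 100)); a raw-proportion scale is available for
compatibility with older practice. Heterogeneity is quantified by Cochran's Q
and I², between-study variance by the DerSimonian–Laird moment estimator, and
a random-effects model is adopted whenever I² > 50% or the Q-test p-value is
below 0.1 — otherwise the fixed-effect (inverse-variance) model is used.
Publication bias is screened by Begg's rank-correlation test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

from .series import PrevalenceSeries

__all__ = [
    "StudyRecord",
    "YearPooledEstimate",
    "heterogeneity_stats",
    "pool_year",
    "beggs_test",
    "build_series",
    "load_study_csv",
]

Scale = Literal["logit", "proportion"]

#: random-effects trigger: I2 above this percent, or Q-test p below 0.1
I2_THRESHOLD = 50.0
Q_PVALUE_THRESHOLD = 0.1


@dataclass(frozen=True)
class StudyRecord:
    """One survey: year, children examined, children with >= 1 carious tooth."""

    year: int
    n_examined: int
    n_caries: int

    def __post_init__(self) -> None:
        if self.n_examined <= 0:
            raise ValueError("n_examined must be positive")
        if not 0 <= self.n_caries <= self.n_examined:
            raise ValueError("n_caries must lie in [0, n_examined]")

    @property
    def prevalence(self) -> float:
        """Observed prevalence in percent."""
        return 100.0 * self.n_caries / self.n_examined


@dataclass(frozen=True)
class YearPooledEstimate:
    year: int
    k_studies: int
    pooled_prevalence: float  # percent
    ci_low: float
    ci_high: float
    Q: float
    Q_pvalue: float
    I2: float
    tau2: float
    model_used: Literal["fixed", "random"]


class HeterogeneityUndefined(ValueError):
    """Raised when heterogeneity statistics are requested for < 2 studies."""


def _effects(studies: Sequence[StudyRecord], scale: Scale) -> tuple[np.ndarray, np.ndarray]:
    """Per-study effect and sampling variance on the pooling scale.

    On the logit scale a 0.5 continuity correction is applied to boundary
    counts (0 or n caries) so the effect and its variance stay finite.
    """
    x = np.array([s.n_caries for s in studies], dtype=float)
    n = np.array([s.n_examined for s in studies], dtype=float)
    if scale == "logit":
        boundary = (x == 0) | (x == n)
        xc = np.where(boundary, x + 0.5, x)
        nc = np.where(boundary, n + 1.0, n)
        y = np.log(xc / (nc - xc))
        v = 1.0 / xc + 1.0 / (nc - xc)
    elif scale == "proportion":
        p = x / n
        pc = np.clip(p, 0.5 / n, 1 - 0.5 / n)
        y = p
        v = pc * (1 - pc) / n
    else:
        raise ValueError(f"unknown pooling scale {scale!r}")
    return y, v


def _to_percent(value: float, scale: Scale) -> float:
    return 100.0 * float(expit(value)) if scale == "logit" else 100.0 * float(value)


def heterogeneity_stats(
    studies: Sequence[StudyRecord], scale: Scale = "logit"
) -> tuple[float, float, float, float]:
    """Cochran's Q (with its p-value), I² (percent) and DerSimonian–Laird tau².

    Q is the inverse-variance weighted sum of squared deviations from the
    fixed-effect mean; under homogeneity it is chi-square with k-1 df.
    I² = max(0, 100 * (Q - (k-1)) / Q). tau² = max(0, (Q - (k-1)) / (S1 -
    S2/S1)) with S1 = sum of weights, S2 = sum of squared weights.
    """
    k = len(studies)
    if k < 2:
        raise HeterogeneityUndefined("heterogeneity needs at least 2 studies")
    y, v = _effects(studies, scale)
    w = 1.0 / v
    ybar = np.sum(w * y) / np.sum(w)
    Q = float(np.sum(w * (y - ybar) ** 2))
    Q_pvalue = float(stats.chi2.sf(Q, k - 1))
    I2 = max(0.0, 100.0 * (Q - (k - 1)) / Q) if Q > 0 else 0.0
    denom = np.sum(w) - np.sum(w**2) / np.sum(w)
    tau2 = max(0.0, (Q - (k - 1)) / denom) if denom > 0 else 0.0
    return Q, Q_pvalue, I2, float(tau2)


def pool_year(
    studies: Sequence[StudyRecord], scale: Scale = "logit", alpha: float = 0.05
) -> YearPooledEstimate:
    """Pool one year's studies into a single prevalence estimate with 95% CI."""
    if len(studies) == 0:
        raise ValueError("cannot pool an empty list of studies")
    years = {s.year for s in studies}
    if len(years) != 1:
        raise ValueError("pool_year expects studies from a single year")
    year = studies[0].year
    zcrit = stats.norm.ppf(1 - alpha / 2)

    if len(studies) == 1:
        s = studies[0]
        lo, hi = _wilson_interval(s.n_caries, s.n_examined, zcrit)
        return YearPooledEstimate(
            year=year, k_studies=1, pooled_prevalence=s.prevalence,
            ci_low=100 * lo, ci_high=100 * hi,
            Q=0.0, Q_pvalue=1.0, I2=0.0, tau2=0.0, model_used="fixed",
        )

    y, v = _effects(studies, scale)
    Q, Q_p, I2, tau2 = heterogeneity_stats(studies, scale)
    random_effects = I2 > I2_THRESHOLD or Q_p < Q_PVALUE_THRESHOLD
    w = 1.0 / (v + tau2) if random_effects else 1.0 / v
    est = float(np.sum(w * y) / np.sum(w))
    se = float(np.sqrt(1.0 / np.sum(w)))
    return YearPooledEstimate(
        year=year,
        k_studies=len(studies),
        pooled_prevalence=_to_percent(est, scale),
        ci_low=_to_percent(est - zcrit * se, scale),
        ci_high=_to_percent(est + zcrit * se, scale),
        Q=Q, Q_pvalue=Q_p, I2=I2, tau2=tau2,
        model_used="random" if random_effects else "fixed",
    )


def _wilson_interval(x: int, n: int, z: float) -> tuple[float, float]:
    p = x / n
    denom = 1 + z**2 / n
    centre = (p + z**2 / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
    return centre - half, centre + half


def beggs_test(studies: Sequence[StudyRecord], scale: Scale = "logit") -> tuple[float, float]:
    """Begg's publication-bias test: Kendall correlation of deviates vs variances.

    Each study's effect is standardized against the fixed-effect pooled mean,
    using the variance of (y_i - pooled) = v_i - 1/sum(w); the test statistic
    is Kendall's tau between these deviates and the variances v_i. The p-value
    is exact (enumeration over rank orderings) for k <= 8 without ties, else
    the standard normal approximation.
    """
    k = len(studies)
    if k < 3:
        raise ValueError("Begg's test needs at least 3 studies")
    y, v = _effects(studies, scale)
    w = 1.0 / v
    pooled = np.sum(w * y) / np.sum(w)
    vstar = v - 1.0 / np.sum(w)
    t = (y - pooled) / np.sqrt(vstar)
    method = "exact" if k <= 8 else "asymptotic"
    res = stats.kendalltau(t, v, method=method)
    return float(res.statistic), float(res.pvalue)


def load_study_csv(path) -> list[StudyRecord]:
    """Read a study table CSV with columns year, n_examined, n_caries."""
    df = pd.read_csv(path)
    missing = {"year", "n_examined", "n_caries"} - set(df.columns)
    if missing:
        raise ValueError(f"study CSV missing columns: {sorted(missing)}")
    return [
        StudyRecord(int(r.year), int(r.n_examined), int(r.n_caries))
        for r in df.itertuples()
    ]


def build_series(
    table: pd.DataFrame | Iterable[StudyRecord], scale: Scale = "logit"
) -> tuple[PrevalenceSeries, pd.DataFrame]:
    """Pool a study table year by year into a contiguous prevalence series.

    Returns the series plus a per-year summary frame (k_studies, CI bounds,
    heterogeneity, model used). Every year in the span must have at least one
    study; a gap is an error naming the year — silent interpolation would feed
    fabricated values to the forecasting stage.
    """
    if isinstance(table, pd.DataFrame):
        studies = [
            StudyRecord(int(r.year), int(r.n_examined), int(r.n_caries))
            for r in table.itertuples()
        ]
    else:
        studies = list(table)
    if not studies:
        raise ValueError("no studies to pool")
    by_year: dict[int, list[StudyRecord]] = {}
    for s in studies:
        by_year.setdefault(s.year, []).append(s)
    y0, y1 = min(by_year), max(by_year)
    gaps = [y for y in range(y0, y1 + 1) if y not in by_year]
    if gaps:
        raise ValueError(f"no studies for year(s) {gaps}: series would not be contiguous")
    estimates = [pool_year(by_year[y], scale=scale) for y in range(y0, y1 + 1)]
    frame = pd.DataFrame(
        {
            "year": [e.year for e in estimates],
            "prevalence": [e.pooled_prevalence for e in estimates],
            "ci_low": [e.ci_low for e in estimates],
            "ci_high": [e.ci_high for e in estimates],
            "k_studies": [e.k_studies for e in estimates],
            "I2": [e.I2 for e in estimates],
            "model_used": [e.model_used for e in estimates],
        }
    )
    series = PrevalenceSeries(frame["year"].to_numpy(int), frame["prevalence"].to_numpy(float))
    return series, frame
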