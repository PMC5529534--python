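"""GM(1,1) grey prediction model.

The grey model treats the observed prevalence series x0 as the increments of a
smoother latent process: the accumulated generating operation (AGO) turns x0
into its running sum x1, which is assumed to follow the first-order whitening
equation

    dy/dt + a*y = b,

with development coefficient ``a`` and grey input ``b``. Discretising with the
trapezoid background value z[k] = (x1[k] + x1[k-1]) / 2 gives the linear system
x0[k] = -a*z[k] + b for k = 2..n, solved by ordinary least squares. The time
response

    y1(t) = (x0[1] - b/a) * exp(-a*(t-1)) + b/a        (t = 1, 2, ...)

is restored to the original scale by inverse accumulation (first differences),
so fitted and forecast values decay geometrically with ratio exp(-a) per year.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .series import PrevalenceSeries

__all__ = ["GreySequence", "GreyFit", "ago", "iago", "fit_gm11", "gm_restore", "gm_forecast"]

#: below this magnitude the development coefficient is treated as exactly zero
#: and the time response degenerates to the linear (constant-increment) limit
_A_ZERO_TOL = 1e-12


@dataclass(frozen=True)
class GreySequence:
    """An original positive series together with its accumulated (AGO) form."""

    years: np.ndarray
    original: np.ndarray     # x0, percent
    accumulated: np.ndarray  # x1, running cumulative sum (percent-years)

    def __len__(self) -> int:
        return len(self.original)


@dataclass(frozen=True)
class GreyFit:
    """Least-squares GM(1,1) parameters and their time-response form.

    ``amplitude`` is the coefficient of the exponential in the time response
    (first original value minus the asymptote b/a); ``b_over_a`` is the
    asymptote of the accumulated process.
    """

    a: float
    b: float
    b_over_a: float
    amplitude: float
    n_fit: int
    first_year: int
    first_value: float

    def time_response(self, k: np.ndarray) -> np.ndarray:
        """Accumulated-scale prediction y1 at steps k = 0, 1, 2, ... (k=0 is year 1)."""
        k = np.asarray(k, dtype=float)
        if abs(self.a) < _A_ZERO_TOL:
            # a -> 0 limit: dy/dt = b, linear accumulation
            return self.first_value + self.b * k
        return self.amplitude * np.exp(-self.a * k) + self.b_over_a

    def to_dict(self) -> dict:
        return {
            "a": self.a,
            "b": self.b,
            "b_over_a": self.b_over_a,
            "amplitude": self.amplitude,
            "n_fit": self.n_fit,
            "first_year": self.first_year,
        }


def ago(series: PrevalenceSeries) -> GreySequence:
    """Accumulated generating operation: running cumulative sum of the series.

    Requires at least 4 strictly positive values (fewer leave the two-parameter
    background regression without enough degrees of freedom to be meaningful).
    """
    x0 = np.asarray(series.values, dtype=float)
    if len(x0) < 4:
        raise ValueError("GM(1,1) needs at least 4 observations")
    if np.any(x0 <= 0):
        raise ValueError("grey model requires strictly positive data")
    return GreySequence(series.years.copy(), x0, np.cumsum(x0))


def iago(accumulated: np.ndarray) -> np.ndarray:
    """Inverse AGO: first differences with the first value kept, exact inverse of cumsum."""
    x1 = np.asarray(accumulated, dtype=float)
    return np.concatenate([x1[:1], np.diff(x1)])


def fit_gm11(seq: GreySequence) -> GreyFit:
    """Estimate (a, b) by least squares on x0[k] = -a*z[k] + b, k = 2..n."""
    x0, x1 = seq.original, seq.accumulated
    z = 0.5 * (x1[1:] + x1[:-1])
    if np.ptp(z) == 0:
        raise ValueError("degenerate background sequence: all z values equal")
    design = np.column_stack([-z, np.ones_like(z)])
    (a, b), *_ = np.linalg.lstsq(design, x0[1:], rcond=None)
    a, b = float(a), float(b)
    if abs(a) < _A_ZERO_TOL:
        a = 0.0
        b_over_a = np.inf
        amplitude = -np.inf
    else:
        b_over_a = b / a
        amplitude = float(x0[0]) - b_over_a
    return GreyFit(
        a=a,
        b=b,
        b_over_a=b_over_a,
        amplitude=amplitude,
        n_fit=len(x0),
        first_year=int(seq.years[0]),
        first_value=float(x0[0]),
    )


def gm_restore(fit: GreyFit, seq: GreySequence) -> np.ndarray:
    """In-sample fitted values on the original scale, NaN for the first year.

    fitted[k] = y1(k) - y1(k-1); the first observation anchors the time
    response and has no fitted counterpart.
    """
    if fit.n_fit != len(seq) or fit.first_year != int(seq.years[0]):
        raise ValueError("fit does not belong to this sequence")
    y1 = fit.time_response(np.arange(len(seq)))
    out = np.diff(y1)
    return np.concatenate([[np.nan], out])


def gm_forecast(fit: GreyFit, horizon: int) -> PrevalenceSeries:
    """Out-of-sample forecasts for the ``horizon`` years after the fit window.

    Extends the restored-increment recursion: each step decays by exp(-a).
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    k = np.arange(fit.n_fit - 1, fit.n_fit + horizon)
    y1 = fit.time_response(k)
    years = np.arange(fit.first_year + fit.n_fit, fit.first_year + fit.n_fit + horizon)
    return PrevalenceSeries(years, np.diff(y1))
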