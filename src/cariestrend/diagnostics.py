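"""Stationarity, correlogram, residual-whiteness and structural-break tests.

Everything here operates on plain numeric sequences (or a
:class:`~cariestrend.series.PrevalenceSeries` where years matter). The tests
are the standard pre- and post-estimation checks of the Box–Jenkins workflow:

* ADF — null of a unit root; regression with a constant (optionally a linear
  trend), lag order fixed or chosen by AIC, p-values from MacKinnon's (1994)
  response-surface polynomials.
* KPSS — null of level stationarity; Bartlett-kernel (Newey–West) long-run
  variance, p-value by interpolation of the standard critical-value table.
* Ljung–Box — portmanteau whiteness test of residuals, with a degrees-of-
  freedom correction for fitted ARMA coefficients.
* Chow — F-test for a structural break of a level-plus-linear-trend
  regression at a given year, used here to check that the train/holdout split
  does not straddle a regime change.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .series import PrevalenceSeries

__all__ = [
    "DiagnosticsResult",
    "Correlogram",
    "difference",
    "adf_test",
    "kpss_test",
    "acf",
    "pacf",
    "correlogram",
    "ljung_box",
    "chow_breakpoint_test",
]


@dataclass(frozen=True)
class DiagnosticsResult:
    test_name: str
    statistic: float
    pvalue: float
    lags_used: int
    reject: bool
    alpha: float
    null_hypothesis: str
    detail: dict = field(default_factory=dict)

    @property
    def decision(self) -> str:
        return "reject" if self.reject else "fail-to-reject"

    def to_dict(self) -> dict:
        return {
            "test": self.test_name,
            "statistic": self.statistic,
            "pvalue": self.pvalue,
            "lags_used": self.lags_used,
            "alpha": self.alpha,
            "decision": self.decision,
            "null_hypothesis": self.null_hypothesis,
            **self.detail,
        }


@dataclass(frozen=True)
class Correlogram:
    lags: np.ndarray
    acf_values: np.ndarray
    pacf_values: np.ndarray
    confidence_band: float  # +/- band half-width, 1.96/sqrt(n)
    n: int


def _values(series) -> np.ndarray:
    if isinstance(series, PrevalenceSeries):
        return np.asarray(series.values, dtype=float)
    return np.asarray(series, dtype=float)


def difference(series, d: int = 1) -> np.ndarray:
    """d-th order differencing; d=0 returns the values unchanged."""
    x = _values(series)
    if d not in (0, 1, 2):
        raise ValueError("differencing order must be 0, 1 or 2")
    if len(x) <= d:
        raise ValueError("series too short to difference")
    return np.diff(x, n=d) if d else x.copy()


# ---------------------------------------------------------------------------
# ADF unit-root test

# MacKinnon (1994) response-surface coefficients for the single-series tau
# distribution, and the validity bounds of the approximation.
_MACKINNON = {
    "c": dict(
        small=(2.1659, 1.4412, 0.038269),
        large=(1.7339, 0.93202, -0.12745, -0.010368),
        star=-1.61, lo=-18.83, hi=2.74,
    ),
    "ct": dict(
        small=(3.2512, 1.6047, 0.049588),
        large=(2.5261, 0.61654, -0.37956, -0.060285),
        star=-2.89, lo=-16.18, hi=0.7,
    ),
}


def _mackinnon_pvalue(tau: float, regression: str) -> float:
    t = _MACKINNON[regression]
    if tau > t["hi"]:
        return 1.0
    if tau < t["lo"]:
        return 0.0
    coef = t["small"] if tau <= t["star"] else t["large"]
    return float(stats.norm.cdf(np.polyval(coef[::-1], tau)))


def _ols(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, float, np.ndarray]:
    """Least squares returning (beta, SSR, se(beta))."""
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    ssr = float(resid @ resid)
    n, k = X.shape
    sigma2 = ssr / (n - k)
    cov = sigma2 * np.linalg.inv(X.T @ X)
    return beta, ssr, np.sqrt(np.diag(cov))


def _gaussian_aic(ssr: float, nobs: int, nparams: int) -> float:
    llf = -nobs / 2 * (np.log(2 * np.pi) + np.log(ssr / nobs) + 1)
    return -2 * llf + 2 * nparams


def _adf_regression(x: np.ndarray, k: int, regression: str, trim: int):
    """Design and response for the ADF test regression with k diff lags.

    ``trim`` observations are dropped at the start (used to put candidate lag
    orders on a common sample during AIC selection).
    """
    dx = np.diff(x)
    n = len(dx)
    rows = np.arange(trim, n)
    y = dx[rows]
    cols = [x[rows]]  # lagged level y_{t-1}
    for i in range(1, k + 1):
        cols.append(dx[rows - i])
    cols.append(np.ones(len(rows)))
    if regression == "ct":
        cols.append(rows.astype(float))
    return y, np.column_stack(cols)


def adf_test(
    series,
    max_lag: int | None = None,
    regression: str = "c",
    autolag: bool = True,
    alpha: float = 0.05,
) -> DiagnosticsResult:
    """Augmented Dickey–Fuller test; H0: the series has a unit root.

    With ``autolag`` the number of lagged differences is chosen by AIC over
    0..max_lag (Schwert's rule 12*(n/100)^(1/4) when max_lag is None), then
    the test regression is refit on the longest sample that lag allows.
    """
    x = _values(series)
    n = len(x)
    if n < 8:
        raise ValueError("ADF test needs at least 8 observations")
    if regression not in ("c", "ct"):
        raise ValueError("regression must be 'c' (constant) or 'ct' (constant+trend)")
    ntrend = 1 if regression == "c" else 2
    if max_lag is None:
        max_lag = min(int(np.ceil(12.0 * (n / 100.0) ** 0.25)), n // 2 - ntrend - 1)
        max_lag = max(max_lag, 0)
    if n - 1 - max_lag < max_lag + ntrend + 2:
        raise ValueError("series too short for the requested lag order")

    if autolag and max_lag > 0:
        best = None
        for k in range(max_lag + 1):
            y, X = _adf_regression(x, k, regression, trim=max_lag)
            _, ssr, _ = _ols(y, X)
            aic = _gaussian_aic(ssr, len(y), X.shape[1])
            if best is None or aic < best[0]:
                best = (aic, k)
        k = best[1]
    else:
        k = max_lag if not autolag else 0

    y, X = _adf_regression(x, k, regression, trim=k)
    beta, ssr, se = _ols(y, X)
    tau = float(beta[0] / se[0])
    pvalue = _mackinnon_pvalue(tau, regression)
    return DiagnosticsResult(
        test_name="adf",
        statistic=tau,
        pvalue=pvalue,
        lags_used=k,
        reject=pvalue < alpha,
        alpha=alpha,
        null_hypothesis="unit root (non-stationary)",
        detail={"regression": regression, "nobs": len(y)},
    )


# ---------------------------------------------------------------------------
# KPSS level-stationarity test

_KPSS_CRIT = np.array([0.347, 0.463, 0.574, 0.739])
_KPSS_PVALS = np.array([0.10, 0.05, 0.025, 0.01])


def kpss_test(series, nlags: int | None = None, alpha: float = 0.05) -> DiagnosticsResult:
    """KPSS test; H0: the series is level-stationary.

    The long-run variance uses a Bartlett kernel with ``nlags`` terms
    (default: the legacy 12*(n/100)^(1/4) bandwidth). The p-value is linear
    interpolation of the 10/5/2.5/1% critical-value table, clamped at the
    table ends.
    """
    x = _values(series)
    n = len(x)
    if n < 8:
        raise ValueError("KPSS test needs at least 8 observations")
    if nlags is None:
        nlags = int(np.ceil(12.0 * (n / 100.0) ** 0.25))
    if nlags >= n:
        raise ValueError("nlags must be smaller than the series length")
    e = x - x.mean()
    s = np.cumsum(e)
    eta = float(np.sum(s**2)) / n**2
    s2 = float(e @ e) / n
    for lag in range(1, nlags + 1):
        w = 1.0 - lag / (nlags + 1.0)
        s2 += 2.0 / n * w * float(e[lag:] @ e[:-lag])
    stat = eta / s2 if s2 > 0 else 0.0
    pvalue = float(np.interp(stat, _KPSS_CRIT, _KPSS_PVALS))
    return DiagnosticsResult(
        test_name="kpss",
        statistic=stat,
        pvalue=pvalue,
        lags_used=nlags,
        reject=pvalue < alpha,
        alpha=alpha,
        null_hypothesis="level stationarity",
        detail={"pvalue_interpolated": True},
    )


# ---------------------------------------------------------------------------
# Correlogram

def acf(series, max_lag: int) -> np.ndarray:
    """Sample autocorrelations at lags 1..max_lag with the biased 1/n denominator."""
    x = _values(series)
    n = len(x)
    if max_lag < 1 or max_lag >= n:
        raise ValueError("max_lag must be in [1, n-1]")
    e = x - x.mean()
    denom = float(e @ e)
    if denom == 0:
        raise ValueError("constant series has undefined autocorrelations")
    return np.array([float(e[k:] @ e[:-k]) / denom for k in range(1, max_lag + 1)])


def pacf(series, max_lag: int) -> np.ndarray:
    """Partial autocorrelations at lags 1..max_lag via Durbin–Levinson on the sample ACF."""
    rho = np.concatenate([[1.0], acf(series, max_lag)])
    phi = np.zeros((max_lag + 1, max_lag + 1))
    out = np.zeros(max_lag)
    phi[1, 1] = rho[1]
    out[0] = rho[1]
    for k in range(2, max_lag + 1):
        num = rho[k] - phi[k - 1, 1:k] @ rho[k - 1:0:-1]
        den = 1.0 - phi[k - 1, 1:k] @ rho[1:k]
        phi[k, k] = num / den
        phi[k, 1:k] = phi[k - 1, 1:k] - phi[k, k] * phi[k - 1, k - 1:0:-1]
        out[k - 1] = phi[k, k]
    return out


def correlogram(series, max_lag: int) -> Correlogram:
    x = _values(series)
    n = len(x)
    if max_lag >= n / 2:
        raise ValueError("max_lag must be below half the series length")
    return Correlogram(
        lags=np.arange(1, max_lag + 1),
        acf_values=acf(x, max_lag),
        pacf_values=pacf(x, max_lag),
        confidence_band=1.96 / np.sqrt(n),
        n=n,
    )


# ---------------------------------------------------------------------------
# Ljung-Box whiteness test

def ljung_box(residuals, h: int | None = None, fitted_params: int = 0,
              alpha: float = 0.05) -> DiagnosticsResult:
    """Ljung–Box portmanteau test; H0: residuals are white noise.

    Q = n(n+2) * sum_{k=1..h} rho_k^2 / (n-k), chi-square with h minus
    ``fitted_params`` degrees of freedom (the p+q correction when the
    residuals come from an ARMA fit). h defaults to min(10, n//4).
    """
    e = _values(residuals)
    n = len(e)
    if h is None:
        h = max(1, min(10, n // 4))
    if h >= n:
        raise ValueError("h must be smaller than the series length")
    if fitted_params >= h:
        raise ValueError("h must exceed the number of fitted ARMA parameters")
    rho = acf(e, h)
    q = float(n * (n + 2) * np.sum(rho**2 / (n - np.arange(1, h + 1))))
    df = h - fitted_params
    pvalue = float(stats.chi2.sf(q, df))
    return DiagnosticsResult(
        test_name="ljung_box",
        statistic=q,
        pvalue=pvalue,
        lags_used=h,
        reject=pvalue < alpha,
        alpha=alpha,
        null_hypothesis="residuals are white noise",
        detail={"df": df},
    )


# ---------------------------------------------------------------------------
# Chow structural-break test

def chow_breakpoint_test(series: PrevalenceSeries, break_year: int,
                         alpha: float = 0.05) -> DiagnosticsResult:
    """Chow F-test for a break after ``break_year`` in a linear-trend regression.

    Both segments and the pooled sample are fit with prevalence ~ 1 + year
    (k = 2 restrictions); segment 1 is years <= break_year. A perfectly
    collinear zero-noise input (all SSRs ~ 0) is reported as no break.
    """
    if not isinstance(series, PrevalenceSeries):
        raise TypeError("chow_breakpoint_test expects a PrevalenceSeries")
    t = series.years.astype(float)
    y = series.values
    mask = series.years <= break_year
    n1, n2 = int(mask.sum()), int((~mask).sum())
    if n1 < 3 or n2 < 3:
        raise ValueError("need at least 3 observations on each side of the break")
    k = 2

    def ssr(tt, yy):
        X = np.column_stack([np.ones_like(tt), tt])
        beta, _, _, _ = np.linalg.lstsq(X, yy, rcond=None)
        r = yy - X @ beta
        return float(r @ r)

    s_pooled = ssr(t, y)
    s_split = ssr(t[mask], y[mask]) + ssr(t[~mask], y[~mask])
    df2 = n1 + n2 - 2 * k
    if s_split <= 1e-12 * max(1.0, s_pooled):
        if s_pooled <= 1e-12:
            f, pvalue = 0.0, 1.0  # both regressions exact: no evidence of a break
        else:
            f, pvalue = np.inf, 0.0
    else:
        f = ((s_pooled - s_split) / k) / (s_split / df2)
        f = max(f, 0.0)
        pvalue = float(stats.f.sf(f, k, df2))
    return DiagnosticsResult(
        test_name="chow",
        statistic=float(f),
        pvalue=pvalue,
        lags_used=0,
        reject=pvalue < alpha,
        alpha=alpha,
        null_hypothesis=f"no structural change after {break_year}",
        detail={"break_year": break_year, "n_before": n1, "n_after": n2},
    )
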