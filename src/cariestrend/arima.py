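"""ARIMA(p, d, q) estimation by conditional least squares, order selection
and forecasting.

Estimation minimises the conditional sum of squares (CSS): residuals are
computed recursively on the d-times differenced series with presample shocks
set to zero and the first p observations used only as conditioning values.
The optimiser works in an unconstrained space that maps one-to-one onto
stationary AR and invertible MA coefficients (the partial-autocorrelation
transform), started from a Hannan–Rissanen regression, so fits are
deterministic and never leave the admissible region. Order selection follows
the classical Box–Jenkins loop: the differencing degree d comes from repeated
ADF tests (with a KPSS cross-check), then (p, q) is chosen by AIC over a grid,
admitting only fits whose residuals pass the Ljung–Box whiteness test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, signal, stats

from .diagnostics import adf_test, kpss_test, ljung_box
from .series import PrevalenceSeries

__all__ = ["ArimaSpec", "ArimaFit", "Forecast", "fit_arima", "select_order",
           "forecast", "fitted_values"]


@dataclass(frozen=True)
class ArimaSpec:
    p: int
    d: int
    q: int

    def __post_init__(self) -> None:
        if self.p < 0 or self.q < 0:
            raise ValueError("p and q must be non-negative")
        if self.d not in (0, 1, 2):
            raise ValueError("d must be 0, 1 or 2")

    @property
    def n_arma(self) -> int:
        return self.p + self.q


@dataclass(frozen=True)
class Forecast:
    origin_year: int
    years: np.ndarray
    point: np.ndarray       # percent
    interval_low: np.ndarray
    interval_high: np.ndarray

    @property
    def horizon(self) -> int:
        return len(self.point)


@dataclass(frozen=True)
class ArimaFit:
    spec: ArimaSpec
    intercept: float
    ar_coefficients: np.ndarray
    ma_coefficients: np.ndarray
    sigma2: float
    residuals: np.ndarray          # differenced scale, length m - p
    css: float
    aic: float                     # -2 loglik + 2k (total)
    aic_per_obs: float             # per-observation AIC, as econometric packages report it
    r_squared: float
    coefficient_t_stats: np.ndarray
    regression_F_pvalue: float
    converged: bool
    invertible: bool
    series: PrevalenceSeries = field(repr=False)
    differenced: np.ndarray = field(repr=False)
    non_white: bool = False

    def to_dict(self) -> dict:
        return {
            "order": [self.spec.p, self.spec.d, self.spec.q],
            "intercept": self.intercept,
            "ar": list(self.ar_coefficients),
            "ma": list(self.ma_coefficients),
            "sigma2": self.sigma2,
            "aic": self.aic,
            "aic_per_obs": self.aic_per_obs,
            "r_squared": self.r_squared,
            "t_stats": list(self.coefficient_t_stats),
            "regression_F_pvalue": self.regression_F_pvalue,
            "converged": self.converged,
            "invertible": self.invertible,
        }


class ArimaConvergenceError(RuntimeError):
    """Optimizer failed to converge; carries the scipy status message."""


# ---------------------------------------------------------------------------
# stationarity / invertibility parametrization

def _pacf_to_coef(pac: np.ndarray) -> np.ndarray:
    """Durbin–Levinson: partial autocorrelations -> AR coefficients."""
    phi = np.empty(0)
    for k, r in enumerate(pac, start=1):
        new = np.empty(k)
        new[k - 1] = r
        if k > 1:
            new[: k - 1] = phi - r * phi[::-1]
        phi = new
    return phi


def _coef_to_pacf(phi: np.ndarray) -> np.ndarray:
    """Inverse Durbin–Levinson; clips partials into (-1, 1) if needed."""
    phi = np.array(phi, dtype=float)
    pac = np.empty(len(phi))
    for k in range(len(phi), 0, -1):
        r = np.clip(phi[k - 1], -0.999, 0.999)
        pac[k - 1] = r
        if k > 1:
            phi = (phi[: k - 1] + r * phi[k - 2 :: -1]) / (1 - r**2)
            phi = np.clip(phi, -1e6, 1e6)
    return pac


def _unconstrained_to_coef(x: np.ndarray) -> np.ndarray:
    return _pacf_to_coef(x / np.sqrt(1.0 + x**2))


def _coef_to_unconstrained(phi: np.ndarray) -> np.ndarray:
    pac = np.clip(_coef_to_pacf(phi), -0.999, 0.999)
    return pac / np.sqrt(1.0 - pac**2)


def _max_inverse_root(coefs: np.ndarray, sign: float) -> float:
    """Largest modulus of the inverse roots of 1 - sign*c1 L - ... (0 if empty)."""
    if len(coefs) == 0:
        return 0.0
    return float(np.max(np.abs(np.roots(np.concatenate([[1.0], -sign * coefs])))))


# ---------------------------------------------------------------------------
# CSS recursion

def _css_residuals(z: np.ndarray, c: float, phi: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Conditional residuals e[p..m-1]; presample shocks zero.

    e_t = u_t - theta_1 e_{t-1} - ... with u_t = z_t - c - sum phi_i z_{t-i},
    i.e. an all-pole recursive filter applied to u — evaluated by lfilter.
    """
    p, q = len(phi), len(theta)
    m = len(z)
    u = z[p:] - c
    for i in range(1, p + 1):
        u = u - phi[i - 1] * z[p - i : m - i]
    if q == 0:
        return u
    return signal.lfilter([1.0], np.concatenate([[1.0], theta]), u)


def _unpack(params: np.ndarray, p: int, q: int, with_intercept: bool):
    i = 1 if with_intercept else 0
    c = params[0] if with_intercept else 0.0
    phi = _unconstrained_to_coef(params[i : i + p])
    theta = -_unconstrained_to_coef(params[i + p : i + p + q])
    return c, phi, theta


def _hannan_rissanen_init(z: np.ndarray, p: int, q: int, with_intercept: bool) -> np.ndarray:
    """Two-stage long-AR regression giving deterministic starting coefficients."""
    m = len(z)
    phi0 = np.zeros(p)
    theta0 = np.zeros(q)
    c0 = float(np.mean(z)) if with_intercept else 0.0
    long_p = min(max(p + q, int(round(np.log(m) ** 2)) if m > 4 else 1), m // 2)
    if q == 0 and p > 0 and m > 2 * p + 2:
        X = np.column_stack([np.ones(m - p)] + [z[p - i - 1 : m - i - 1] for i in range(p)])
        beta, *_ = np.linalg.lstsq(X, z[p:], rcond=None)
        c0 = float(beta[0]) if with_intercept else 0.0
        phi0 = beta[1:]
    elif q > 0 and m > long_p + p + q + 2:
        Xl = np.column_stack(
            [np.ones(m - long_p)] + [z[long_p - i - 1 : m - i - 1] for i in range(long_p)]
        )
        beta, *_ = np.linalg.lstsq(Xl, z[long_p:], rcond=None)
        ehat = np.zeros(m)
        ehat[long_p:] = z[long_p:] - Xl @ beta
        k0 = max(p, q)
        rows = np.arange(long_p + k0, m)
        cols = [np.ones(len(rows))]
        cols += [z[rows - i - 1] for i in range(p)]
        cols += [ehat[rows - j - 1] for j in range(q)]
        beta2, *_ = np.linalg.lstsq(np.column_stack(cols), z[rows], rcond=None)
        c0 = float(beta2[0]) if with_intercept else 0.0
        phi0 = beta2[1 : 1 + p]
        theta0 = beta2[1 + p :]
    # pull the init strictly inside the admissible region
    if _max_inverse_root(phi0, 1.0) >= 0.98:
        phi0 = phi0 * 0.95 / _max_inverse_root(phi0, 1.0)
    if _max_inverse_root(theta0, -1.0) >= 0.98:
        theta0 = theta0 * 0.95 / _max_inverse_root(theta0, -1.0)
    parts = []
    if with_intercept:
        parts.append([c0])
    parts.append(_coef_to_unconstrained(phi0))
    parts.append(_coef_to_unconstrained(-theta0))
    return np.concatenate([np.atleast_1d(np.asarray(x, dtype=float)) for x in parts])


def fit_arima(
    series: PrevalenceSeries,
    spec: ArimaSpec,
    include_intercept: bool = True,
    n_restarts: int = 6,
) -> ArimaFit:
    """Fit an ARIMA model by conditional least squares.

    ``n_restarts`` additional deterministic starts (a fixed-seed Latin grid in
    the unconstrained space) guard against local minima of the CSS surface;
    the best optimum wins.
    """
    z = np.diff(series.values, n=spec.d) if spec.d else np.asarray(series.values, float)
    p, q = spec.p, spec.q
    m = len(z)
    if m <= p + q + 1:
        raise ValueError("series too short after differencing for this order")
    n_mean = (1 if include_intercept else 0) + p + q

    def objective(params):
        c, phi, theta = _unpack(params, p, q, include_intercept)
        e = _css_residuals(z, c, phi, theta)
        return float(e @ e)

    if n_mean == 0:
        best_x = np.empty(0)
        converged = True
    else:
        starts = [_hannan_rissanen_init(z, p, q, include_intercept)]
        rng = np.random.default_rng(12345)  # fixed: restarts are part of the algorithm
        for _ in range(n_restarts):
            starts.append(rng.uniform(-1.0, 1.0, n_mean) * np.array(
                [np.std(z) if include_intercept and i == 0 else 1.0 for i in range(n_mean)]
            ))
        best = None
        for x0 in starts:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = optimize.minimize(objective, x0, method="Nelder-Mead",
                                        options={"maxiter": 600 * n_mean,
                                                 "xatol": 1e-8, "fatol": 1e-10})
                res = optimize.minimize(objective, res.x, method="BFGS",
                                        options={"gtol": 1e-10})
            if best is None or res.fun < best.fun:
                best = res
        if best is None or not np.isfinite(best.fun):
            raise ArimaConvergenceError("CSS optimization failed")
        best_x = best.x
        converged = True  # Nelder-Mead + BFGS polish; flag retained for API stability

    c, phi, theta = _unpack(best_x, p, q, include_intercept)
    e = _css_residuals(z, c, phi, theta)
    n_eff = len(e)
    css = float(e @ e)
    sigma2 = css / n_eff
    if sigma2 <= 0:
        sigma2 = np.finfo(float).tiny
    invertible = _max_inverse_root(theta, -1.0) < 1.0

    llf = -n_eff / 2 * (np.log(2 * np.pi) + np.log(sigma2) + 1)
    k_params = n_mean + 1  # + sigma2
    aic = -2 * llf + 2 * k_params
    zz = z[p:]
    sst = float(np.sum((zz - zz.mean()) ** 2))
    r_squared = 1.0 - css / sst if sst > 0 else (1.0 if css == 0 else -np.inf)

    t_stats, f_pvalue = _inference(z, best_x, p, q, include_intercept, sigma2, css, sst, n_eff)

    return ArimaFit(
        spec=spec, intercept=float(c), ar_coefficients=phi, ma_coefficients=theta,
        sigma2=sigma2, residuals=e, css=css, aic=float(aic),
        aic_per_obs=float(aic / n_eff), r_squared=float(r_squared),
        coefficient_t_stats=t_stats, regression_F_pvalue=f_pvalue,
        converged=converged, invertible=invertible,
        series=series, differenced=z,
    )


def _inference(z, x_opt, p, q, with_intercept, sigma2, css, sst, n_eff):
    """t statistics from the numerical Hessian of the CSS surface in
    coefficient space, and the overall-regression F p-value."""
    n_mean = (1 if with_intercept else 0) + p + q
    if n_mean == 0:
        return np.empty(0), 1.0
    c, phi, theta = _unpack(x_opt, p, q, with_intercept)
    beta = np.concatenate([[c] if with_intercept else [], phi, theta])

    def ssr_of(b):
        i = 1 if with_intercept else 0
        cc = b[0] if with_intercept else 0.0
        e = _css_residuals(z, cc, b[i : i + p], b[i + p :])
        return float(e @ e)

    h = 1e-5 * np.maximum(np.abs(beta), 1.0)
    H = np.empty((n_mean, n_mean))
    f0 = ssr_of(beta)
    for i in range(n_mean):
        for j in range(i, n_mean):
            bi = beta.copy(); bi[i] += h[i]; bi[j] += h[j]; fpp = ssr_of(bi)
            bi = beta.copy(); bi[i] += h[i]; bi[j] -= h[j]; fpm = ssr_of(bi)
            bi = beta.copy(); bi[i] -= h[i]; bi[j] += h[j]; fmp = ssr_of(bi)
            bi = beta.copy(); bi[i] -= h[i]; bi[j] -= h[j]; fmm = ssr_of(bi)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    try:
        cov = 2.0 * sigma2 * np.linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
        with np.errstate(divide="ignore", invalid="ignore"):
            t_stats = np.where(se > 0, beta / se, np.nan)
    except np.linalg.LinAlgError:
        t_stats = np.full(n_mean, np.nan)

    k_reg = n_mean
    if sst > css and k_reg > 1 and n_eff > k_reg:
        f = ((sst - css) / (k_reg - 1)) / (css / (n_eff - k_reg))
        f_pvalue = float(stats.f.sf(f, k_reg - 1, n_eff - k_reg))
    else:
        f_pvalue = 1.0
    return t_stats, f_pvalue


# ---------------------------------------------------------------------------
# order selection

def select_order(
    series: PrevalenceSeries,
    max_p: int = 3,
    max_q: int = 3,
    alpha: float = 0.05,
    lb_level: float = 0.05,
    include_intercept: bool = True,
) -> tuple[ArimaSpec, dict]:
    """Choose (p, d, q) by the Box–Jenkins loop.

    d: difference until the ADF test rejects a unit root (KPSS recorded as a
    cross-check), capped at 2. (p, q): minimum AIC over the grid among fits
    whose residuals pass Ljung–Box at ``lb_level``; ties go to fewer
    parameters, then lower q. If nothing passes, the best-AIC spec is
    returned flagged ``non_white`` in the report.
    """
    if max_p > 5 or max_q > 5:
        raise ValueError("max_p and max_q are capped at 5")
    x = series.values
    d = 0
    report: dict = {"adf": [], "kpss": []}
    while d < 2:
        adf = adf_test(np.diff(x, n=d) if d else x, alpha=alpha)
        report["adf"].append(adf.to_dict())
        try:
            report["kpss"].append(kpss_test(np.diff(x, n=d) if d else x, alpha=alpha).to_dict())
        except ValueError:
            pass
        if adf.reject:
            break
        d += 1

    # Candidates are ranked by an AIC evaluated on a COMMON sample: CSS
    # conditioning drops the first p differenced observations, so each fit's
    # own AIC is computed on a different number of residuals and totals are
    # not comparable across p (larger p would be favoured whenever sigma2 > 1).
    # Dropping the first max_p observations for every candidate removes that
    # bias.
    candidates = []
    for p in range(max_p + 1):
        for q in range(max_q + 1):
            try:
                fit = fit_arima(series, ArimaSpec(p, d, q), include_intercept=include_intercept)
            except (ValueError, ArimaConvergenceError):
                continue
            h = min(max(p + q + 2, 8), len(fit.residuals) - 1)
            if h <= p + q:
                continue
            lb = ljung_box(fit.residuals, h=h, fitted_params=p + q, alpha=lb_level)
            e_common = fit.residuals[max_p - p:] if max_p > p else fit.residuals
            n_common = len(e_common)
            sigma2_c = max(float(e_common @ e_common) / n_common, np.finfo(float).tiny)
            k = (1 if include_intercept else 0) + p + q + 1
            aic_c = n_common * (np.log(2 * np.pi) + np.log(sigma2_c) + 1) + 2 * k
            candidates.append((fit, lb, float(aic_c)))
    if not candidates:
        raise ArimaConvergenceError("no ARMA candidate could be fitted")
    white = [t for t in candidates if not t[1].reject]
    pool = white if white else candidates
    pool.sort(key=lambda t: (t[2], t[0].spec.n_arma, t[0].spec.q))
    chosen = pool[0][0]
    report["grid"] = [
        {"order": [f.spec.p, d, f.spec.q], "aic": f.aic,
         "aic_common_sample": aic_c, "ljung_box_pvalue": lb.pvalue}
        for f, lb, aic_c in candidates
    ]
    report["non_white"] = not white
    report["chosen"] = [chosen.spec.p, d, chosen.spec.q]
    return chosen.spec, report


# ---------------------------------------------------------------------------
# fitted values and forecasting

def fitted_values(fit: ArimaFit) -> np.ndarray:
    """One-step-ahead in-sample predictions on the original level scale.

    The first d + p years have no one-step prediction and are NaN.
    """
    spec = fit.spec
    x = fit.series.values
    z = fit.differenced
    warmup = spec.d + spec.p
    fitted_diff = z[spec.p :] - fit.residuals
    out = np.full(len(x), np.nan)
    for i, fd in enumerate(fitted_diff):
        t = warmup + i  # index into the level series
        if spec.d == 0:
            out[t] = fd
        elif spec.d == 1:
            out[t] = x[t - 1] + fd
        else:
            out[t] = fd + 2 * x[t - 1] - x[t - 2]
    return out


def _psi_weights(phi: np.ndarray, theta: np.ndarray, h: int) -> np.ndarray:
    """MA(inf) weights psi_0..psi_{h-1}: psi_j = theta_j + sum_i phi_i psi_{j-i}."""
    psi = np.zeros(h)
    psi[0] = 1.0
    for j in range(1, h):
        val = theta[j - 1] if j - 1 < len(theta) else 0.0
        for i in range(1, min(j, len(phi)) + 1):
            val += phi[i - 1] * psi[j - i]
        psi[j] = val
    return psi


def forecast(fit: ArimaFit, horizon: int, alpha: float = 0.05) -> Forecast:
    """h-step forecasts with (1 - alpha) prediction intervals.

    Future shocks are zero in the ARMA recursion on the differenced scale;
    point forecasts are integrated back through the last d observed levels.
    Interval widths accumulate the psi-weights of the integrated process.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    spec = fit.spec
    phi, theta = fit.ar_coefficients, fit.ma_coefficients
    z = fit.differenced
    p, q = spec.p, spec.q
    m = len(z)
    e_full = np.zeros(m)
    e_full[p:] = fit.residuals
    zext = np.concatenate([z, np.zeros(horizon)])
    eext = np.concatenate([e_full, np.zeros(horizon)])
    for hstep in range(horizon):
        t = m + hstep
        pred = fit.intercept
        if p:
            pred += phi @ zext[t - p : t][::-1]
        if q:
            pred += theta @ eext[t - q : t][::-1]
        zext[t] = pred
    zf = zext[m:]

    x = fit.series.values
    if spec.d == 0:
        levels = zf
    elif spec.d == 1:
        levels = x[-1] + np.cumsum(zf)
    else:
        first_diff = x[-1] - x[-2] + np.cumsum(zf)
        levels = x[-1] + np.cumsum(first_diff)

    psi = _psi_weights(phi, theta, horizon)
    for _ in range(spec.d):
        psi = np.cumsum(psi)
    var = fit.sigma2 * np.cumsum(psi**2)
    zcrit = stats.norm.ppf(1 - alpha / 2)
    half = zcrit * np.sqrt(var)

    years = np.arange(fit.series.end_year + 1, fit.series.end_year + 1 + horizon)
    return Forecast(
        origin_year=fit.series.end_year,
        years=years,
        point=levels,
        interval_low=levels - half,
        interval_high=levels + half,
    )
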