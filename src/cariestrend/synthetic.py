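"""Synthetic study-level prevalence tables and ARMA benchmark series.

The pooled national series underlying the analysis is built from dozens of
regional cross-sectional caries surveys; those study-level tables are rarely
redistributable, so this module generates tables with the same statistical
structure: per-year clusters of binomial surveys whose true prevalences
scatter, on the log-odds scale, around a slowly declining secular trend.

Generative model for one study in calendar year t:

    logit(pi) = intercept + slope * (t - year_start) + u,   u ~ N(0, tau^2)
    n_caries ~ Binomial(n_examined, pi)

with ``tau`` the between-study standard deviation on the logit scale — the
random-effects heterogeneity the pooling stage is meant to recover.

All randomness flows through ``numpy.random.default_rng`` (PCG64), so a seed
pins every table and series bit-for-bit across runs and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from scipy.special import expit

__all__ = ["StudyGenConfig", "generate_study_table", "generate_arma_series"]


@dataclass(frozen=True)
class StudyGenConfig:
    """Parameters of the study-table generator.

    ``logit_intercept`` is the log-odds of prevalence at ``year_start``;
    ``logit_slope`` the per-year change (negative for a declining trend);
    ``tau`` the between-study SD on the logit scale; ``n_range`` the inclusive
    range of per-study sample sizes, drawn uniformly.
    """

    year_start: int = 1988
    year_end: int = 2013
    studies_per_year: int = 3
    n_range: tuple[int, int] = (200, 1000)
    logit_intercept: float = 1.4
    logit_slope: float = -0.05
    tau: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.year_end < self.year_start:
            raise ValueError("year_end must be >= year_start")
        if self.studies_per_year < 1:
            raise ValueError("studies_per_year must be positive")
        lo, hi = self.n_range
        if lo < 1 or hi < lo:
            raise ValueError("n_range must satisfy 1 <= lo <= hi")
        if self.tau < 0:
            raise ValueError("tau must be non-negative")


def generate_study_table(config: StudyGenConfig) -> pd.DataFrame:
    """Draw a study table: columns year, n_examined, n_caries, true_prevalence.

    ``true_prevalence`` (percent) is the study's latent prevalence before
    binomial sampling; downstream pooling only sees the counts.
    """
    rng = np.random.default_rng(config.seed)
    years = np.arange(config.year_start, config.year_end + 1)
    rows = []
    lo, hi = config.n_range
    for year in years:
        mu = config.logit_intercept + config.logit_slope * (year - config.year_start)
        u = rng.normal(0.0, config.tau, size=config.studies_per_year) if config.tau > 0 else np.zeros(config.studies_per_year)
        pi = expit(mu + u)
        n = rng.integers(lo, hi + 1, size=config.studies_per_year)
        x = rng.binomial(n, pi)
        for ni, xi, pi_i in zip(n, x, pi):
            rows.append((int(year), int(ni), int(xi), 100.0 * pi_i))
    return pd.DataFrame(rows, columns=["year", "n_examined", "n_caries", "true_prevalence"])


def generate_arma_series(
    phi=(), theta=(), sigma: float = 1.0, n: int = 100, seed: int = 0, mean: float = 0.0
) -> np.ndarray:
    """Simulate a zero-mean (plus ``mean``) ARMA(p, q) realization of length ``n``.

    The AR polynomial must be stationary (all roots of 1 - phi_1 z - ... -
    phi_p z^p outside the unit circle). A burn-in of ``10 * max(p, q) + 50``
    steps is discarded so the returned stretch is free of initialization
    transients.
    """
    phi = np.asarray(phi, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if n < 1:
        raise ValueError("n must be >= 1")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    p, q = len(phi), len(theta)
    if p and np.max(np.abs(np.roots(np.concatenate([[1.0], -phi])))) >= 1.0:
        raise ValueError("AR coefficients are non-stationary")
    burn = 10 * max(p, q, 0) + 50
    total = n + burn
    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, sigma, size=total) if sigma > 0 else np.zeros(total)
    x = np.zeros(total)
    for t in range(total):
        ar = x[t - p:t][::-1] @ phi if p and t >= p else (x[:t][::-1] @ phi[:t] if p else 0.0)
        ma = eps[t - q:t][::-1] @ theta if q and t >= q else (eps[:t][::-1] @ theta[:t] if q else 0.0)
        x[t] = ar + ma + eps[t]
    return mean + x[burn:]
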