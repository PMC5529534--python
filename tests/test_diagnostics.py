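import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cariestrend import (
    PrevalenceSeries,
    acf,
    adf_test,
    chow_breakpoint_test,
    correlogram,
    difference,
    generate_arma_series,
    kpss_test,
    ljung_box,
    pacf,
)


def test_first_difference_of_series_head(benchmark):
    np.testing.assert_allclose(difference(benchmark.values[:3], 1), [-7.0, -0.8])


def test_difference_orders_and_errors():
    x = np.arange(10, dtype=float)
    assert np.all(difference(x, 1) == 1.0)
    assert np.all(difference(x, 2) == 0.0)
    np.testing.assert_array_equal(difference(x, 0), x)
    with pytest.raises(ValueError):
        difference(x, 3)


@settings(deadline=None, max_examples=25)
@given(st.lists(st.floats(min_value=-100, max_value=100, allow_nan=False), min_size=2, max_size=40))
def test_difference_then_integrate_is_identity(values):
    x = np.asarray(values)
    d1 = difference(x, 1)
    np.testing.assert_allclose(np.concatenate([[x[0]], x[0] + np.cumsum(d1)]), x, atol=1e-9)


def test_acf_lag1_by_direct_formula():
    # sum (x_t - xbar)(x_{t+1} - xbar) / sum (x_t - xbar)^2 = 1.25 / 5
    assert acf([1, 2, 3, 4], 1)[0] == pytest.approx(0.25)


def test_pacf_lag1_equals_acf_lag1():
    x = generate_arma_series(phi=[0.5], n=200, seed=8)
    assert pacf(x, 3)[0] == pytest.approx(acf(x, 1)[0], abs=1e-12)


def test_ar1_pacf_truncates_after_lag1():
    x = generate_arma_series(phi=[0.7], n=2000, seed=14)
    assert abs(pacf(x, 3)[1]) < 0.05


def test_acf_invariant_to_time_reversal():
    x = generate_arma_series(phi=[0.4], theta=[0.2], n=300, seed=4)
    np.testing.assert_allclose(acf(x, 10), acf(x[::-1], 10), atol=1e-10)


def test_correlogram_bounds_and_band():
    x = generate_arma_series(phi=[0.6], n=400, seed=9)
    cg = correlogram(x, 20)
    assert np.all(np.abs(cg.acf_values) <= 1) and np.all(np.abs(cg.pacf_values) <= 1)
    assert cg.confidence_band == pytest.approx(1.96 / np.sqrt(400))
    with pytest.raises(ValueError):
        correlogram(x, 200)


def test_ljung_box_matches_hand_formula():
    x = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 6.0])
    n = 6
    e = x - x.mean()
    rho = [float(e[k:] @ e[:-k]) / float(e @ e) for k in (1, 2)]
    q_oracle = n * (n + 2) * sum(r**2 / (n - k) for k, r in zip((1, 2), rho))
    res = ljung_box(x, h=2)
    assert res.statistic == pytest.approx(q_oracle, abs=1e-6)


def test_ljung_box_rejects_unmodelled_ar1():
    hits = 0
    for seed in range(60):
        x = generate_arma_series(phi=[0.8], n=300, seed=seed)
        hits += ljung_box(x, h=10).reject
    assert hits >= 57  # >= 95% power


def test_ljung_box_input_validation():
    with pytest.raises(ValueError):
        ljung_box(np.arange(5.0), h=10)
    with pytest.raises(ValueError):
        ljung_box(np.arange(20.0), h=2, fitted_params=3)


# --- ADF / KPSS qualitative behaviour --------------------------------------

def test_adf_level_vs_differenced_benchmark(benchmark):
    level = adf_test(benchmark)
    assert not level.reject and level.pvalue > 0.05
    diff = adf_test(np.diff(benchmark.values))
    assert diff.reject and diff.pvalue < 0.05


def test_adf_size_under_random_walk_null():
    """AIC lag selection inflates the finite-sample size slightly above the
    nominal 5% (the oracle implementation behaves identically), so the band
    allows that distortion plus binomial noise (SE about 1.1% at 400 reps)."""
    rng = np.random.default_rng(3)
    hits = 0
    n_rep = 400
    for _ in range(n_rep):
        x = np.cumsum(rng.normal(size=250))
        hits += adf_test(x, max_lag=4).reject
    assert 0.02 <= hits / n_rep <= 0.09


def test_kpss_size_and_power():
    rng = np.random.default_rng(17)
    size_hits = sum(kpss_test(rng.normal(size=500)).reject for _ in range(200))
    assert abs(size_hits / 200 - 0.05) < 0.04
    # KPSS power against a pure random walk at n=500 is high but not 1
    # (the Newey-West bandwidth grows with n and damps the statistic)
    power_hits = sum(kpss_test(np.cumsum(rng.normal(size=500))).reject for _ in range(100))
    assert power_hits >= 80


def test_kpss_constant_series_statistic_zero():
    res = kpss_test(np.full(50, 3.0))
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert not res.reject


def test_short_series_rejected():
    with pytest.raises(ValueError):
        adf_test(np.arange(5.0))
    with pytest.raises(ValueError):
        kpss_test(np.arange(5.0))


# --- Chow breakpoint test ---------------------------------------------------

def _mk_series(start_year, values):
    return PrevalenceSeries(np.arange(start_year, start_year + len(values)), np.asarray(values))


def test_chow_on_identical_noise_free_line_is_no_break():
    y = 80 - 0.5 * np.arange(12)
    res = chow_breakpoint_test(_mk_series(2000, y), 2005)
    assert res.statistic == 0.0 and not res.reject


def test_chow_detects_intercept_jump_and_matches_ols_oracle():
    rng = np.random.default_rng(5)
    t = np.arange(2000, 2012, dtype=float)
    y = 60 - 0.3 * (t - 2000) + rng.normal(0, 0.1, 12)
    y[6:] += 10.0
    series = _mk_series(2000, y)
    res = chow_breakpoint_test(series, 2005)

    def ssr(tt, yy):
        b = np.polyfit(tt, yy, 1)
        r = yy - np.polyval(b, tt)
        return r @ r

    sp, s1, s2 = ssr(t, y), ssr(t[:6], y[:6]), ssr(t[6:], y[6:])
    f_oracle = ((sp - s1 - s2) / 2) / ((s1 + s2) / (12 - 4))
    assert res.statistic == pytest.approx(f_oracle, rel=1e-9)
    assert res.pvalue < 0.001


def test_chow_finds_no_break_at_benchmark_split(full_series):
    res = chow_breakpoint_test(full_series, 2010)
    assert res.pvalue > 0.05 and not res.reject


def test_chow_needs_three_points_per_segment(full_series):
    with pytest.raises(ValueError):
        chow_breakpoint_test(full_series, 2012)


# --- oracle equivalence against statsmodels ---------------------------------

def _random_series(seed, n=120):
    rng = np.random.default_rng(seed)
    kind = seed % 3
    if kind == 0:
        return generate_arma_series(phi=[0.5], n=n, seed=seed)
    if kind == 1:
        return np.cumsum(rng.normal(size=n))
    return generate_arma_series(phi=[0.3], theta=[0.4], n=n, seed=seed)


@pytest.mark.parametrize("seed", range(20))
def test_adf_matches_reference_implementation(seed):
    from statsmodels.tsa.stattools import adfuller
    x = _random_series(seed)
    stat, pval, usedlag, *_ = adfuller(x, maxlag=6, regression="c", autolag="AIC")
    mine = adf_test(x, max_lag=6)
    assert mine.statistic == pytest.approx(stat, abs=1e-4)
    assert mine.pvalue == pytest.approx(pval, abs=1e-4)
    assert mine.lags_used == usedlag


@pytest.mark.parametrize("seed", range(20))
def test_kpss_and_ljung_box_match_reference_implementation(seed):
    import warnings
    from statsmodels.stats.diagnostic import acorr_ljungbox
    from statsmodels.tsa.stattools import kpss as sm_kpss
    x = _random_series(seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stat, pval, *_ = sm_kpss(x, regression="c", nlags=8)
    mine = kpss_test(x, nlags=8)
    assert mine.statistic == pytest.approx(stat, abs=1e-4)

    lb = acorr_ljungbox(x, lags=[10])
    mine_lb = ljung_box(x, h=10)
    assert mine_lb.statistic == pytest.approx(float(lb["lb_stat"].iloc[0]), abs=1e-4)
    assert mine_lb.pvalue == pytest.approx(float(lb["lb_pvalue"].iloc[0]), abs=1e-4)
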