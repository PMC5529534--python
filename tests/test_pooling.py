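from itertools import permutations

import numpy as np
import pytest
from scipy import stats
from scipy.special import expit

from cariestrend import (
    StudyGenConfig,
    StudyRecord,
    beggs_test,
    build_series,
    generate_study_table,
    heterogeneity_stats,
    pool_year,
)
from cariestrend.pooling import HeterogeneityUndefined


def _logit_effects(records):
    """Independent closed-form oracle: logit effects and variances."""
    x = np.array([r.n_caries for r in records], float)
    n = np.array([r.n_examined for r in records], float)
    return np.log(x / (n - x)), 1 / x + 1 / (n - x)


THREE_STUDIES = [StudyRecord(2000, 100, 40), StudyRecord(2000, 100, 50), StudyRecord(2000, 100, 60)]


def test_identical_studies_have_zero_heterogeneity():
    recs = [StudyRecord(2000, 200, 80), StudyRecord(2000, 200, 80)]
    Q, p, I2, tau2 = heterogeneity_stats(recs)
    assert Q == pytest.approx(0.0, abs=1e-12)
    assert I2 == 0.0 and tau2 == 0.0


def test_heterogeneity_matches_hand_computed_dersimonian_laird():
    """Q, I2 and tau2 must equal the closed-form inverse-variance arithmetic."""
    y, v = _logit_effects(THREE_STUDIES)
    w = 1 / v
    ybar = (w * y).sum() / w.sum()
    Q_o = float((w * (y - ybar) ** 2).sum())
    I2_o = max(0, 100 * (Q_o - 2) / Q_o)
    tau2_o = max(0, (Q_o - 2) / (w.sum() - (w**2).sum() / w.sum()))
    Q, p, I2, tau2 = heterogeneity_stats(THREE_STUDIES)
    assert Q == pytest.approx(Q_o, abs=1e-6)
    assert p == pytest.approx(stats.chi2.sf(Q_o, 2), abs=1e-6)
    assert I2 == pytest.approx(I2_o, abs=1e-6)
    assert tau2 == pytest.approx(tau2_o, abs=1e-6)


def test_heterogeneity_needs_two_studies():
    with pytest.raises(HeterogeneityUndefined):
        heterogeneity_stats([StudyRecord(2000, 100, 50)])


def test_qtest_type_one_error_under_homogeneity():
    """With tau=0 the Q-test should flag heterogeneity at the 0.1 level in
    about 10% of replicates."""
    rng = np.random.default_rng(123)
    n_rep, hits = 1000, 0
    for _ in range(n_rep):
        n = rng.integers(100, 500, size=5)
        x = rng.binomial(n, 0.6)
        x = np.clip(x, 1, n - 1)
        recs = [StudyRecord(2000, int(ni), int(xi)) for ni, xi in zip(n, x)]
        _, p, _, _ = heterogeneity_stats(recs)
        hits += p < 0.1
    assert abs(hits / n_rep - 0.10) < 0.02


def test_single_study_pools_to_itself():
    est = pool_year([StudyRecord(1999, 100, 50)])
    assert est.pooled_prevalence == 50.0
    assert est.model_used == "fixed"
    assert est.ci_low < 50 < est.ci_high


def test_homogeneous_pair_pools_to_common_value_with_narrower_ci():
    single = pool_year([StudyRecord(2000, 200, 120)])
    pair = pool_year([StudyRecord(2000, 200, 120), StudyRecord(2000, 200, 120)])
    assert pair.pooled_prevalence == pytest.approx(60.0, abs=1e-9)
    assert (pair.ci_high - pair.ci_low) < (single.ci_high - single.ci_low)


def test_pooled_value_matches_hand_computed_weighted_mean():
    y, v = _logit_effects(THREE_STUDIES)
    _, _, _, tau2 = heterogeneity_stats(THREE_STUDIES)
    w = 1 / (v + tau2)  # heterogeneous toy triggers the random-effects model
    oracle = 100 * expit((w * y).sum() / w.sum())
    est = pool_year(THREE_STUDIES)
    assert est.model_used == "random"
    assert est.pooled_prevalence == pytest.approx(oracle, abs=1e-6)


def test_pooled_estimate_within_study_range():
    rng = np.random.default_rng(99)
    for _ in range(50):
        n = rng.integers(50, 400, size=4)
        x = np.clip(rng.binomial(n, rng.uniform(0.3, 0.8)), 1, n - 1)
        recs = [StudyRecord(2001, int(ni), int(xi)) for ni, xi in zip(n, x)]
        est = pool_year(recs)
        prevs = [r.prevalence for r in recs]
        assert min(prevs) - 1e-9 <= est.pooled_prevalence <= max(prevs) + 1e-9


def test_fixed_and_random_pooling_coincide_when_tau2_zero():
    recs = [StudyRecord(2000, 300, 150), StudyRecord(2000, 300, 151)]
    _, _, _, tau2 = heterogeneity_stats(recs)
    assert tau2 == 0.0
    y, v = _logit_effects(recs)
    fixed = 100 * expit((y / v).sum() / (1 / v).sum())
    assert pool_year(recs).pooled_prevalence == pytest.approx(fixed, abs=1e-9)


def test_dl_tau2_has_median_zero_under_homogeneity():
    rng = np.random.default_rng(7)
    tau2s = []
    for _ in range(200):
        n = rng.integers(100, 400, size=5)
        x = np.clip(rng.binomial(n, 0.5), 1, n - 1)
        recs = [StudyRecord(2000, int(ni), int(xi)) for ni, xi in zip(n, x)]
        tau2s.append(heterogeneity_stats(recs)[3])
    assert np.median(tau2s) == 0.0


# --- Begg's test -----------------------------------------------------------

def test_begg_perfect_concordance():
    recs = [StudyRecord(2000, n, x) for n, x in [(400, 200), (200, 110), (100, 60), (50, 35)]]
    y, v = _logit_effects(recs)
    order = np.argsort(v)
    assert np.all(np.diff(np.array(y)[order]) > 0)  # deviates increase with variance
    tau, _ = beggs_test(recs)
    assert tau == pytest.approx(1.0)


def test_begg_exact_pvalue_matches_enumeration():
    recs = [StudyRecord(2000, 200, 30), StudyRecord(2000, 150, 45),
            StudyRecord(2000, 100, 50), StudyRecord(2000, 80, 70)]
    y, v = _logit_effects(recs)
    w = 1 / v
    pooled = (w * y).sum() / w.sum()
    t = (y - pooled) / np.sqrt(v - 1 / w.sum())

    def ktau(a, b):
        s = sum(np.sign((a[i] - a[j]) * (b[i] - b[j]))
                for i in range(len(a)) for j in range(i + 1, len(a)))
        return s / (len(a) * (len(a) - 1) / 2)

    obs = ktau(t, v)
    more_extreme = sum(abs(ktau(t[list(p)], v)) >= abs(obs) - 1e-12
                       for p in permutations(range(4)))
    tau, p = beggs_test(recs)
    assert tau == pytest.approx(obs, abs=1e-12)
    assert p == pytest.approx(more_extreme / 24, abs=1e-12)


def test_begg_needs_three_studies():
    with pytest.raises(ValueError):
        beggs_test([StudyRecord(2000, 100, 50), StudyRecord(2000, 100, 60)])


# --- build_series ----------------------------------------------------------

def test_single_study_per_year_passes_through():
    recs = [StudyRecord(2000, 100, 50), StudyRecord(2001, 100, 60), StudyRecord(2002, 100, 55)]
    series, frame = build_series(recs)
    np.testing.assert_allclose(series.values, [50.0, 60.0, 55.0])
    assert list(frame["k_studies"]) == [1, 1, 1]


def test_gap_year_is_an_error_naming_the_year():
    recs = [StudyRecord(2000, 100, 50), StudyRecord(2002, 100, 55)]
    with pytest.raises(ValueError, match="2001"):
        build_series(recs)


def test_series_tracks_true_trend_within_ci():
    cfg = StudyGenConfig(year_start=1990, year_end=2009, studies_per_year=5,
                         n_range=(300, 800), tau=0.15, seed=21)
    table = generate_study_table(cfg)
    _, frame = build_series(table)
    truth = 100 * expit(cfg.logit_intercept + cfg.logit_slope * np.arange(20))
    covered = ((frame["ci_low"] <= truth) & (truth <= frame["ci_high"])).mean()
    assert covered >= 0.9


def test_slope_recovery_from_pooled_logits():
    """Weighted regression of pooled logits on year recovers the generating
    slope within 2 SE in >= 90% of replicates."""
    from scipy.special import logit as logit_fn
    slope = -0.05
    ok = 0
    n_rep = 200
    for rep in range(n_rep):
        cfg = StudyGenConfig(year_start=1995, year_end=2009, studies_per_year=3,
                             n_range=(200, 600), logit_slope=slope, tau=0.1,
                             seed=10_000 + rep)
        _, frame = build_series(generate_study_table(cfg))
        t = frame["year"].to_numpy(float) - 1995
        yl = logit_fn(frame["prevalence"].to_numpy() / 100)
        X = np.column_stack([np.ones_like(t), t])
        beta, _, _, _ = np.linalg.lstsq(X, yl, rcond=None)
        resid = yl - X @ beta
        s2 = resid @ resid / (len(t) - 2)
        se = np.sqrt(s2 * np.linalg.inv(X.T @ X)[1, 1])
        ok += abs(beta[1] - slope) < 2 * se
    assert ok / n_rep >= 0.9
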