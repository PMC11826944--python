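"""Rubin pooling, pooled correlations and stepwise model selection."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from phenoframe.inference import (
    fit_standardized_model,
    pooled_correlation,
    rubin_pool,
    run_model_suite,
    screen_candidates,
    stepwise_backward,
)


def _brute_rubin(q, u, nu_com):
    """Independent textbook implementation used as oracle."""
    q, u = np.asarray(q, float), np.asarray(u, float)
    m = len(q)
    qbar, w = q.mean(), u.mean()
    b = q.var(ddof=1) if m > 1 else 0.0
    t = w + (1 + 1 / m) * b
    if t <= 0 or b <= 0:
        df = (nu_com + 1) / (nu_com + 3) * nu_com
    else:
        lam = (1 + 1 / m) * b / t
        nu_old = (m - 1) / lam**2
        nu_obs = (nu_com + 1) / (nu_com + 3) * nu_com * (1 - lam)
        df = nu_old * nu_obs / (nu_old + nu_obs)
    return qbar, t, df


def test_rubin_pool_no_between_variance():
    est = rubin_pool([0.3, 0.3, 0.3], [0.04, 0.04, 0.04], nu_com=50)
    assert est.estimate == pytest.approx(0.3)
    assert est.between == 0.0
    assert est.total == pytest.approx(0.04)
    assert est.df == pytest.approx(50 * 51 / 53)


def test_rubin_pool_hand_example():
    est = rubin_pool([0.0, 1.0], [1.0, 1.0], nu_com=30)
    assert est.estimate == pytest.approx(0.5)
    assert est.between == pytest.approx(0.5)
    assert est.total == pytest.approx(1.0 + 1.5 * 0.5)


def test_rubin_pool_matches_brute_force_on_random_inputs():
    rng = np.random.default_rng(6)
    for _ in range(100):
        m = int(rng.integers(2, 12))
        q = rng.normal(0, 1, m)
        u = rng.uniform(0.01, 2.0, m)
        nu = float(rng.integers(5, 200))
        est = rubin_pool(q, u, nu)
        qbar, t, df = _brute_rubin(q, u, nu)
        assert est.estimate == pytest.approx(qbar)
        assert est.total == pytest.approx(t)
        assert est.df == pytest.approx(df)
        assert est.total >= est.within - 1e-12  # T >= W always
        half = stats.t.ppf(0.975, df) * np.sqrt(t)
        assert est.ci == pytest.approx((qbar - half, qbar + half))


def test_rubin_pool_rejects_negative_variance_and_passes_through_m1():
    with pytest.raises(ValueError):
        rubin_pool([0.1, 0.2], [0.5, -0.1], nu_com=10)
    est = rubin_pool([0.4], [0.09], nu_com=20)
    assert est.estimate == 0.4 and est.df == 20


def _tables(points, m=3):
    df = pd.DataFrame(points, columns=["screen_duration_mean_mean", "phq8_sum"])
    return [df.copy() for _ in range(m)]


def test_pooled_correlation_identical_tables_hand_value():
    tabs = _tables([(0, 0), (1, 1), (2, 0), (3, 1)])
    est = pooled_correlation(tabs, "screen_duration_mean_mean", "phq8_sum")
    assert est.estimate == pytest.approx(1 / np.sqrt(5))  # hand Pearson, n=4
    assert est.between == 0.0
    z = np.arctanh(1 / np.sqrt(5))
    half = stats.t.ppf(0.975, est.df) * 1.0  # var(z) = 1/(n-3) = 1
    assert est.ci == pytest.approx((np.tanh(z - half), np.tanh(z + half)))


def test_pooled_correlation_symmetry_and_self():
    tabs = _tables([(0.1, 3), (1.3, 5), (2.2, 4), (3.1, 9), (1.7, 2)])
    a = pooled_correlation(tabs, "screen_duration_mean_mean", "phq8_sum")
    b = pooled_correlation(tabs, "phq8_sum", "screen_duration_mean_mean")
    assert a.estimate == pytest.approx(b.estimate)
    self_r = pooled_correlation(tabs, "phq8_sum", "phq8_sum")
    assert self_r.estimate == pytest.approx(1.0)
    assert self_r.degenerate


def test_pooled_correlation_zero_variance_error():
    tabs = _tables([(1.0, 3), (1.0, 5), (1.0, 4), (1.0, 9)])
    with pytest.raises(ValueError):
        pooled_correlation(tabs, "screen_duration_mean_mean", "phq8_sum")


def test_candidate_screening_uses_full_precision_bounds():
    from phenoframe.inference import PooledEstimate

    def pe(lo, hi):
        est = (lo + hi) / 2
        return PooledEstimate(est, 0.01, 0.0, 0.01, 100.0, (lo, hi))

    cands = screen_candidates(
        {
            "ema_valence_mean": pe(-0.67, -0.41),
            "app_freq_entropy_sd": pe(-0.37, -1e-9),  # prints as -0.00 but excludes zero
            "screen_duration_mean_mean": pe(-0.10, 0.20),
        }
    )
    assert cands["ema"] == ["ema_valence_mean"]
    assert cands["app"] == ["app_freq_entropy_sd"]
    assert cands["screen"] == []


def _synthetic_episode_table(rng, n, betas, label_cols, noise=1.0):
    x = rng.normal(size=(n, len(label_cols)))
    y = x @ betas + rng.normal(0, noise, n)
    df = pd.DataFrame(x, columns=label_cols)
    df["phq8_sum"] = y
    df["participant_id"] = [f"p{i}" for i in range(n)]
    return df


def test_single_predictor_beta_equals_correlation():
    rng = np.random.default_rng(7)
    t = _synthetic_episode_table(rng, 80, np.array([0.5]), ["ema_valence_mean"])
    rep = fit_standardized_model([t], "phq8_sum", ["ema_valence_mean"])
    r = np.corrcoef(t["ema_valence_mean"], t["phq8_sum"])[0, 1]
    assert rep.predictors["ema_valence_mean"].estimate == pytest.approx(r)


def test_adjusted_r2_matches_statsmodels():
    rng = np.random.default_rng(8)
    cols = ["ema_valence_mean", "ema_stress_mean"]
    t = _synthetic_episode_table(rng, 40, np.array([0.6, -0.3]), cols)
    rep = fit_standardized_model([t], "phq8_sum", cols)
    y = (t["phq8_sum"] - t["phq8_sum"].mean()) / t["phq8_sum"].std(ddof=1)
    x = sm.add_constant(np.column_stack([(t[c] - t[c].mean()) / t[c].std(ddof=1) for c in cols]))
    oracle = sm.OLS(y, x).fit().rsquared_adj * 100
    assert rep.adj_r2.estimate == pytest.approx(oracle, abs=1e-9)
    assert rep.adj_r2.ci[0] <= rep.adj_r2.estimate <= rep.adj_r2.ci[1]


def test_collinear_predictors_rejected():
    rng = np.random.default_rng(9)
    t = _synthetic_episode_table(rng, 50, np.array([0.5]), ["ema_valence_mean"])
    t["ema_arousal_mean"] = t["ema_valence_mean"] * 2.0
    with pytest.raises(ValueError, match="collinear"):
        fit_standardized_model([t], "phq8_sum", ["ema_valence_mean", "ema_arousal_mean"])


def test_stepwise_keeps_strong_orthogonal_predictors():
    rng = np.random.default_rng(10)
    cols = ["ema_valence_mean", "ema_stress_mean"]
    t = _synthetic_episode_table(rng, 150, np.array([0.7, -0.6]), cols, noise=0.8)
    rep = stepwise_backward([t], "phq8_sum", cols)
    assert set(rep.predictors) == set(cols)
    assert rep.trace == []


def test_stepwise_mostly_empty_on_pure_noise():
    cols = ["ema_valence_mean", "ema_stress_mean", "ema_sleep_mean", "ema_arousal_mean"]
    empties = 0
    for seed in range(11):
        rng = np.random.default_rng(100 + seed)
        t = _synthetic_episode_table(rng, 150, np.zeros(4), cols)
        rep = stepwise_backward([t], "phq8_sum", cols)
        empties += rep.empty
        # trace is strictly shrinking and final model satisfies the CI invariant
        assert len(rep.trace) == 4 - len(rep.predictors)
        assert all(est.excludes_zero() for est in rep.predictors.values())
    assert empties >= 6  # majority of replicates


def test_model_suite_nesting_and_sensitivity(medium_cohort, episode_tables):
    suite = run_model_suite(
        episode_tables, demographics=medium_cohort.participants, sensing_pool="survivors"
    )
    models = suite["models"]
    assert set(models) == {"ema", "app", "call", "location", "screen", "sensing", "combined"}
    if not models["combined"].empty:
        floor = max(models["ema"].adj_r2.estimate, models["sensing"].adj_r2.estimate)
        assert models["combined"].adj_r2.estimate >= floor - 1e-6
    for rep in suite["sensitivity"].values():
        assert set(rep.covariates) == {"age", "gender"}
    for rep in models.values():
        assert rep.adj_r2.estimate < 100.0
        assert -100.0 <= rep.adj_r2.ci[0] <= rep.adj_r2.ci[1] <= 100.0
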