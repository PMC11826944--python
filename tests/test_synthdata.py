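"""Generator contracts: determinism, range invariants, effect injection."""

import numpy as np
import pandas as pd
import pytest

from phenoframe.episodes import build_analysis_set
from phenoframe.features import extract_day_features
from phenoframe.impute import aggregate_to_episode
from phenoframe.synth import CohortConfig, generate_cohort, generate_phq8_items


def test_same_seed_byte_identical():
    cfg = CohortConfig(n_participants=4, seed=123, sensors=("screen", "calls", "ema"))
    a, b = generate_cohort(cfg), generate_cohort(cfg)
    for stream in ("screen", "app", "calls", "gps", "ema", "phq8", "participants"):
        assert getattr(a, stream).to_csv(index=False) == getattr(b, stream).to_csv(index=False)
    assert a.truth == b.truth


def test_different_seeds_differ():
    a = generate_cohort(CohortConfig(n_participants=4, seed=1, sensors=("ema",)))
    b = generate_cohort(CohortConfig(n_participants=4, seed=2, sensors=("ema",)))
    assert not a.ema.equals(b.ema)


def test_range_invariants(small_cohort):
    c = small_cohort
    assert c.ema["value"].between(0, 100).all()
    assert c.phq8[[f"item_{k}" for k in range(1, 9)]].isin([0, 1, 2, 3]).all().all()
    assert (c.calls["duration_s"] >= 0).all()
    assert c.gps["lat"].abs().le(90).all() and c.gps["lon"].abs().le(180).all()
    assert (c.app["end"] >= c.app["start"]).all()


def test_complete_cohort_has_no_missing_cells(small_day_table):
    values = small_day_table.drop(columns=["participant_id", "date"])
    assert int(values.isna().sum().sum()) == 0


def test_missingness_produces_missing_cells_and_unanswered_prompts():
    cfg = CohortConfig(
        n_participants=8, seed=5, sensors=("screen", "ema"), missing_rate_day=0.3, missing_rate_ema=0.3
    )
    c = generate_cohort(cfg)
    day = extract_day_features(c.to_bundle())
    assert day["screen_duration_mean"].isna().any()
    assert day["ema_valence"].isna().any()
    # fewer prompts than the complete 3/day schedule
    assert len(c.ema) < 8 * 14 * (4 + 3 + 7)


def test_unknown_and_unsupported_effect_features_rejected():
    with pytest.raises(ValueError):
        CohortConfig(n_participants=5, effect_map={"no_such_feature": 0.3})
    with pytest.raises(ValueError):
        CohortConfig(n_participants=5, effect_map={"location_entropy": 0.3})  # recognized, not injectable


def test_infeasible_targets_rejected():
    with pytest.raises(ValueError):
        CohortConfig(n_participants=5, effect_map={"ema_valence": 0.97})  # |r| cap
    with pytest.raises(ValueError):
        CohortConfig(n_participants=5, effect_map={"call_incoming_count": 0.9})  # day noise too large


def test_phq8_items_zero_noise_limits():
    rng = np.random.default_rng(0)
    assert generate_phq8_items(0.0, rng, noise_sd=1e-12).sum() == 0
    assert generate_phq8_items(24.0, rng, noise_sd=1e-12).sum() == 24
    with pytest.raises(ValueError):
        generate_phq8_items(25.0, rng)


def test_phq8_sum_unbiased_at_midscale():
    rng = np.random.default_rng(1)
    sums = [generate_phq8_items(12.0, rng).sum() for _ in range(2000)]
    assert 11.0 <= np.mean(sums) <= 13.0


def test_null_effect_map_gives_null_correlations():
    cfg = CohortConfig(n_participants=200, seed=9, effect_map={}, sensors=("screen", "ema"))
    c = generate_cohort(cfg)
    day = extract_day_features(c.to_bundle())
    table, _ = build_analysis_set(c.phq8, day)
    ep = aggregate_to_episode(table)
    for col in ("screen_duration_mean_mean", "ema_valence_mean", "screen_episode_count_mean"):
        r = np.corrcoef(ep[col], ep["phq8_sum"])[0, 1]
        assert abs(r) < 3.0 / np.sqrt(len(ep))  # within Monte-Carlo error of zero


def test_injected_correlation_recovered():
    cfg = CohortConfig(
        n_participants=300,
        seed=17,
        effect_map={"ema_valence": -0.5, "screen_duration_mean": 0.4},
        sensors=("screen", "ema"),
    )
    c = generate_cohort(cfg)
    day = extract_day_features(c.to_bundle())
    table, _ = build_analysis_set(c.phq8, day)
    ep = aggregate_to_episode(table)
    n = len(ep)
    for col, target in (("ema_valence_mean", -0.5), ("screen_duration_mean_mean", 0.4)):
        r = np.corrcoef(ep[col], ep["phq8_sum"])[0, 1]
        assert abs(r - target) <= 2.0 * (1 - target**2) / np.sqrt(n)


def test_writers_round_trip(tmp_path, small_cohort):
    from phenoframe.synth import read_events_dir

    small_cohort.write(tmp_path)
    expected = {
        "screen_events.csv",
        "app_events.csv",
        "calls.csv",
        "gps.csv",
        "ema.csv",
        "phq8.csv",
        "participants.csv",
        "truth.json",
    }
    assert expected <= {p.name for p in tmp_path.iterdir()}
    bundle, phq8, participants = read_events_dir(tmp_path)
    assert len(bundle.screen) == len(small_cohort.screen)
    assert len(phq8) == len(small_cohort.phq8)
    pd.testing.assert_series_equal(
        bundle.gps["lat"].round(9), small_cohort.gps["lat"].round(9), check_names=False
    )
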