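"""Episode construction, missingness accounting and eligibility filters."""

import numpy as np
import pandas as pd
import pytest

from phenoframe.episodes import (
    apply_exclusion,
    build_analysis_set,
    build_episodes,
    episode_missingness,
    select_best_episode,
)

T = pd.Timestamp


def _phq8(rows):
    """rows: (pid, date, total) with the total spread over items 3,3,3,..."""
    recs = []
    for pid, date, total in rows:
        items = [min(3, max(0, total - 3 * k)) for k in range(8)]
        recs.append({"participant_id": pid, "date": T(date), **{f"item_{k+1}": items[k] for k in range(8)}})
    return pd.DataFrame(recs)


def _day_table(pid, dates, values):
    return pd.DataFrame(
        {
            "participant_id": pid,
            "date": [T(d) for d in dates],
            "f1": values,
            "f2": values,
            "f3": values,
        }
    )


def test_one_episode_per_response_and_missing_days_count():
    dates = pd.date_range("2024-01-01", periods=28)
    day = _day_table("a", dates, np.ones(28))
    phq = _phq8([("a", "2024-01-14", 6), ("a", "2024-01-28", 6)])
    eps = build_episodes(phq, day)
    assert len(eps) == 2
    assert all(len(e.day_block) == 14 for e in eps)
    assert eps[0].missingness == 0.0
    assert eps[0].phq8_sum == 6


def test_participant_without_day_rows_is_fully_missing():
    day = _day_table("a", pd.date_range("2024-01-01", periods=14), np.ones(14))
    phq = _phq8([("b", "2024-01-14", 3)])
    (ep,) = build_episodes(phq, day)
    assert ep.missingness == 1.0


def test_missingness_arithmetic():
    dates = pd.date_range("2024-01-01", periods=14)
    vals = np.ones(14)
    day = _day_table("a", dates, vals)
    # 7 of 14 days fully absent -> 0.5
    half = day.iloc[:7]
    phq = _phq8([("a", "2024-01-14", 2)])
    (ep,) = build_episodes(phq, half)
    assert ep.missingness == pytest.approx(0.5)
    # 3 features x 14 days with 21 missing cells -> 0.5
    block = build_episodes(phq, day)[0].day_block.copy()
    flat = block.to_numpy().ravel()
    flat[:21] = np.nan
    block.loc[:, :] = flat.reshape(block.shape)
    assert episode_missingness(block, ["f1", "f2", "f3"]) == pytest.approx(0.5)
    with pytest.raises(ValueError):
        episode_missingness(block, [])


def test_phq8_item_validation():
    phq = _phq8([("a", "2024-01-14", 3)])
    phq.loc[0, "item_1"] = 4
    with pytest.raises(ValueError):
        build_episodes(phq, _day_table("a", pd.date_range("2024-01-01", periods=14), np.ones(14)))


def test_select_best_episode_and_tie_break():
    dates = pd.date_range("2024-01-01", periods=56)
    day = _day_table("a", dates, np.ones(56))
    phq = _phq8([("a", "2024-01-14", 2), ("a", "2024-01-28", 2), ("a", "2024-02-11", 2)])
    eps = build_episodes(phq, day)
    eps[0].missingness, eps[1].missingness, eps[2].missingness = 0.4, 0.1, 0.3
    assert select_best_episode(eps) is eps[1]
    eps[0].missingness, eps[1].missingness, eps[2].missingness = 0.2, 0.2, 0.5
    assert select_best_episode(eps) is eps[0]  # tie -> earliest date
    assert select_best_episode([eps[2]]) is eps[2]


def test_exclusion_boundary_is_strict():
    dates = pd.date_range("2024-01-01", periods=14)
    day = _day_table("a", dates, np.ones(14))
    phq = _phq8([("a", "2024-01-14", 2)])
    (ep,) = build_episodes(phq, day)
    ep.missingness = 0.50
    kept, report = apply_exclusion([ep])
    assert len(kept) == 1 and report["n_excluded"] == 0
    ep.missingness = 0.51
    kept, report = apply_exclusion([ep])
    assert len(kept) == 0 and report["n_excluded"] == 1


def test_structural_exclusion_on_lossy_cohort():
    from phenoframe.features import extract_day_features
    from phenoframe.synth import CohortConfig, generate_cohort

    cfg = CohortConfig(
        n_participants=30, seed=21, sensors=("screen", "ema"), missing_rate_day=0.5, missing_rate_ema=0.5
    )
    c = generate_cohort(cfg)
    day = extract_day_features(c.to_bundle())
    table, report = build_analysis_set(c.phq8, day)
    assert report["n_before"] == 30
    assert 0 < report["n_excluded"] < 30
    assert report["n_after"] == report["n_before"] - report["n_excluded"]
    # exactly one 14-day block per retained participant
    counts = table.groupby("participant_id").size()
    assert (counts == 14).all()
    assert len(counts) == report["n_after"]


def test_exclusion_monotone_in_day_missingness():
    from phenoframe.features import extract_day_features
    from phenoframe.synth import CohortConfig, generate_cohort

    excluded = []
    for rate in (0.35, 0.65):
        cfg = CohortConfig(
            n_participants=25, seed=33, sensors=("screen", "ema"), missing_rate_day=rate, missing_rate_ema=rate
        )
        c = generate_cohort(cfg)
        day = extract_day_features(c.to_bundle())
        _, report = build_analysis_set(c.phq8, day)
        excluded.append(report["n_excluded"])
    assert excluded[1] >= excluded[0]
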