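"""Motion classification, place clustering and the rhythm/routine features."""

import math

import numpy as np
import pandas as pd
import pytest

from phenoframe.features import (
    circadian_movement,
    classify_motion,
    cluster_places,
    location_routine_index,
    location_variance,
)
from phenoframe.synth import generate_day_fixes, make_anchors

T = pd.Timestamp
KM_PER_DEG_LAT = 110.54


def _fixes(rows):
    df = pd.DataFrame(rows, columns=["timestamp", "lat", "lon"])
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    df.insert(0, "participant_id", "p")
    return df


def test_stationary_trace_all_static():
    f = classify_motion(_fixes([(f"2024-01-01 10:{m:02d}", 48.4, 9.9) for m in range(0, 60, 5)]))
    assert (f["state"] == "static").all()


def test_speed_threshold_and_tie_break():
    # 1 km in 30 min = 2 km/h -> moving
    f = _fixes([("2024-01-01 10:00", 0.0, 0.0), ("2024-01-01 10:30", 1.0 / KM_PER_DEG_LAT, 0.0)])
    assert classify_motion(f)["state"].iloc[1] == "moving"
    # exactly 1 km/h -> static (tie goes to static)
    f = _fixes([("2024-01-01 10:00", 0.0, 0.0), ("2024-01-01 11:00", 1.0 / (6371.0 * math.pi / 180.0), 0.0)])
    assert classify_motion(f)["state"].iloc[1] == "static"


def test_duplicate_timestamps_deduplicated():
    f = _fixes(
        [
            ("2024-01-01 10:00", 0.0, 0.0),
            ("2024-01-01 10:00", 5.0, 5.0),
            ("2024-01-01 10:05", 0.0, 0.0),
        ]
    )
    out = classify_motion(f)
    assert len(out) == 2
    assert out["lat"].iloc[0] == 0.0  # first kept


def test_moving_static_ratio_alternating_speeds():
    # 20 segments alternating 2 km/h and 0.5 km/h, 10 each -> ratio 1.0
    from phenoframe.features import location_day_features

    rows, t, lat = [], T("2024-01-01 08:00"), 0.0
    for i in range(21):
        rows.append((t, lat, 0.0))
        step_kmh = 2.0 if i % 2 == 0 else 0.5
        lat += (step_kmh * 0.5) / KM_PER_DEG_LAT
        t += pd.Timedelta(30, "min")
    day = location_day_features(_fixes(rows)).iloc[0]
    assert day["moving_static_ratio"] == pytest.approx(1.0)


def test_location_variance_hand_value():
    f = _fixes([("2024-01-01 10:00", 0.0, 0.0), ("2024-01-01 10:05", 0.01, 0.0)])
    assert location_variance(f) == pytest.approx(math.log(2.5e-5))
    same = _fixes([("2024-01-01 10:00", 1.0, 1.0), ("2024-01-01 10:05", 1.0, 1.0)])
    assert math.isnan(location_variance(same))


def _day_at_anchors(anchors_km, dwell_h, start="2024-01-01 08:00", step_min=5):
    """Static dwell at each anchor in sequence with a fast hop between them."""
    rows, t = [], T(start)
    for (lat_km, lon_km), dwell in zip(anchors_km, dwell_h):
        lat, lon = lat_km / KM_PER_DEG_LAT, lon_km / KM_PER_DEG_LAT
        n = max(2, int(dwell * 60 / step_min))
        for _ in range(n):
            rows.append((t, lat, lon))
            t += pd.Timedelta(step_min, "min")
        t += pd.Timedelta(2, "min")  # quick hop -> high speed -> moving
    return classify_motion(_fixes(rows))


def test_single_tight_cluster():
    f = _day_at_anchors([(0.0, 0.0)], [6.0])
    clusters, feats = cluster_places(f)
    assert feats["n_significant_clusters"] == 1
    assert feats["location_entropy"] == pytest.approx(0.0)
    assert feats["outlier_time_ratio"] == pytest.approx(0.0)


def test_two_anchors_one_km_apart():
    f = _day_at_anchors([(0.0, 0.0), (1.0, 0.0)], [6.0, 6.0])
    clusters, feats = cluster_places(f)
    assert feats["n_significant_clusters"] == 2
    assert feats["location_entropy"] == pytest.approx(math.log(2), abs=1e-3)
    assert feats["location_norm_entropy"] == pytest.approx(1.0, abs=1e-3)
    assert feats["n_transitions"] >= 1
    assert feats["time_top3"] == 0.0  # only two significant places exist


def test_five_minute_visit_not_significant():
    f = _day_at_anchors([(0.0, 0.0), (1.0, 0.0)], [6.0, 5.0 / 60.0])
    _, feats = cluster_places(f)
    assert feats["n_significant_clusters"] == 1


def test_cluster_recovery_on_generated_trace():
    rng = np.random.default_rng(5)
    anchors = make_anchors(rng)
    fixes, truth = generate_day_fixes(rng, anchors, T("2024-01-01"), visit_other=True)
    fixes.insert(0, "participant_id", "p")
    _, feats = cluster_places(classify_motion(fixes))
    assert feats["n_significant_clusters"] == truth


def _commute_week(seed=0, shuffle=False, n_days=7):
    rng = np.random.default_rng(seed)
    anchors = make_anchors(rng)
    frames = []
    for d in range(n_days):
        rng_day = np.random.default_rng(100)  # identical schedule each day
        fixes, _ = generate_day_fixes(rng_day, anchors, T("2024-01-01") + pd.Timedelta(d, "D"), visit_other=False)
        frames.append(fixes)
    if shuffle:
        # destroy the 24 h alignment by rolling each day's coordinates
        rng_s = np.random.default_rng(seed + 1)
        for i, f in enumerate(frames):
            k = int(rng_s.integers(40, 248))
            frames[i] = f.assign(lat=np.roll(f["lat"].to_numpy(), k), lon=np.roll(f["lon"].to_numpy(), k))
    out = pd.concat(frames, ignore_index=True)
    out.insert(0, "participant_id", "p")
    return classify_motion(out)


def test_circadian_movement_prefers_aligned_days():
    aligned = circadian_movement(_commute_week())
    rolled = circadian_movement(_commute_week(shuffle=True))
    assert aligned > rolled


def test_circadian_movement_band_selectivity():
    # a 24 h-periodic location signal carries more 24 h-band power than a 12 h one
    t_h = np.arange(0, 24 * 7, 0.5)
    base = T("2024-01-01")

    def trace(period):
        return classify_motion(
            _fixes([(base + pd.Timedelta(h, "h"), 0.01 * math.sin(2 * math.pi * h / period), 0.0) for h in t_h])
        )

    assert circadian_movement(trace(24.0)) > circadian_movement(trace(12.0))


def test_circadian_movement_undefined_for_constant_or_short():
    const = _fixes([(T("2024-01-01") + pd.Timedelta(h, "h"), 1.0, 1.0) for h in range(0, 72, 1)])
    assert math.isnan(circadian_movement(classify_motion(const)))
    short = _fixes([("2024-01-01 08:00", 0.0, 0.0), ("2024-01-01 09:00", 0.01, 0.0)])
    assert math.isnan(circadian_movement(classify_motion(short)))


def test_routine_index_identical_days_is_one():
    f = _commute_week()
    assert location_routine_index(f) == pytest.approx(1.0)
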