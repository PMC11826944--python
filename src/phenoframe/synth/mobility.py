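"""Synthetic GPS traces: transitions among per-participant anchor places.

Each participant gets 2-3 anchor points (home, work, optionally "other"),
pairwise at least 600 m apart, and a weekday-like daily schedule: home
overnight, a commute to work in the morning, back in the late afternoon,
with an occasional evening errand to the third anchor. Fixes are emitted
every 5 minutes with isotropic Gaussian jitter (sigma = 25 m), so place
clustering has a known ground-truth cluster count per day.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

FIX_INTERVAL_MIN = 5
JITTER_M = 25.0
TRAVEL_SPEED_KMH = 15.0
MIN_ANCHOR_SEPARATION_KM = 0.6

_M_PER_DEG_LAT = 110540.0
_M_PER_DEG_LON = 111320.0


def _offset(lat0: float, lon0: float, dist_km: float, bearing_rad: float) -> tuple[float, float]:
    dy = dist_km * 1000.0 * np.cos(bearing_rad)
    dx = dist_km * 1000.0 * np.sin(bearing_rad)
    return lat0 + dy / _M_PER_DEG_LAT, lon0 + dx / (_M_PER_DEG_LON * np.cos(np.radians(lat0)))


def _dist_km(a, b) -> float:
    lat0 = a[0]
    return (
        np.hypot((b[0] - a[0]) * _M_PER_DEG_LAT, (b[1] - a[1]) * _M_PER_DEG_LON * np.cos(np.radians(lat0)))
        / 1000.0
    )


def make_anchors(rng: np.random.Generator, n_anchors: int = 3) -> np.ndarray:
    """Anchor coordinates (n, 2) lat/lon, pairwise >= 600 m apart."""
    lat0 = 48.4 + rng.uniform(-0.05, 0.05)
    lon0 = 9.9 + rng.uniform(-0.05, 0.05)
    anchors = [(lat0, lon0)]
    for _ in range(n_anchors - 1):
        for _attempt in range(50):
            cand = _offset(lat0, lon0, rng.uniform(0.9, 2.5), rng.uniform(0, 2 * np.pi))
            if min(_dist_km(cand, a) for a in anchors) >= MIN_ANCHOR_SEPARATION_KM:
                anchors.append(cand)
                break
        else:  # pragma: no cover - 50 draws in a 2.5 km disk always suffice
            raise RuntimeError("could not place separated anchors")
    return np.array(anchors)


def day_waypoints(rng: np.random.Generator, visit_other: bool) -> list[tuple[int, float]]:
    """(anchor_index, departure_hour) itinerary; the last anchor holds to 24 h.

    Anchor 0 is home, 1 is work, 2 the optional errand place.
    """
    leave_home = 8.5 + rng.normal(0, 0.25)
    leave_work = 16.5 + rng.normal(0, 0.25)
    wp = [(0, leave_home), (1, leave_work)]
    if visit_other:
        depart_other = leave_work + rng.uniform(0.8, 1.2)
        wp.append((2, depart_other))
    wp.append((0, 24.0))
    return wp


def generate_day_fixes(
    rng: np.random.Generator,
    anchors: np.ndarray,
    day_start: pd.Timestamp,
    visit_other: bool,
    jitter_m: float = JITTER_M,
) -> tuple[pd.DataFrame, int]:
    """One day of 5-minute GPS fixes; returns (fixes, n_anchors_visited).

    Travel between anchors is interpolated at ~15 km/h so commutes produce
    genuine moving states; anchor dwell produces stationary runs. The
    returned ground truth counts anchors occupied for at least 10 minutes.
    """
    wp = day_waypoints(rng, visit_other and len(anchors) > 2)
    t_grid = np.arange(0.0, 24.0, FIX_INTERVAL_MIN / 60.0)
    lat = np.empty_like(t_grid)
    lon = np.empty_like(t_grid)

    # build piecewise (t_from, t_to, kind) legs: dwell at anchor or travel
    legs = []  # (t0, t1, a_from, a_to); a_from == a_to means stationary
    t_cursor = 0.0
    dwell_h: dict[int, float] = {}
    for i, (a, depart) in enumerate(wp):
        depart = max(depart, t_cursor)
        legs.append((t_cursor, depart, a, a))
        dwell_h[a] = dwell_h.get(a, 0.0) + (depart - t_cursor)
        if i + 1 < len(wp):
            nxt = wp[i + 1][0]
            tau = _dist_km(anchors[a], anchors[nxt]) / TRAVEL_SPEED_KMH
            legs.append((depart, depart + tau, a, nxt))
            t_cursor = depart + tau

    for i, t in enumerate(t_grid):
        pos = anchors[wp[-1][0]]
        for t0, t1, a_from, a_to in legs:
            if t0 <= t < t1:
                if a_from == a_to:
                    pos = anchors[a_from]
                else:
                    frac = (t - t0) / (t1 - t0)
                    pos = anchors[a_from] + frac * (anchors[a_to] - anchors[a_from])
                break
        lat[i], lon[i] = pos

    lat = lat + rng.normal(0, jitter_m, len(t_grid)) / _M_PER_DEG_LAT
    lon = lon + rng.normal(0, jitter_m, len(t_grid)) / (_M_PER_DEG_LON * np.cos(np.radians(anchors[0][0])))
    ts = day_start + pd.to_timedelta(t_grid, unit="h")
    fixes = pd.DataFrame({"timestamp": ts, "lat": lat, "lon": lon})
    n_visited = sum(1 for v in dwell_h.values() if v >= 10.0 / 60.0)
    return fixes, n_visited
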