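"""GPS/location features: motion classification, significant-place clustering,
mobility statistics, circadian rhythm, and the location routine index.

Significant places follow the stay-point construction used in mobile-sensing
pipelines: k-means over stationary fixes with k grown until two centroids
would come closer than 400 m; pauses (maximal stationary runs) within 200 m
of a centroid count as visits; clusters with at least 10 minutes of total
dwell are significant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import lombscargle
from sklearn.cluster import KMeans

from phenoframe.features import metrics
from phenoframe.features.metrics import _haversine_km_arrays

SPEED_THRESHOLD_KMH = 1.0  # > moving, < static; exactly 1 km/h counts as static
CLUSTER_MIN_SEPARATION_M = 400.0
VISIT_RADIUS_M = 200.0
SIGNIFICANT_DWELL_H = 10.0 / 60.0
CIRCADIAN_BAND_H = (23.5, 24.5)
_MAX_CLUSTERS = 10

LOCATION_DAY_COLUMNS = [
    "total_distance",
    "location_variance",
    "moving_static_ratio",
    "n_significant_clusters",
    "stay_duration_mean",
    "stay_duration_max",
    "stay_duration_sd",
    "time_top1",
    "time_top2",
    "time_top3",
    "location_entropy",
    "location_norm_entropy",
    "n_transitions",
    "outlier_time_ratio",
]


@dataclass
class StayCluster:
    cluster_id: int
    centroid: tuple[float, float]
    total_dwell: float  # hours
    visit_count: int
    significant: bool


def classify_motion(fixes: pd.DataFrame) -> pd.DataFrame:
    """Label each fix moving/static from the speed of the preceding segment.

    Fixes with duplicate timestamps are deduplicated (first kept). Speed
    between consecutive fixes is haversine distance over elapsed time; a fix
    is "moving" when that speed exceeds 1 km/h (exactly 1 km/h is static).
    The first fix copies the state of the following segment.
    """
    f = fixes.sort_values("timestamp", kind="mergesort").drop_duplicates("timestamp", keep="first").reset_index(drop=True)
    n = len(f)
    if n == 0:
        f["state"] = pd.Series(dtype=object)
        return f
    lat = f["lat"].to_numpy(float)
    lon = f["lon"].to_numpy(float)
    if np.any(np.abs(lat) > 90) or np.any(np.abs(lon) > 180):
        raise ValueError("invalid GPS coordinates")
    state = np.full(n, "static", dtype=object)
    if n > 1:
        t = f["timestamp"].astype("int64").to_numpy() / 3.6e12  # hours
        dist = _haversine_km_arrays(lat[:-1], lon[:-1], lat[1:], lon[1:])
        dt = np.diff(t)
        speed = np.divide(dist, dt, out=np.zeros_like(dist), where=dt > 0)
        state[1:] = np.where(speed > SPEED_THRESHOLD_KMH, "moving", "static")
        state[0] = state[1]
    f["state"] = state
    return f


def _project_m(lat, lon, lat0, lon0):
    """Local equirectangular projection to meters around (lat0, lon0)."""
    x = (np.asarray(lon) - lon0) * 111320.0 * np.cos(np.radians(lat0))
    y = (np.asarray(lat) - lat0) * 110540.0
    return np.column_stack([x, y])


def _pauses(day_fixes: pd.DataFrame) -> pd.DataFrame:
    """Maximal runs of >=2 consecutive static fixes within one day.

    Returns one row per pause: lat, lon (centroid), start, end, dwell_h.
    """
    static = (day_fixes["state"] == "static").to_numpy()
    runs = []
    i = 0
    n = len(day_fixes)
    while i < n:
        if static[i]:
            j = i
            while j + 1 < n and static[j + 1]:
                j += 1
            if j > i:
                runs.append((i, j))
            i = j + 1
        else:
            i += 1
    rows = []
    for i, j in runs:
        seg = day_fixes.iloc[i : j + 1]
        rows.append(
            {
                "lat": seg["lat"].mean(),
                "lon": seg["lon"].mean(),
                "start": seg["timestamp"].iloc[0],
                "end": seg["timestamp"].iloc[-1],
                "dwell_h": (seg["timestamp"].iloc[-1] - seg["timestamp"].iloc[0]).total_seconds() / 3600.0,
            }
        )
    return pd.DataFrame(rows, columns=["lat", "lon", "start", "end", "dwell_h"])


def _grow_kmeans(points_m: np.ndarray, max_k: int) -> np.ndarray:
    """Centroids from k-means with k grown until separation < 400 m.

    Returns the centroid array of the largest k whose pairwise centroid
    distances all stay >= the 400 m separation rule.
    """
    best = points_m.mean(axis=0, keepdims=True)
    n_distinct = len(np.unique(points_m, axis=0))
    for k in range(2, min(max_k, n_distinct) + 1):
        km = KMeans(n_clusters=k, n_init=4, random_state=0).fit(points_m)
        c = km.cluster_centers_
        d = np.sqrt(((c[:, None, :] - c[None, :, :]) ** 2).sum(-1))
        if d[np.triu_indices(k, 1)].min() < CLUSTER_MIN_SEPARATION_M:
            break
        best = c
    return best


def cluster_places(static_day_fixes: pd.DataFrame) -> tuple[list[StayCluster], dict]:
    """Significant-place clustering of one participant-day's stationary fixes.

    Returns the clusters and the day's location-cluster feature dict
    (all-NaN when there are no usable stationary pauses).
    """
    feats = {c: np.nan for c in LOCATION_DAY_COLUMNS if c not in ("total_distance", "location_variance", "moving_static_ratio")}
    pauses = _pauses(static_day_fixes)
    if pauses.empty:
        return [], feats
    lat0, lon0 = static_day_fixes["lat"].mean(), static_day_fixes["lon"].mean()
    pts = _project_m(static_day_fixes["lat"], static_day_fixes["lon"], lat0, lon0)
    centroids = _grow_kmeans(pts, max_k=min(_MAX_CLUSTERS, len(pauses)))
    p_xy = _project_m(pauses["lat"], pauses["lon"], lat0, lon0)
    d = np.sqrt(((p_xy[:, None, :] - centroids[None, :, :]) ** 2).sum(-1))
    nearest = d.argmin(axis=1)
    within = d[np.arange(len(pauses)), nearest] <= VISIT_RADIUS_M
    assigned = np.where(within, nearest, -1)

    clusters: list[StayCluster] = []
    for k in range(len(centroids)):
        mask = assigned == k
        dwell = float(pauses.loc[mask, "dwell_h"].sum())
        c_lat = lat0 + centroids[k, 1] / 110540.0
        c_lon = lon0 + centroids[k, 0] / (111320.0 * np.cos(np.radians(lat0)))
        clusters.append(
            StayCluster(
                cluster_id=k,
                centroid=(float(c_lat), float(c_lon)),
                total_dwell=dwell,
                visit_count=int(mask.sum()),
                significant=dwell >= SIGNIFICANT_DWELL_H,
            )
        )

    sig = sorted((c for c in clusters if c.significant), key=lambda c: -c.total_dwell)
    sig_dwell = np.array([c.total_dwell for c in sig])
    outlier_dwell = float(pauses.loc[assigned == -1, "dwell_h"].sum()) + sum(
        c.total_dwell for c in clusters if not c.significant
    )
    feats["n_significant_clusters"] = float(len(sig))
    if len(sig) > 0:
        feats["stay_duration_mean"] = float(sig_dwell.mean())
        feats["stay_duration_max"] = float(sig_dwell.max())
        feats["stay_duration_sd"] = float(sig_dwell.std(ddof=1)) if len(sig) > 1 else np.nan
        for k in (1, 2, 3):
            feats[f"time_top{k}"] = float(sig_dwell[k - 1]) if len(sig) >= k else 0.0
        feats["location_entropy"] = metrics.shannon_entropy(sig_dwell) if sig_dwell.sum() > 0 else np.nan
        feats["location_norm_entropy"] = metrics.normalized_entropy(sig_dwell)
        if sig_dwell.sum() > 0:
            feats["outlier_time_ratio"] = outlier_dwell / float(sig_dwell.sum())
    seq = assigned[assigned >= 0]
    feats["n_transitions"] = float(np.sum(seq[1:] != seq[:-1])) if len(seq) > 1 else 0.0
    return clusters, feats


def location_variance(fixes: pd.DataFrame) -> float:
    """ln of the combined population variance of latitude and longitude."""
    if len(fixes) < 2:
        return float("nan")
    v = float(np.var(fixes["lat"].to_numpy(float)) + np.var(fixes["lon"].to_numpy(float)))
    return float(np.log(v)) if v > 0 else float("nan")


def circadian_movement(fixes_one: pd.DataFrame) -> float:
    """ln of the summed 24 h-band Lomb-Scargle energy of lat and lon series.

    Least-squares spectral power is averaged over an evenly spaced grid of
    periods between 23.5 and 24.5 hours. Requires fixes spanning at least
    two days; returns NaN otherwise or when the band energy is zero.
    """
    f = fixes_one.sort_values("timestamp")
    if f["timestamp"].dt.normalize().nunique() < 2:
        return float("nan")
    t = f["timestamp"].astype("int64").to_numpy() / 3.6e12
    t = t - t[0]
    if t[-1] < 24.0:
        return float("nan")
    periods = np.linspace(CIRCADIAN_BAND_H[0], CIRCADIAN_BAND_H[1], 25)
    omega = 2.0 * np.pi / periods
    energy = 0.0
    for col in ("lat", "lon"):
        y = f[col].to_numpy(float)
        y = y - y.mean()
        if np.allclose(y, 0):
            continue
        energy += float(lombscargle(t, y, omega).mean())
    return float(np.log(energy)) if energy > 0 else float("nan")


def location_routine_index(fixes_one: pd.DataFrame) -> float:
    """Regularity of the hourly dominant significant place across days.

    Places are clustered once per participant (same growing-k rule) so that
    cluster identities are comparable across days; each hour's state is the
    cluster holding the most dwell in that hour, or "away" when no pause
    touches it. NaN with fewer than two days of stationary data.
    """
    day_groups = [g for _, g in fixes_one.groupby(fixes_one["timestamp"].dt.normalize())]
    pause_frames = []
    for g in day_groups:
        p = _pauses(g.reset_index(drop=True))
        if not p.empty:
            pause_frames.append(p)
    if len(pause_frames) < 2:
        return float("nan")
    pauses = pd.concat(pause_frames, ignore_index=True)
    lat0, lon0 = pauses["lat"].mean(), pauses["lon"].mean()
    static = fixes_one[fixes_one["state"] == "static"]
    pts = _project_m(static["lat"], static["lon"], lat0, lon0)
    centroids = _grow_kmeans(pts, max_k=_MAX_CLUSTERS)
    p_xy = _project_m(pauses["lat"], pauses["lon"], lat0, lon0)
    d = np.sqrt(((p_xy[:, None, :] - centroids[None, :, :]) ** 2).sum(-1))
    nearest = d.argmin(axis=1)
    within = d[np.arange(len(pauses)), nearest] <= VISIT_RADIUS_M
    pauses = pauses.assign(cluster=np.where(within, nearest, -1))
    pauses = pauses[pauses["cluster"] >= 0]
    if pauses.empty:
        return float("nan")
    dates = np.sort(pauses["start"].dt.normalize().unique())
    if len(dates) < 2:
        return float("nan")
    idx = {d_: i for i, d_ in enumerate(dates)}
    occupancy = np.zeros((len(centroids), len(dates), 24))
    day0 = pauses["start"].dt.normalize()
    s_h = ((pauses["start"] - day0).dt.total_seconds() / 3600.0).to_numpy()
    e_h = ((pauses["end"] - day0).dt.total_seconds() / 3600.0).to_numpy()
    rows = day0.map(idx).to_numpy()
    clus = pauses["cluster"].to_numpy()
    hours = np.arange(24.0)
    ov = np.clip(np.minimum(e_h[:, None], hours + 1.0) - np.maximum(s_h[:, None], hours), 0.0, None)
    for r, c, o in zip(rows, clus, ov):
        occupancy[c, r, :] += o
    dominant = np.argmax(occupancy, axis=0).astype(float)
    dominant[occupancy.max(axis=0) <= 0] = -1.0  # away
    return metrics.regularity_index(dominant)


def location_day_features(fixes_one: pd.DataFrame) -> pd.DataFrame:
    """All per-day location features for one participant's GPS stream.

    The two window-level features (circadian movement, routine index) are
    computed once over the whole stream and replicated on every day row.
    """
    if fixes_one.empty:
        return pd.DataFrame(columns=["participant_id", "date"] + LOCATION_DAY_COLUMNS)
    f = classify_motion(fixes_one)
    f["counted"] = True
    f.iloc[0, f.columns.get_loc("counted")] = False
    pid = f["participant_id"].iloc[0]
    rows = []
    for date, g in f.groupby(f["timestamp"].dt.normalize()):
        g = g.reset_index(drop=True)
        rec: dict = {"participant_id": pid, "date": date}
        lat, lon = g["lat"].to_numpy(float), g["lon"].to_numpy(float)
        rec["total_distance"] = (
            float(_haversine_km_arrays(lat[:-1], lon[:-1], lat[1:], lon[1:]).sum()) if len(g) > 1 else 0.0
        )
        rec["location_variance"] = location_variance(g)
        # ratio counts segment states: the stream's first fix only mirrors
        # its following segment and would double-count it
        states = g.loc[g["counted"], "state"]
        n_moving = int((states == "moving").sum())
        n_static = int((states == "static").sum())
        rec["moving_static_ratio"] = n_moving / n_static if n_static > 0 else np.nan
        _, cluster_feats = cluster_places(g)
        rec.update(cluster_feats)
        rows.append(rec)
    out = pd.DataFrame(rows)
    out["circadian_movement"] = circadian_movement(f)
    out["location_routine_index"] = location_routine_index(f)
    return out
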