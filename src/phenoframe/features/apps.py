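"""App-usage features: daily foreground-episode aggregates and regularity."""

from __future__ import annotations

import numpy as np
import pandas as pd

from phenoframe.features import metrics
from phenoframe.features._intervals import clip_to_days, hourly_durations


def app_day_features(episodes: pd.DataFrame) -> pd.DataFrame:
    """Per-day app features from foreground episodes.

    Columns in: participant_id, app_id, start, end. ``app_count`` is the
    number of foreground episodes of the day, ``app_duration_mean`` the mean
    episode duration in hours, and ``app_freq_entropy`` the Shannon entropy
    of per-app episode counts within the day.
    """
    cols = ["app_count", "app_duration_mean", "app_freq_entropy"]
    if episodes.empty:
        return pd.DataFrame(columns=["participant_id", "date"] + cols)
    pieces = clip_to_days(episodes)
    g = pieces.groupby(["participant_id", "date"], observed=True)
    out = g["duration_h"].agg(app_count="count", app_duration_mean="mean").reset_index()
    ent = (
        g["app_id"]
        .apply(lambda s: metrics.shannon_entropy(s.value_counts().to_numpy()))
        .rename("app_freq_entropy")
        .reset_index()
    )
    return out.merge(ent, on=["participant_id", "date"], how="left")


def app_regularity(episodes_one: pd.DataFrame) -> float:
    """Regularity of the hourly most-used app across one participant's days.

    The dominant state of an hour is the app with the largest foreground
    duration in that hour, or "idle" when nothing ran. NaN with fewer than
    two days of app data.
    """
    if episodes_one.empty:
        return float("nan")
    pieces = clip_to_days(episodes_one)
    per_app = hourly_durations(pieces, by="app_id")
    all_dates = np.sort(pieces["date"].unique())
    if len(all_dates) < 2:
        return float("nan")
    idx = {d: i for i, d in enumerate(all_dates)}
    apps = sorted(per_app)
    cube = np.zeros((len(apps), len(all_dates), 24))
    for a_i, app in enumerate(apps):
        dates, mat = per_app[app]
        rows = [idx[d] for d in dates]
        cube[a_i, rows, :] = mat
    dominant = np.argmax(cube, axis=0).astype(float)
    dominant[cube.max(axis=0) <= 0] = -1.0  # idle hours form their own state
    return metrics.regularity_index(dominant)
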