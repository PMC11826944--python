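"""Screen sensor features: unlock-episode sessionization and daily aggregates.

Pairing rules for raw lock/unlock events (the stream may be malformed):
an unlock opens an episode; the episode closes at the very next event,
whether that is a lock or another unlock (zero-gap policy for consecutive
unlocks); a lock without an open episode is dropped; a trailing unlock
with no later event is dropped. Under these rules every unlock except a
trailing one yields exactly one episode ending at the next event.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from phenoframe.features import metrics
from phenoframe.features._intervals import clip_to_days, hourly_durations


def sessionize_screen(events: pd.DataFrame) -> pd.DataFrame:
    """Pair lock/unlock events into unlock episodes.

    Parameters
    ----------
    events : DataFrame with columns participant_id, timestamp, state
        state in {"unlock", "lock"}; any participant mix is accepted.

    Returns
    -------
    DataFrame with columns participant_id, start, end, one row per episode,
    time-ordered and non-overlapping within participant.
    """
    if events.empty:
        return pd.DataFrame(columns=["participant_id", "start", "end"])
    ev = events.sort_values(["participant_id", "timestamp"], kind="mergesort").reset_index(drop=True)
    same_pid = ev["participant_id"].shift(-1) == ev["participant_id"]
    nxt = ev["timestamp"].shift(-1)
    keep = (ev["state"] == "unlock") & same_pid
    out = pd.DataFrame(
        {
            "participant_id": ev.loc[keep, "participant_id"],
            "start": ev.loc[keep, "timestamp"],
            "end": nxt[keep],
        }
    ).reset_index(drop=True)
    return out


def screen_day_features(episodes: pd.DataFrame) -> pd.DataFrame:
    """Per-day screen features from unlock episodes (one or many participants).

    An episode crossing midnight is clipped so each day is credited its own
    share; each clipped piece counts as an episode of its day. Days without
    any screen episode yield no row (missing sensor-day upstream).
    """
    cols = [
        "screen_episode_count",
        "screen_duration_sum",
        "screen_duration_mean",
        "screen_duration_max",
        "screen_entropy",
        "screen_norm_entropy",
    ]
    if episodes.empty:
        return pd.DataFrame(columns=["participant_id", "date"] + cols)
    pieces = clip_to_days(episodes)
    g = pieces.groupby(["participant_id", "date"], observed=True)["duration_h"]
    out = g.agg(
        screen_episode_count="count",
        screen_duration_sum="sum",
        screen_duration_mean="mean",
        screen_duration_max="max",
    ).reset_index()
    # entropy of the day's usage-duration distribution across unlock episodes
    ent = g.apply(lambda s: metrics.shannon_entropy(s.to_numpy()) if s.sum() > 0 else np.nan)
    nent = g.apply(lambda s: metrics.normalized_entropy(s.to_numpy()))
    out = out.merge(ent.rename("screen_entropy"), on=["participant_id", "date"])
    out = out.merge(nent.rename("screen_norm_entropy"), on=["participant_id", "date"])
    return out


def screen_regularity(episodes_one: pd.DataFrame) -> float:
    """Regularity index of the hourly dominant screen state (on/off).

    Computed across all days of one participant's observation window; an
    hour is "on" when unlock episodes cover at least half of it. NaN with
    fewer than two days of screen data.
    """
    if episodes_one.empty:
        return float("nan")
    pieces = clip_to_days(episodes_one)
    _, mat = hourly_durations(pieces)
    if mat.shape[0] < 2:
        return float("nan")
    states = (mat >= 0.5).astype(int)
    return metrics.regularity_index(states)
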