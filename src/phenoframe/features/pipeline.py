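"""Day-level feature table construction from raw event streams.

The pipeline accepts the five delimited-text streams (screen, app, call,
GPS, EMA) and produces one row per participant-day with one column per
feature. A sensor-day with no events at all yields missing values (never
zeros) for that sensor's features: absence of events is indistinguishable
from the sensor being off, and the distinction is what the downstream
missingness accounting runs on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from phenoframe.features.apps import app_day_features, app_regularity
from phenoframe.features.calls import CALL_COLUMNS, call_features
from phenoframe.features.ema import EMA_ITEMS, ema_daily
from phenoframe.features.location import LOCATION_DAY_COLUMNS, location_day_features
from phenoframe.features.screen import screen_day_features, screen_regularity, sessionize_screen

#: feature name -> (cluster, units, window_level)
FEATURES: dict[str, tuple[str, str, bool]] = {
    "screen_episode_count": ("screen", "count", False),
    "screen_duration_sum": ("screen", "hours", False),
    "screen_duration_mean": ("screen", "hours", False),
    "screen_duration_max": ("screen", "hours", False),
    "screen_entropy": ("screen", "nats", False),
    "screen_norm_entropy": ("screen", "unitless [0,1]", False),
    "screen_regularity": ("screen", "unitless [0,1]", True),
    "app_count": ("app", "count", False),
    "app_duration_mean": ("app", "hours", False),
    "app_freq_entropy": ("app", "nats", False),
    "app_regularity": ("app", "unitless [0,1]", True),
    **{c: ("call", "hours" if "duration" in c else ("nats" if "entropy" in c else "count"), False) for c in CALL_COLUMNS},
    "total_distance": ("location", "km", False),
    "location_variance": ("location", "ln(deg^2)", False),
    "moving_static_ratio": ("location", "ratio", False),
    "n_significant_clusters": ("location", "count", False),
    "stay_duration_mean": ("location", "hours", False),
    "stay_duration_max": ("location", "hours", False),
    "stay_duration_sd": ("location", "hours", False),
    "time_top1": ("location", "hours", False),
    "time_top2": ("location", "hours", False),
    "time_top3": ("location", "hours", False),
    "location_entropy": ("location", "nats", False),
    "location_norm_entropy": ("location", "unitless [0,1]", False),
    "n_transitions": ("location", "count", False),
    "outlier_time_ratio": ("location", "ratio", False),
    "circadian_movement": ("location", "ln(power)", True),
    "location_routine_index": ("location", "unitless [0,1]", True),
    **{f"ema_{i}": ("ema", "0-100 slider", False) for i in EMA_ITEMS},
}

#: features computed once per participant over the observation window and
#: replicated across its day rows (their 14-day SD is zero by construction)
WINDOW_FEATURES = frozenset(name for name, (_, _, w) in FEATURES.items() if w)

SENSORS = ("screen", "app", "calls", "gps", "ema")


def feature_dictionary() -> list[dict]:
    """Machine-readable feature dictionary (name, cluster, units, window level)."""
    return [
        {"name": name, "cluster": cluster, "units": units, "window_level": window}
        for name, (cluster, units, window) in FEATURES.items()
    ]


@dataclass
class EventBundle:
    """The five raw event streams of a cohort (any subset may be present)."""

    screen: pd.DataFrame | None = None
    app: pd.DataFrame | None = None
    calls: pd.DataFrame | None = None
    gps: pd.DataFrame | None = None
    ema: pd.DataFrame | None = None

    def sensors(self) -> list[str]:
        return [s for s in SENSORS if getattr(self, s) is not None]


def _merge(left: pd.DataFrame | None, right: pd.DataFrame) -> pd.DataFrame:
    if left is None:
        return right
    return left.merge(right, on=["participant_id", "date"], how="outer")


def extract_day_features(bundle: EventBundle) -> pd.DataFrame:
    """Compute the participant x date x feature table for all present sensors.

    Day rows are re-indexed to each participant's full observed date range,
    so interior days on which every sensor was silent appear as all-missing
    rows. Empty cells are NaN.
    """
    table: pd.DataFrame | None = None

    if bundle.screen is not None and not bundle.screen.empty:
        episodes = sessionize_screen(bundle.screen)
        day = screen_day_features(episodes)
        reg = (
            episodes.groupby("participant_id", observed=True)
            .apply(screen_regularity, include_groups=False)
            .rename("screen_regularity")
            .reset_index()
        )
        table = _merge(table, day.merge(reg, on="participant_id", how="left"))

    if bundle.app is not None and not bundle.app.empty:
        day = app_day_features(bundle.app)
        reg = (
            bundle.app.groupby("participant_id", observed=True)
            .apply(app_regularity, include_groups=False)
            .rename("app_regularity")
            .reset_index()
        )
        table = _merge(table, day.merge(reg, on="participant_id", how="left"))

    if bundle.calls is not None and not bundle.calls.empty:
        table = _merge(table, call_features(bundle.calls))

    if bundle.gps is not None and not bundle.gps.empty:
        parts = [
            location_day_features(g.reset_index(drop=True))
            for _, g in bundle.gps.groupby("participant_id", observed=True)
        ]
        table = _merge(table, pd.concat(parts, ignore_index=True))

    if bundle.ema is not None and not bundle.ema.empty:
        table = _merge(table, ema_daily(bundle.ema))

    if table is None:
        return pd.DataFrame(columns=["participant_id", "date"])

    # fill each participant's internal date gaps with all-missing rows
    filled = []
    for pid, g in table.groupby("participant_id", observed=True):
        rng = pd.date_range(g["date"].min(), g["date"].max(), freq="D")
        g = g.set_index("date").reindex(rng).rename_axis("date").reset_index()
        g["participant_id"] = pid
        for col in g.columns:
            if col in WINDOW_FEATURES:
                vals = g[col].dropna()
                if not vals.empty:
                    g[col] = vals.iloc[0]
        filled.append(g)
    out = pd.concat(filled, ignore_index=True)
    ordered = [c for c in FEATURES if c in out.columns]
    return out[["participant_id", "date"] + ordered].sort_values(["participant_id", "date"]).reset_index(drop=True)
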