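"""Call-log features, computed separately for incoming/outgoing/missed calls.

Counts and distinct contacts exist for all three directions; duration
aggregates (hours) and the duration-share entropy only for incoming and
outgoing calls (missed calls have no duration). A call is credited to the
day of its start timestamp.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from phenoframe.features import metrics

DIRECTIONS = ("incoming", "outgoing", "missed")

_COUNT_COLS = [f"call_{d}_{s}" for d in DIRECTIONS for s in ("count", "distinct")]
_DUR_COLS = [
    f"call_{d}_{s}"
    for d in ("incoming", "outgoing")
    for s in ("duration_mean", "duration_sum", "duration_max", "entropy")
]
CALL_COLUMNS = _COUNT_COLS + _DUR_COLS


def call_features(records: pd.DataFrame) -> pd.DataFrame:
    """Per-day call aggregates for any number of participants.

    Columns in: participant_id, timestamp, direction, contact_hash,
    duration_s. Days with no call record yield no row; a participant-day
    that has records but none of a given direction gets count 0 for that
    direction and missing duration features.
    """
    if records.empty:
        return pd.DataFrame(columns=["participant_id", "date"] + CALL_COLUMNS)
    rec = records.copy()
    if not set(rec["direction"]).issubset(DIRECTIONS):
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    rec["date"] = rec["timestamp"].dt.normalize()
    rec["duration_h"] = rec["duration_s"].astype(float) / 3600.0
    if (rec["duration_h"] < 0).any():
        raise ValueError("negative call duration")

    base = rec[["participant_id", "date"]].drop_duplicates().set_index(["participant_id", "date"])
    out = base.copy()
    for d in DIRECTIONS:
        sub = rec[rec["direction"] == d]
        g = sub.groupby(["participant_id", "date"], observed=True)
        out[f"call_{d}_count"] = g["direction"].count()
        out[f"call_{d}_distinct"] = g["contact_hash"].nunique()
        if d != "missed":
            out[f"call_{d}_duration_mean"] = g["duration_h"].mean()
            out[f"call_{d}_duration_sum"] = g["duration_h"].sum()
            out[f"call_{d}_duration_max"] = g["duration_h"].max()
            out[f"call_{d}_entropy"] = g["duration_h"].apply(
                lambda s: metrics.shannon_entropy(s.to_numpy()) if s.sum() > 0 else np.nan
            )
    for d in DIRECTIONS:  # a day with records has an observed (possibly zero) count
        out[f"call_{d}_count"] = out[f"call_{d}_count"].fillna(0).astype(float)
        out[f"call_{d}_distinct"] = out[f"call_{d}_distinct"].fillna(0).astype(float)
    return out.reset_index()[["participant_id", "date"] + CALL_COLUMNS]
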