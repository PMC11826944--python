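"""EMA daily aggregation: per-item mean over the answered prompts of a day."""

from __future__ import annotations

import pandas as pd

EMA_ITEMS = (
    "valence",
    "arousal",
    "stress",
    "sleep",
    "social_quality",
    "social_quantity",
    "nutrition",
    "physical_activity",
)


def ema_daily(responses: pd.DataFrame) -> pd.DataFrame:
    """Daily means of EMA items (0-100 sliders, up to 3 prompts/day).

    Columns in: participant_id, timestamp, item, value. Unanswered items
    of a day are simply absent and stay missing in the output.
    """
    cols = [f"ema_{i}" for i in EMA_ITEMS]
    if responses.empty:
        return pd.DataFrame(columns=["participant_id", "date"] + cols)
    r = responses.copy()
    if not set(r["item"]).issubset(EMA_ITEMS):
        unknown = sorted(set(r["item"]) - set(EMA_ITEMS))
        raise ValueError(f"unknown EMA item(s): {unknown}")
    if ((r["value"] < 0) | (r["value"] > 100)).any():
        raise ValueError("EMA values must lie in [0, 100]")
    r["date"] = r["timestamp"].dt.normalize()
    wide = r.pivot_table(index=["participant_id", "date"], columns="item", values="value", aggfunc="mean")
    wide = wide.rename(columns={i: f"ema_{i}" for i in EMA_ITEMS}).reindex(columns=cols)
    return wide.reset_index()
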