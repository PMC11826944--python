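"""Delimited-text writers/readers for cohort event streams (RFC-4180, UTF-8).

File schemas:
  screen_events.csv  participant_id, timestamp_iso8601, state{unlock,lock}
  app_events.csv     participant_id, app_id, start_iso, end_iso
  calls.csv          participant_id, timestamp_iso, direction, contact_hash, duration_s
  gps.csv            participant_id, timestamp_iso, lat, lon
  ema.csv            participant_id, timestamp_iso, item, value
  phq8.csv           participant_id, date, item_1..item_8
  participants.csv   participant_id, age, gender
  truth.json         ground-truth severities and the injected effect map
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

_TS_FMT = "%Y-%m-%dT%H:%M:%S.%f"


def _fmt(df: pd.DataFrame, cols: dict[str, str]) -> pd.DataFrame:
    out = df.rename(columns=cols).copy()
    for c in out.columns:
        if c.endswith(("iso", "iso8601")):
            out[c] = pd.to_datetime(out[c]).dt.strftime(_TS_FMT)
    return out


def write_cohort(cohort, outdir) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    _fmt(cohort.screen, {"timestamp": "timestamp_iso8601"}).to_csv(out / "screen_events.csv", index=False)
    _fmt(cohort.app, {"start": "start_iso", "end": "end_iso"}).to_csv(out / "app_events.csv", index=False)
    _fmt(cohort.calls, {"timestamp": "timestamp_iso"}).to_csv(out / "calls.csv", index=False)
    _fmt(cohort.gps, {"timestamp": "timestamp_iso"}).to_csv(out / "gps.csv", index=False)
    _fmt(cohort.ema, {"timestamp": "timestamp_iso"}).to_csv(out / "ema.csv", index=False)
    phq = cohort.phq8.copy()
    phq["date"] = phq["date"].dt.strftime("%Y-%m-%d")
    phq.to_csv(out / "phq8.csv", index=False)
    cohort.participants.to_csv(out / "participants.csv", index=False)
    truth = dict(cohort.truth)
    if cohort.day_anchor_counts is not None:
        dac = cohort.day_anchor_counts.copy()
        dac["date"] = dac["date"].dt.strftime("%Y-%m-%d")
        truth["day_anchor_counts"] = dac.to_dict(orient="records")
    (out / "truth.json").write_text(json.dumps(truth, indent=1))


def read_events_dir(indir):
    """Read the event files of a cohort directory into an EventBundle plus logs.

    Returns (bundle, phq8, participants); missing files yield None entries.
    """
    from phenoframe.features.pipeline import EventBundle

    ind = Path(indir)

    def _read(name: str, ts_cols: dict[str, str]) -> pd.DataFrame | None:
        p = ind / name
        if not p.exists():
            return None
        df = pd.read_csv(p)
        for src, dst in ts_cols.items():
            if src in df.columns:
                df[dst] = pd.to_datetime(df[src])
                if src != dst:
                    df = df.drop(columns=[src])
        return df

    bundle = EventBundle(
        screen=_read("screen_events.csv", {"timestamp_iso8601": "timestamp", "timestamp": "timestamp"}),
        app=_read("app_events.csv", {"start_iso": "start", "end_iso": "end", "start": "start", "end": "end"}),
        calls=_read("calls.csv", {"timestamp_iso": "timestamp", "timestamp": "timestamp"}),
        gps=_read("gps.csv", {"timestamp_iso": "timestamp", "timestamp": "timestamp"}),
        ema=_read("ema.csv", {"timestamp_iso": "timestamp", "timestamp": "timestamp"}),
    )
    phq8 = _read("phq8.csv", {"date": "date"})
    participants = _read("participants.csv", {})
    return bundle, phq8, participants
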