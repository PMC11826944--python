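"""Interval helpers: clipping usage episodes to local-day boundaries.

Days are local [00:00, 24:00); an episode crossing midnight is split so
that each calendar day is credited exactly the duration that falls inside
it (total duration is conserved by construction).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

_NS = pd.Timedelta(1, "ns")


def clip_to_days(df: pd.DataFrame, start_col: str = "start", end_col: str = "end") -> pd.DataFrame:
    """Split episodes at midnight; returns one row per (episode, day) piece.

    Output columns: all input columns plus ``date`` (normalized day),
    ``piece_start``, ``piece_end``, ``duration_h``.
    """
    if df.empty:
        out = df.copy()
        out["date"] = pd.Series(dtype="datetime64[ns]")
        out["piece_start"] = pd.Series(dtype="datetime64[ns]")
        out["piece_end"] = pd.Series(dtype="datetime64[ns]")
        out["duration_h"] = pd.Series(dtype=float)
        return out
    start = df[start_col]
    end = df[end_col]
    if (end < start).any():
        raise ValueError("episode end precedes start")
    d_first = start.dt.normalize()
    # an episode ending exactly at midnight belongs to the preceding day
    end_eff = end.where(end > start, start)
    d_last = (end_eff - _NS).dt.normalize()
    d_last = d_last.where(end > start, d_first)

    simple_mask = (d_first == d_last).to_numpy()
    simple = df.loc[simple_mask].copy()
    simple["date"] = d_first[simple_mask]
    simple["piece_start"] = start[simple_mask]
    simple["piece_end"] = end[simple_mask]

    pieces = [simple]
    spanning = df.loc[~simple_mask]
    for idx, row in spanning.iterrows():
        s, e = row[start_col], row[end_col]
        day = s.normalize()
        while s < e:
            nxt = day + pd.Timedelta(1, "D")
            pe = min(e, nxt)
            piece = row.copy()
            piece["date"] = day
            piece["piece_start"] = s
            piece["piece_end"] = pe
            pieces.append(piece.to_frame().T)
            s, day = nxt, nxt
    out = pd.concat(pieces, ignore_index=True)
    out["piece_start"] = pd.to_datetime(out["piece_start"])
    out["piece_end"] = pd.to_datetime(out["piece_end"])
    out["date"] = pd.to_datetime(out["date"])
    out["duration_h"] = (out["piece_end"] - out["piece_start"]).dt.total_seconds() / 3600.0
    return out


def hourly_durations(pieces: pd.DataFrame, by: str | None = None) -> np.ndarray | dict:
    """Duration (hours) falling into each hour bin of each day.

    ``pieces`` must carry ``date``, ``piece_start``, ``piece_end`` for one
    participant. Returns (dates, matrix) where matrix[d, h] is the summed
    overlap of all pieces with hour h of day d. If ``by`` is given, returns
    {value -> (dates, matrix)} grouped by that column (e.g. app id).
    """
    if by is not None:
        return {k: hourly_durations(g) for k, g in pieces.groupby(by, observed=True)}
    dates = np.sort(pieces["date"].unique())
    date_idx = {d: i for i, d in enumerate(dates)}
    mat = np.zeros((len(dates), 24))
    if pieces.empty:
        return dates, mat
    day0 = pieces["date"]
    s_h = ((pieces["piece_start"] - day0).dt.total_seconds() / 3600.0).to_numpy()
    e_h = ((pieces["piece_end"] - day0).dt.total_seconds() / 3600.0).to_numpy()
    rows = pieces["date"].map(date_idx).to_numpy()
    hours = np.arange(24.0)
    # overlap of [s, e) with each unit hour bin, vectorized pieces x 24
    ov = np.clip(np.minimum(e_h[:, None], hours + 1.0) - np.maximum(s_h[:, None], hours), 0.0, None)
    np.add.at(mat, rows, ov)
    return dates, mat
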