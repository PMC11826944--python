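"""14-day episode assembly around PHQ-8 responses and eligibility filtering.

The PHQ-8 asks about the last 14 days, so an episode spans the completion
day and the 13 preceding days. Per participant, only the episode with the
lowest missingness enters the analysis (ties broken by earliest date), and
participants whose best episode still misses more than 50% of cells are
excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

EPISODE_DAYS = 14
MISSINGNESS_CUTOFF = 0.5

_ITEM_COLS = [f"item_{k}" for k in range(1, 9)]


@dataclass
class Episode:
    """One PHQ-8 response plus the 14-day day-level feature block it covers."""

    participant_id: str
    phq8_date: pd.Timestamp
    phq8_sum: int
    day_block: pd.DataFrame  # exactly 14 rows, indexed by date
    missingness: float


def episode_missingness(day_block: pd.DataFrame, counted_features: list[str]) -> float:
    """Fraction of missing cells over 14 days x the counted feature columns."""
    if not counted_features:
        raise ValueError("counted feature list must not be empty")
    block = day_block[counted_features]
    return float(block.isna().to_numpy().mean())


def build_episodes(
    phq8: pd.DataFrame,
    day_features: pd.DataFrame,
    counted_features: list[str] | None = None,
) -> list[Episode]:
    """One Episode per PHQ-8 response; absent days appear as all-missing rows.

    ``phq8`` must carry participant_id, date and item_1..item_8 (each in
    {0..3}); participants without any PHQ-8 response simply yield no episode.
    """
    items = phq8[_ITEM_COLS]
    if items.isna().any().any() or not items.isin([0, 1, 2, 3]).all().all():
        raise ValueError("PHQ-8 items must all lie in {0, 1, 2, 3}")
    feature_cols = [c for c in day_features.columns if c not in ("participant_id", "date")]
    counted = counted_features if counted_features is not None else feature_cols
    missing_in_table = set(counted) - set(feature_cols)
    if missing_in_table:
        raise ValueError(f"counted features absent from the day table: {sorted(missing_in_table)}")

    episodes: list[Episode] = []
    by_pid = dict(tuple(day_features.groupby("participant_id", observed=True)))
    for _, row in phq8.iterrows():
        pid, date = row["participant_id"], pd.Timestamp(row["date"])
        window = pd.date_range(date - pd.Timedelta(EPISODE_DAYS - 1, "D"), date, freq="D")
        g = by_pid.get(pid)
        if g is None:
            block = pd.DataFrame(index=window, columns=feature_cols, dtype=float)
        else:
            block = g.set_index("date").reindex(window)[feature_cols]
        block = block.rename_axis("date")
        episodes.append(
            Episode(
                participant_id=pid,
                phq8_date=date,
                phq8_sum=int(row[_ITEM_COLS].sum()),
                day_block=block.astype(float),
                missingness=episode_missingness(block, counted),
            )
        )
    return episodes


def select_best_episode(episodes: list[Episode]) -> Episode:
    """The minimum-missingness episode of one participant; ties -> earliest."""
    if not episodes:
        raise ValueError("participant has no episodes")
    return min(episodes, key=lambda e: (e.missingness, e.phq8_date))


def apply_exclusion(selected: list[Episode]) -> tuple[list[Episode], dict]:
    """Drop episodes with more than 50% missing cells (strict inequality).

    Returns the analysis set and an exclusion report with counts.
    """
    kept = [e for e in selected if e.missingness <= MISSINGNESS_CUTOFF]
    report = {
        "n_before": len(selected),
        "n_excluded": len(selected) - len(kept),
        "n_after": len(kept),
        "cutoff": MISSINGNESS_CUTOFF,
        "excluded_participants": sorted(e.participant_id for e in selected if e.missingness > MISSINGNESS_CUTOFF),
    }
    return kept, report


def phq8_descriptives(sums, cutoff: int = 10) -> dict:
    """Cohort-level PHQ-8 summary: mean, SD, and share at/above the cutoff.

    The share is reported in percent rounded to one decimal, the convention
    used for prevalence of clinically relevant severity (PHQ-8 >= 10).
    """
    s = np.asarray(list(sums), dtype=float)
    if s.size == 0:
        raise ValueError("no PHQ-8 sums supplied")
    n_above = int((s >= cutoff).sum())
    return {
        "n": int(s.size),
        "mean": float(s.mean()),
        "sd": float(s.std(ddof=1)) if s.size > 1 else float("nan"),
        "n_above_cutoff": n_above,
        "pct_above_cutoff": round(100.0 * n_above / s.size, 1),
    }


def build_analysis_set(
    phq8: pd.DataFrame,
    day_features: pd.DataFrame,
    counted_features: list[str] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Episode filters end-to-end: build, select best per person, exclude.

    Returns a stacked day-level table (participant_id, date, phq8_sum and
    feature columns; 14 rows per retained participant) ready for imputation,
    plus the exclusion report.
    """
    episodes = build_episodes(phq8, day_features, counted_features)
    by_pid: dict[str, list[Episode]] = {}
    for e in episodes:
        by_pid.setdefault(e.participant_id, []).append(e)
    selected = [select_best_episode(v) for v in by_pid.values()]
    kept, report = apply_exclusion(selected)
    report["selected_episodes"] = [
        {
            "participant_id": e.participant_id,
            "phq8_date": str(e.phq8_date.date()),
            "phq8_sum": e.phq8_sum,
            "missingness": e.missingness,
            "retained": e.missingness <= MISSINGNESS_CUTOFF,
        }
        for e in sorted(selected, key=lambda e: e.participant_id)
    ]

    frames = []
    for e in sorted(kept, key=lambda e: e.participant_id):
        block = e.day_block.reset_index()
        block.insert(0, "participant_id", e.participant_id)
        block.insert(2, "phq8_sum", float(e.phq8_sum))
        frames.append(block)
    table = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["participant_id", "date", "phq8_sum"])
    )
    return table, report
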