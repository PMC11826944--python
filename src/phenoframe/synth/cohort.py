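"""Synthetic cohort generation: event streams, EMA, PHQ-8 and ground truth.

Every stream is driven by a per-participant latent depression severity on
the PHQ-8 scale (0-24). Features named in the effect map get generating
parameters linear in standardized severity (see ``config.calibrate_loading``);
everything else varies between persons independently of severity. Sensor-days
and EMA prompts are dropped according to the missingness model (MCAR by
default, severity-dependent when ``dropout_mnar_slope`` is nonzero).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import hashlib

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from phenoframe.features.pipeline import EventBundle
from phenoframe.synth import config as cfg
from phenoframe.synth.config import CohortConfig
from phenoframe.synth.mobility import generate_day_fixes, make_anchors

START_DATE = pd.Timestamp("2024-01-01")

_EMA_SLOTS = (
    ("morning", 8.0, ("valence", "arousal", "stress", "sleep")),
    ("midday", 13.0, ("valence", "arousal", "stress")),
    ("evening", 20.0, ("valence", "arousal", "stress", "social_quality", "social_quantity", "nutrition", "physical_activity")),
)

_APP_POOL = [f"app_{i:02d}" for i in range(8)]


def generate_phq8_items(severity: float, rng: np.random.Generator, noise_sd: float = cfg.PHQ_NOISE_SD) -> np.ndarray:
    """Eight item scores in {0..3} whose sum has expectation ~ severity.

    The noisy severity is rounded to a total in [0, 24] and spread as evenly
    as possible over the items (a random subset carries the remainder), so
    severity 24 yields all 3s and severity 0 all 0s in the zero-noise limit.
    """
    if not (0.0 <= severity <= 24.0):
        raise ValueError(f"severity must lie in [0, 24], got {severity}")
    total = int(np.clip(np.round(severity + rng.normal(0.0, noise_sd)), 0, 24))
    q, rem = divmod(total, 8)
    items = np.full(8, q, dtype=int)
    if rem:
        items[rng.choice(8, size=rem, replace=False)] += 1
    return items


@dataclass
class SyntheticCohort:
    """Generated raw streams plus the ground truth that produced them."""

    config: CohortConfig
    participants: pd.DataFrame
    screen: pd.DataFrame
    app: pd.DataFrame
    calls: pd.DataFrame
    gps: pd.DataFrame
    ema: pd.DataFrame
    phq8: pd.DataFrame
    truth: dict = field(repr=False)
    day_anchor_counts: pd.DataFrame | None = None

    def to_bundle(self) -> EventBundle:
        s = self.config.sensors
        return EventBundle(
            screen=self.screen if "screen" in s else None,
            app=self.app if "app" in s else None,
            calls=self.calls if "calls" in s else None,
            gps=self.gps if "gps" in s else None,
            ema=self.ema if "ema" in s else None,
        )

    def write(self, outdir) -> None:
        from phenoframe.synth.writers import write_cohort

        write_cohort(self, outdir)


def _participant_params(config: CohortConfig, rng: np.random.Generator, z: np.ndarray, mood: np.ndarray) -> dict:
    """Per-participant generating parameters for every stream."""
    n = config.n_participants
    eff = config.effect_map

    def theta(feature: str, mood_sign: float = 0.0) -> np.ndarray:
        m, s, _ = cfg.INJECTABLE[feature]
        r = eff.get(feature, 0.0)
        mood_var = cfg.EMA_MOOD_VAR if feature.startswith("ema_") else 0.0
        b, g, d = cfg.calibrate_loading(r, feature, mood_var)
        return m + s * (b * z + g * mood_sign * mood + d * rng.standard_normal(n))

    p: dict = {}
    for item, (_, _, _, sign) in cfg.EMA_PARAMS.items():
        p[f"ema_{item}"] = np.clip(theta(f"ema_{item}", mood_sign=sign), 1.0, 99.0)
    if "screen_duration_sum" in eff:
        total = np.clip(theta("screen_duration_sum"), 0.2, None)
        p["screen_mu"] = total / cfg.SCREEN_K_MEAN
        p["screen_k"] = np.full(n, cfg.SCREEN_K_MEAN) + cfg.SCREEN_K_SD * rng.standard_normal(n)
    else:
        p["screen_mu"] = theta("screen_duration_mean")
        p["screen_k"] = theta("screen_episode_count")
    p["screen_mu"] = np.clip(p["screen_mu"], 0.02, None)
    p["screen_k"] = np.clip(p["screen_k"], 6.0, None)
    for d in ("incoming", "outgoing"):
        p[f"call_mu_{d}"] = np.clip(theta(f"call_{d}_duration_mean"), 0.008, None)
        p[f"call_rate_{d}"] = np.clip(theta(f"call_{d}_count"), 1.2, None)
    # per-participant app preference: permuted power-law weights
    w = (np.arange(1, len(_APP_POOL) + 1)) ** -1.2
    p["app_weights"] = np.stack([rng.permutation(w / w.sum()) for _ in range(n)])
    return p


def _drop_prob(p0: float, slope: float, z: np.ndarray) -> np.ndarray:
    if p0 <= 0.0:
        return np.zeros_like(z)
    if p0 >= 1.0:
        return np.ones_like(z)
    if slope == 0.0:
        return np.full_like(z, p0)
    return expit(logit(p0) + slope * z)


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate the full cohort deterministically from ``config.seed``."""
    n = config.n_participants
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(n + 1)
    crng = np.random.default_rng(children[0])

    severity = crng.gamma(cfg.GAMMA_SHAPE, cfg.GAMMA_SCALE, n)
    while np.any(severity > cfg.SEVERITY_MAX):  # truncated right tail
        bad = severity > cfg.SEVERITY_MAX
        severity[bad] = crng.gamma(cfg.GAMMA_SHAPE, cfg.GAMMA_SCALE, int(bad.sum()))
    # standardize within the realized cohort: correlation targets then do not
    # inherit the sampling error of the severity draw itself
    if n > 1 and severity.std() > 0:
        z = (severity - severity.mean()) / severity.std()
    else:
        z = np.zeros(n)
    mood = crng.standard_normal(n)
    age = np.clip(18 + np.round(crng.gamma(2.0, 2.4, n)), 18, 56).astype(int)
    gender = np.where(crng.uniform(size=n) < 0.776, "female", "male")
    params = _participant_params(config, crng, z, mood)

    pids = [f"p{i:04d}" for i in range(n)]
    p_day = _drop_prob(config.missing_rate_day, config.dropout_mnar_slope, z)
    p_ema = _drop_prob(config.missing_rate_ema, config.dropout_mnar_slope, z)
    sensors = set(config.sensors)
    need_sessions = bool(sensors & {"screen", "app"})
    total_days = config.total_days

    screen_rows: list = []  # (pid, day, hour, state)
    app_rows: list = []  # (pid, app, day, start_h, end_h)
    call_rows: list = []  # (pid, day, hour, direction, contact, dur_s)
    ema_rows: list = []  # (pid, day, hour, item, value)
    gps_frames: list = []
    phq_rows: list = []
    anchor_rows: list = []

    for i, pid in enumerate(pids):
        prng = np.random.default_rng(children[i + 1])
        anchors = make_anchors(prng) if "gps" in sensors else None
        contacts = [hashlib.md5(f"{pid}:{j}".encode()).hexdigest()[:12] for j in range(6)]
        contact_w = np.arange(1.0, 7.0) ** -1.0
        contact_w /= contact_w.sum()
        mu_s, k_s = params["screen_mu"][i], params["screen_k"][i]
        gap = max(24.0 / k_s - mu_s, 0.05)

        for d in range(total_days):
            drop = {s: prng.uniform() < p_day[i] for s in ("screen", "app", "calls", "gps")}

            if need_sessions:
                t = 0.0
                sessions = []
                while True:
                    t += prng.exponential(gap)
                    if t >= 24.0:
                        break
                    dur = prng.gamma(cfg.SCREEN_SESSION_SHAPE, mu_s / cfg.SCREEN_SESSION_SHAPE)
                    end = min(t + dur, 24.0 - 1e-6)
                    sessions.append((t, end))
                    t = end
                if "screen" in sensors and not drop["screen"]:
                    for s0, s1 in sessions:
                        screen_rows.append((pid, d, s0, "unlock"))
                        screen_rows.append((pid, d, s1, "lock"))
                if "app" in sensors and not drop["app"]:
                    for s0, s1 in sessions:
                        dur = s1 - s0
                        n_ep = 1 + int(prng.poisson(min(dur / 0.08, 5.0)))
                        n_ep = min(n_ep, 8)
                        splits = prng.dirichlet(np.ones(n_ep)) * dur
                        apps = prng.choice(_APP_POOL, size=n_ep, p=params["app_weights"][i])
                        t0 = s0
                        for a, w_len in zip(apps, splits):
                            app_rows.append((pid, a, d, t0, t0 + w_len))
                            t0 += w_len

            if "calls" in sensors:
                for direction in ("incoming", "outgoing"):
                    n_calls = 1 + int(prng.poisson(params[f"call_rate_{direction}"][i] - 1.0))
                    times = np.sort(prng.uniform(8.0, 22.0, n_calls))
                    durs = prng.gamma(cfg.CALL_DUR_SHAPE, params[f"call_mu_{direction}"][i] / cfg.CALL_DUR_SHAPE, n_calls)
                    whos = prng.choice(6, size=n_calls, p=contact_w)
                    if not drop["calls"]:
                        for t_c, du, who in zip(times, durs, whos):
                            call_rows.append((pid, d, t_c, direction, contacts[who], du * 3600.0))
                n_missed = int(prng.poisson(cfg.MISSED_RATE))
                if n_missed and not drop["calls"]:
                    times = np.sort(prng.uniform(8.0, 22.0, n_missed))
                    whos = prng.choice(6, size=n_missed, p=contact_w)
                    for t_c, who in zip(times, whos):
                        call_rows.append((pid, d, t_c, "missed", contacts[who], 0.0))

            if "gps" in sensors:
                visit_other = prng.uniform() < 0.35
                fixes, n_anchor = generate_day_fixes(prng, anchors, START_DATE + pd.Timedelta(d, "D"), visit_other)
                if not drop["gps"]:
                    fixes.insert(0, "participant_id", pid)
                    gps_frames.append(fixes)
                    anchor_rows.append((pid, d, n_anchor))

            if "ema" in sensors:
                for _slot, hour0, items in _EMA_SLOTS:
                    answered = prng.uniform() >= p_ema[i]
                    t_h = hour0 + prng.uniform()
                    vals = {item: float(np.clip(params[f"ema_{item}"][i] + prng.normal(0.0, cfg.EMA_PROMPT_SD), 0.0, 100.0)) for item in items}
                    if answered:
                        for item, v in vals.items():
                            ema_rows.append((pid, d, t_h, item, v))

        for e in range(config.episodes_per_participant):
            d_idx = 14 * (e + 1) - 1
            if d_idx < total_days:
                items = generate_phq8_items(severity[i], prng)
                phq_rows.append((pid, d_idx, *items))

    def _ts(day: pd.Series, hour: pd.Series) -> pd.Series:
        return START_DATE + pd.to_timedelta(day.to_numpy() * 24.0 + hour.to_numpy(), unit="h")

    screen = pd.DataFrame(screen_rows, columns=["participant_id", "day", "hour", "state"])
    screen["timestamp"] = _ts(screen["day"], screen["hour"])
    screen = screen.sort_values(["participant_id", "timestamp"]).reset_index(drop=True)[["participant_id", "timestamp", "state"]]

    app = pd.DataFrame(app_rows, columns=["participant_id", "app_id", "day", "s0", "s1"])
    app["start"] = _ts(app["day"], app["s0"])
    app["end"] = _ts(app["day"], app["s1"])
    app = app[["participant_id", "app_id", "start", "end"]]

    calls = pd.DataFrame(call_rows, columns=["participant_id", "day", "hour", "direction", "contact_hash", "duration_s"])
    calls["timestamp"] = _ts(calls["day"], calls["hour"])
    calls = calls[["participant_id", "timestamp", "direction", "contact_hash", "duration_s"]]

    ema = pd.DataFrame(ema_rows, columns=["participant_id", "day", "hour", "item", "value"])
    ema["timestamp"] = _ts(ema["day"], ema["hour"])
    ema = ema[["participant_id", "timestamp", "item", "value"]]

    gps = (
        pd.concat(gps_frames, ignore_index=True)[["participant_id", "timestamp", "lat", "lon"]]
        if gps_frames
        else pd.DataFrame(columns=["participant_id", "timestamp", "lat", "lon"])
    )

    phq8 = pd.DataFrame(phq_rows, columns=["participant_id", "day"] + [f"item_{k}" for k in range(1, 9)])
    phq8["date"] = START_DATE + pd.to_timedelta(phq8["day"], unit="D")
    phq8 = phq8[["participant_id", "date"] + [f"item_{k}" for k in range(1, 9)]]

    participants = pd.DataFrame({"participant_id": pids, "age": age, "gender": gender})
    anchor_counts = pd.DataFrame(anchor_rows, columns=["participant_id", "day", "n_anchors"]) if anchor_rows else None
    if anchor_counts is not None:
        anchor_counts["date"] = START_DATE + pd.to_timedelta(anchor_counts["day"], unit="D")
        anchor_counts = anchor_counts[["participant_id", "date", "n_anchors"]]

    truth = {
        "seed": config.seed,
        "effect_map": dict(config.effect_map),
        "participants": [
            {"participant_id": pid, "severity": float(severity[i]), "age": int(age[i]), "gender": str(gender[i])}
            for i, pid in enumerate(pids)
        ],
    }
    return SyntheticCohort(
        config=config,
        participants=participants,
        screen=screen,
        app=app,
        calls=calls,
        gps=gps,
        ema=ema,
        phq8=phq8,
        truth=truth,
        day_anchor_counts=anchor_counts,
    )
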