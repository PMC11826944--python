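"""Cohort configuration and the feature-severity calibration tables.

Correlation injection is between-person: a feature named in ``effect_map``
gets its per-participant generating parameter drawn linearly in latent
depression severity, with the loading calibrated so that the correlation
between the feature's 14-day mean and the *observed* PHQ-8 sum hits the
target. Two attenuation sources are compensated analytically: day-to-day
noise shrinking the 14-day mean's between-person signal, and PHQ-8
measurement noise (item discretization) shrinking any correlation with
the questionnaire score.
"""

from __future__ import annotations

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from phenoframe.features.pipeline import FEATURES

# latent severity: gamma right-skew matching a subclinical cohort
SEVERITY_MEAN = 5.82
SEVERITY_SD = 4.44
SEVERITY_MAX = 24.0
GAMMA_SHAPE = SEVERITY_MEAN**2 / SEVERITY_SD**2
GAMMA_SCALE = SEVERITY_SD**2 / SEVERITY_MEAN

PHQ_NOISE_SD = 0.8
# corr(severity, PHQ-8 sum): attenuation from additive noise + rounding
PHQ_ATTENUATION = SEVERITY_SD / float(np.sqrt(SEVERITY_SD**2 + PHQ_NOISE_SD**2 + 1.0 / 12.0))

EMA_PROMPT_SD = 8.0
AGG_DAYS = 14  # episode aggregation window

# EMA item -> (baseline, between-person SD, prompts/day, mood-factor sign)
EMA_PARAMS: dict[str, tuple[float, float, int, float]] = {
    "valence": (66.0, 12.8, 3, +1.0),
    "arousal": (50.0, 12.2, 3, +1.0),
    "stress": (39.0, 15.7, 3, -1.0),
    "sleep": (62.0, 12.0, 1, +1.0),
    "social_quality": (65.0, 12.0, 1, +1.0),
    "social_quantity": (65.0, 12.0, 1, +1.0),
    "nutrition": (62.0, 12.0, 1, +1.0),
    "physical_activity": (50.0, 13.0, 1, +1.0),
}
# EMA items are conditionally independent given severity: a feature absent
# from the effect map is null both marginally and as a partial effect (a
# shared affect factor would turn marginal nulls into genuine suppressors)
EMA_MOOD_VAR = 0.0

# screen usage generating parameters
SCREEN_MU_MEAN, SCREEN_MU_SD = 0.11, 0.035  # session duration mean (h)
SCREEN_K_MEAN, SCREEN_K_SD = 24.0, 6.0  # sessions per day
SCREEN_SESSION_SHAPE = 2.0  # gamma shape of session durations

# call generating parameters
CALL_RATE_MEAN, CALL_RATE_SD = 2.5, 0.8  # calls/day per direction (>= 1)
CALL_MU_MEAN, CALL_MU_SD = 0.06, 0.022  # call duration mean (h)
CALL_DUR_SHAPE = 1.5
MISSED_RATE = 0.4


def _day_noise_var() -> dict[str, float]:
    """Variance of the 14-day feature mean due to within-day noise alone."""
    v_session = SCREEN_MU_MEAN**2 / SCREEN_SESSION_SHAPE
    v_call = CALL_MU_MEAN**2 / CALL_DUR_SHAPE
    out = {
        "screen_duration_mean": v_session / (SCREEN_K_MEAN * AGG_DAYS),
        "screen_episode_count": SCREEN_K_MEAN / AGG_DAYS,
        "screen_duration_sum": (SCREEN_K_MEAN * v_session + SCREEN_MU_MEAN**2 * SCREEN_K_MEAN) / AGG_DAYS,
        "call_incoming_duration_mean": v_call / (CALL_RATE_MEAN * AGG_DAYS),
        "call_outgoing_duration_mean": v_call / (CALL_RATE_MEAN * AGG_DAYS),
        "call_incoming_count": (CALL_RATE_MEAN - 1.0) / AGG_DAYS,
        "call_outgoing_count": (CALL_RATE_MEAN - 1.0) / AGG_DAYS,
    }
    for item, (_, _, n_p, _) in EMA_PARAMS.items():
        out[f"ema_{item}"] = EMA_PROMPT_SD**2 / (n_p * AGG_DAYS)
    return out


#: feature name -> (natural-scale mean, between-person SD, day-noise var of 14-day mean)
INJECTABLE: dict[str, tuple[float, float, float]] = {}
for _name, _v in _day_noise_var().items():
    if _name.startswith("ema_"):
        _m, _s, _, _ = EMA_PARAMS[_name[4:]]
    elif _name == "screen_duration_mean":
        _m, _s = SCREEN_MU_MEAN, SCREEN_MU_SD
    elif _name == "screen_episode_count":
        _m, _s = SCREEN_K_MEAN, SCREEN_K_SD
    elif _name == "screen_duration_sum":
        _m, _s = SCREEN_K_MEAN * SCREEN_MU_MEAN, 0.9
    elif _name.endswith("duration_mean"):
        _m, _s = CALL_MU_MEAN, CALL_MU_SD
    else:  # call counts
        _m, _s = CALL_RATE_MEAN, CALL_RATE_SD
    INJECTABLE[_name] = (_m, _s, _v)

#: study-condition defaults: the strongest reported feature-severity signals
DEFAULT_EFFECT_MAP: dict[str, float] = {
    "ema_valence": -0.55,
    "ema_social_quality": -0.51,
    "ema_sleep": -0.50,
    "ema_arousal": -0.42,
    "ema_social_quantity": -0.39,
    "ema_nutrition": -0.25,
    "ema_stress": 0.42,
    "screen_duration_mean": 0.37,
    "call_outgoing_duration_mean": 0.25,
    "call_incoming_duration_mean": 0.21,
}

SENSOR_NAMES = ("screen", "app", "calls", "gps", "ema")


def calibrate_loading(target_r: float, feature: str, mood_var: float = 0.0) -> tuple[float, float, float]:
    """Decompose a generating parameter's unit variance for a target correlation.

    Returns (b, gamma, delta): severity loading, shared-mood loading and
    unique loading such that b^2 + gamma^2 + delta^2 + c2/s2 = 1 and the
    induced feature-vs-PHQ-8 correlation equals ``target_r``.
    """
    m, s, c2 = INJECTABLE[feature]
    b = target_r / PHQ_ATTENUATION
    q = c2 / s**2
    if abs(b) > 0.95:
        raise ValueError(f"target correlation {target_r} for {feature} infeasible after attenuation")
    g2 = min(mood_var, max(0.0, 1.0 - b**2 - q - 0.1))
    d2 = 1.0 - b**2 - g2 - q
    if d2 < 0:
        raise ValueError(f"target correlation {target_r} for {feature} infeasible given day-level noise")
    return b, float(np.sqrt(g2)), float(np.sqrt(d2))


class CohortConfig(BaseModel):
    """Study-design parameters of a synthetic cohort.

    Defaults emulate the observed study conditions: a right-skewed
    subclinical severity distribution (PHQ-8 mean ~5.8, SD ~4.4), 14-day
    episodes, and between-person feature-severity correlations at the
    reported magnitudes.
    """

    model_config = ConfigDict(frozen=True)

    n_participants: int = Field(gt=0)
    days_per_participant: int = Field(default=14, ge=14)
    episodes_per_participant: int = Field(default=1, ge=1)
    seed: int = 0
    effect_map: dict[str, float] = Field(default_factory=lambda: dict(DEFAULT_EFFECT_MAP))
    missing_rate_day: float = Field(default=0.0, ge=0.0, le=1.0)
    missing_rate_ema: float = Field(default=0.0, ge=0.0, le=1.0)
    dropout_mnar_slope: float = 0.0
    sensors: tuple[str, ...] = SENSOR_NAMES

    @property
    def total_days(self) -> int:
        return max(self.days_per_participant, 14 * self.episodes_per_participant)

    @model_validator(mode="after")
    def _check(self) -> "CohortConfig":
        unknown_sensors = set(self.sensors) - set(SENSOR_NAMES)
        if unknown_sensors:
            raise ValueError(f"unknown sensors: {sorted(unknown_sensors)}")
        for name, r in self.effect_map.items():
            if name not in FEATURES:
                raise ValueError(f"unknown feature name in effect_map: {name!r}")
            if name not in INJECTABLE:
                raise ValueError(f"correlation injection is not supported for feature {name!r}")
            if abs(r) > 0.95:
                raise ValueError(f"|target correlation| for {name} exceeds 0.95")
            calibrate_loading(r, name, EMA_MOOD_VAR if name.startswith("ema_") else 0.0)
        if "screen_duration_sum" in self.effect_map and (
            "screen_duration_mean" in self.effect_map or "screen_episode_count" in self.effect_map
        ):
            raise ValueError("screen_duration_sum cannot be injected together with its factors")
        return self
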