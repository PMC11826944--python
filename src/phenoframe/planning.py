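"""Study-planning utilities: effect-size conversion and sample size for
detecting a Pearson correlation under a bivariate normal model.

The power model is the Fisher z approximation with the small-sample bias
term r/(2(n-1)): under a true correlation rho, atanh(r) is approximately
normal with mean atanh(rho) + rho/(2(n-1)) and variance 1/(n-3).
"""

from __future__ import annotations

import numpy as np
from pydantic import BaseModel, ConfigDict, Field
from scipy import stats

N_MAX = 10**6


class PowerQuery(BaseModel):
    """A required-sample-size query for the test of zero correlation."""

    model_config = ConfigDict(frozen=True)

    target_r: float = Field(gt=0.0, lt=1.0)
    power: float = Field(default=0.8, gt=0.0, lt=1.0)
    alpha: float = Field(default=0.05, gt=0.0, lt=1.0)
    sides: int = Field(default=2, ge=1, le=2)


def smd_to_r(d: float) -> float:
    """Standardized mean difference to point-biserial r: r = d / sqrt(d^2 + 4).

    Odd in d, with |r| < 1; assumes equal group sizes.
    """
    if not np.isfinite(d):
        raise ValueError("d must be finite")
    return float(d / np.sqrt(d * d + 4.0))


def r_to_smd(r: float) -> float:
    """Inverse conversion: d = 2 r / sqrt(1 - r^2)."""
    if not (-1.0 < r < 1.0):
        raise ValueError("r must lie in (-1, 1)")
    return float(2.0 * r / np.sqrt(1.0 - r * r))


def correlation_power(n: int, r: float, alpha: float = 0.05, sides: int = 2) -> float:
    """Power of the n-sample test of rho = 0 against true correlation r."""
    if n < 4:
        return 0.0
    z_crit = stats.norm.ppf(1.0 - alpha / sides)
    mu = (np.arctanh(r) + r / (2.0 * (n - 1.0))) * np.sqrt(n - 3.0)
    power = float(stats.norm.cdf(mu - z_crit))
    if sides == 2:
        power += float(stats.norm.cdf(-mu - z_crit))
    return power


def required_n_correlation(query: PowerQuery) -> int:
    """Smallest n at which the test of zero correlation reaches the power.

    Deterministic: a closed-form initial guess is refined by a local scan
    (power is monotone in n under the Fisher z model).
    """
    r, power, alpha, sides = query.target_r, query.power, query.alpha, query.sides
    z_a = stats.norm.ppf(1.0 - alpha / sides)
    z_b = stats.norm.ppf(power)
    guess = int(((z_a + z_b) / np.arctanh(r)) ** 2 + 3)
    n = max(4, guess - 10)
    while correlation_power(n, r, alpha, sides) < power:
        n += 1
        if n > N_MAX:
            raise ValueError(f"target power unreachable below n = {N_MAX}")
    while n > 4 and correlation_power(n - 1, r, alpha, sides) >= power:
        n -= 1
    return n
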