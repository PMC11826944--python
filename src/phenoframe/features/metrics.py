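"""Scalar behavioral metrics shared by all feature clusters.

Entropies are reported in nats; the normalized form divides by ``ln(N)``
and is therefore base-invariant. The regularity index is the mean, over
all unordered day pairs, of the fraction of the 24 hours whose dominant
behavioral state agrees between the two days.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0


def shannon_entropy(frequencies) -> float:
    """Shannon entropy (nats) of a non-negative frequency vector.

    Frequencies are normalized to probabilities internally; zero entries
    contribute nothing. Raises ``ValueError`` if all frequencies are zero
    or any is negative.
    """
    f = np.asarray(frequencies, dtype=float)
    if f.size == 0 or np.any(f < 0):
        raise ValueError("frequencies must be a non-empty vector of non-negative reals")
    total = f.sum()
    if total <= 0:
        raise ValueError("entropy undefined for an all-zero frequency vector")
    p = f[f > 0] / total
    return float(-(p * np.log(p)).sum())


def normalized_entropy(frequencies) -> float:
    """Entropy divided by ``ln(N)`` where N is the number of states.

    Returns NaN when fewer than two states are present (the normalizer
    is then zero and the quantity is undefined).
    """
    f = np.asarray(frequencies, dtype=float)
    n_states = f.size
    if n_states < 2:
        return float("nan")
    return shannon_entropy(f) / np.log(n_states)


def regularity_index(hourly_states) -> float:
    """Similarity of behavior between the same hours across different days.

    Parameters
    ----------
    hourly_states : array-like, shape (n_days, 24)
        Dominant behavioral state per hour and day. States may be any
        hashable/encodable values; NaN is treated as its own state.

    Returns
    -------
    float
        Mean over all unordered day pairs of the fraction of hours whose
        dominant state agrees; in [0, 1]. NaN with fewer than 2 days.
    """
    m = np.asarray(hourly_states)
    if m.ndim != 2:
        raise ValueError("expected a days x hours matrix")
    n_days = m.shape[0]
    if n_days < 2:
        return float("nan")
    # encode to integers so NaN compares equal to NaN
    _, codes = np.unique(m.astype(object).astype(str), return_inverse=True)
    codes = codes.reshape(m.shape)
    agree = []
    for i in range(n_days):
        for j in range(i + 1, n_days):
            agree.append(np.mean(codes[i] == codes[j]))
    return float(np.mean(agree))


def haversine_km(p1, p2) -> float:
    """Great-circle distance in km between (lat, lon) points, R=6371 km."""
    lat1, lon1 = p1
    lat2, lon2 = p2
    for lat, lon in ((lat1, lon1), (lat2, lon2)):
        if not (-90.0 <= lat <= 90.0) or not (-180.0 <= lon <= 180.0):
            raise ValueError(f"invalid coordinate ({lat}, {lon})")
    return float(_haversine_km_arrays(np.array([lat1]), np.array([lon1]), np.array([lat2]), np.array([lon2]))[0])


def _haversine_km_arrays(lat1, lon1, lat2, lon2):
    """Vectorized haversine on arrays of degrees."""
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlam = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2.0) ** 2
    a = np.clip(a, 0.0, 1.0)
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))
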