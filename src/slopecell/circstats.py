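"""Minimal circular statistics: resultants, Rayleigh, Watson-Williams.

Angles are radians internally; public helpers that take degrees say so.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = [
    "resultant_length", "circmean_deg", "rayleigh_test",
    "watson_williams_test", "vonmises_kappa",
]


def resultant_length(angles_rad: np.ndarray) -> float:
    a = np.asarray(angles_rad, dtype=float)
    return float(np.abs(np.exp(1j * a).mean()))


def circmean_deg(angles_deg: np.ndarray) -> float:
    """Circular mean of angles in degrees, returned in [0, 360)."""
    a = np.deg2rad(np.asarray(angles_deg, dtype=float))
    m = np.angle(np.exp(1j * a).mean())
    return float(np.rad2deg(m) % 360.0)


def rayleigh_test(angles_deg: np.ndarray) -> tuple[float, float]:
    """Rayleigh test of circular uniformity.

    Returns (Z, p) where Z = n * Rbar^2 and p uses the standard
    finite-sample correction (Zar).  Requires n >= 3.
    """
    a = np.deg2rad(np.asarray(angles_deg, dtype=float))
    n = a.size
    if n < 3:
        raise ValueError("rayleigh_test needs at least 3 angles")
    rbar = resultant_length(a)
    z = n * rbar**2
    p = np.exp(-z) * (
        1.0
        + (2.0 * z - z**2) / (4.0 * n)
        - (24.0 * z - 132.0 * z**2 + 76.0 * z**3 - 9.0 * z**4) / (288.0 * n**2)
    )
    return float(z), float(min(max(p, 0.0), 1.0))


def vonmises_kappa(rbar: float, n: int | None = None) -> float:
    """Estimate the von Mises concentration from a mean resultant length.

    Best & Fisher approximation with the optional small-sample
    correction of Fisher (1993).
    """
    rbar = float(rbar)
    if rbar < 0.53:
        kappa = 2 * rbar + rbar**3 + 5 * rbar**5 / 6
    elif rbar < 0.85:
        kappa = -0.4 + 1.39 * rbar + 0.43 / (1 - rbar)
    else:
        kappa = 1.0 / (rbar**3 - 4 * rbar**2 + 3 * rbar)
    if n is not None and n < 16 and kappa > 0:
        if kappa < 2:
            kappa = max(kappa - 2.0 / (n * kappa), 0.0)
        else:
            kappa = kappa * (n - 1) ** 3 / (n**3 + n)
    return float(kappa)


def watson_williams_test(
    groups_deg: list[np.ndarray],
) -> tuple[float, float, bool]:
    """Watson-Williams test for equality of group circular means.

    Returns (F, p, assumptions_ok).  ``assumptions_ok`` is False when the
    pooled concentration is too low (kappa < 1, i.e. pooled Rbar below
    about 0.45) for the F approximation to be trustworthy; the statistic
    is still returned.
    """
    groups = [np.deg2rad(np.asarray(g, dtype=float)) for g in groups_deg]
    k = len(groups)
    if k < 2 or any(g.size < 5 for g in groups):
        raise ValueError("watson_williams_test needs >= 2 groups of >= 5 angles")
    n = sum(g.size for g in groups)
    Rs = [g.size * resultant_length(g) for g in groups]
    pooled = np.concatenate(groups)
    R = n * resultant_length(pooled)
    rw = sum(Rs) / n
    kappa = vonmises_kappa(rw)
    assumptions_ok = kappa >= 1.0
    correction = 1.0 + 3.0 / (8.0 * kappa) if kappa > 0 else 1.0
    num = (sum(Rs) - R) / (k - 1)
    den = (n - sum(Rs)) / (n - k)
    if den <= 0:
        return float("inf"), 0.0, assumptions_ok
    F = correction * num / den
    p = float(stats.f.sf(F, k - 1, n - k))
    return float(F), p, assumptions_ok
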