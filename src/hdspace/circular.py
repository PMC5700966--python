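"""Circular-statistics primitives shared across modules.

Angles are radians in [0, 2*pi), 0 along +x ("East"), counter-clockwise
positive. Degrees appear only at file boundaries.
"""
from __future__ import annotations

import numpy as np

TWO_PI = 2.0 * np.pi


def wrap_angle(a):
    """Wrap angle(s) to [0, 2*pi)."""
    return np.mod(a, TWO_PI)


def wrap_pi(a):
    """Wrap angle(s) to (-pi, pi]."""
    return np.pi - np.mod(np.pi - np.asarray(a), TWO_PI)


def resultant(angles, weights=None):
    """Weighted circular resultant.

    Parameters
    ----------
    angles : array-like of radians
    weights : optional non-negative weights (e.g. per-bin firing rates)

    Returns
    -------
    (length, direction) : length in [0, 1] (normalized by the total weight),
        direction in [0, 2*pi). For zero total weight both are ``nan``; for a
        zero-length resultant the direction is ``nan``.
    """
    angles = np.asarray(angles, dtype=float)
    if weights is None:
        weights = np.ones_like(angles)
    weights = np.asarray(weights, dtype=float)
    total = weights.sum()
    if not np.isfinite(total) or total <= 0:
        return np.nan, np.nan
    c = float(np.sum(weights * np.cos(angles)))
    s = float(np.sum(weights * np.sin(angles)))
    length = np.hypot(c, s) / total
    if length < 1e-15:
        return 0.0, np.nan
    return length, float(wrap_angle(np.arctan2(s, c)))


def kappa_from_resultant(r, cap=None):
    """Invert the von Mises mean resultant length A(kappa) = I1(k)/I0(k).

    Uses the standard piecewise approximation (Fisher, *Statistical Analysis
    of Circular Data*, 1993). ``r`` outside (0, 1) maps to 0 / +inf (or
    ``cap`` if given).
    """
    r = float(r)
    if not np.isfinite(r) or r <= 0:
        return 0.0
    if r >= 1.0 - 1e-12:  # A(kappa) inversion diverges at r = 1
        return np.inf if cap is None else float(cap)
    if r < 0.53:
        k = 2.0 * r + r**3 + 5.0 * r**5 / 6.0
    elif r < 0.85:
        k = -0.4 + 1.39 * r + 0.43 / (1.0 - r)
    else:
        k = 1.0 / (r**3 - 4.0 * r**2 + 3.0 * r)
    if cap is not None:
        k = min(k, float(cap))
    return float(k)
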