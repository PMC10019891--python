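"""Circular helpers for the 180°-periodic orientation space.

Orientations live on a half-circle: a grating at 170° is 20° away from one
at 10°. Signed differences are mapped to [-90, 90) and absolute distances
to [0, 90].
"""

from __future__ import annotations

import numpy as np

ORIENTATION_PERIOD = 180.0


def wrap_orientation(theta):
    """Wrap angles into [0, 180)."""
    return np.asarray(theta, dtype=float) % ORIENTATION_PERIOD


def signed_orientation_diff(a, b):
    """Signed circular difference a - b in degrees, mapped to [-90, 90)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("orientation inputs must be finite")
    half = ORIENTATION_PERIOD / 2.0
    return (a - b + half) % ORIENTATION_PERIOD - half


def orientation_distance(a, b):
    """Absolute circular orientation distance in degrees, in [0, 90]."""
    return np.abs(signed_orientation_diff(a, b))
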