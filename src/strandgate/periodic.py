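"""Angle arithmetic on the periodic domain (-180, 180] degrees."""

from __future__ import annotations

import numpy as np


def wrap_angle(angle_deg):
    """Wrap angle(s) onto (-180, 180] degrees."""
    wrapped = np.mod(np.asarray(angle_deg, dtype=float) + 180.0, 360.0) - 180.0
    # mod maps 180 -> -180; put the boundary on +180 instead
    wrapped = np.where(wrapped == -180.0, 180.0, wrapped)
    if np.ndim(angle_deg) == 0:
        return float(wrapped)
    return wrapped


def periodic_delta(a_deg, b_deg):
    """Minimal-image difference a - b on the circle, in (-180, 180]."""
    return wrap_angle(np.asarray(a_deg, dtype=float) - np.asarray(b_deg, dtype=float))


def in_circular_range(angle_deg, lo_deg: float, hi_deg: float):
    """Membership of angle(s) in the arc travelled from ``lo`` to ``hi``
    in the direction of increasing angle (wrapping through 180/-180)."""
    span = np.mod(hi_deg - lo_deg, 360.0)
    rel = np.mod(np.asarray(angle_deg, dtype=float) - lo_deg, 360.0)
    result = rel <= span
    if np.ndim(angle_deg) == 0:
        return bool(result)
    return result
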