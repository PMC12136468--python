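"""Circular (angular) arithmetic helpers.

Angles are degrees everywhere in the public API; conversion to radians happens
only where a trigonometric kernel is evaluated. Signed differences live in
(-180, 180], absolute positions in [0, 360).
"""

from __future__ import annotations

import numpy as np

DEG2RAD = np.pi / 180.0
RAD2DEG = 180.0 / np.pi


def wrap_360(angle_deg):
    """Wrap angle(s) into [0, 360)."""
    return np.asarray(angle_deg) % 360.0


def wrap_180(angle_deg):
    """Wrap signed angular difference(s) into (-180, 180]."""
    a = np.asarray(angle_deg, dtype=float)
    return -((-a + 180.0) % 360.0 - 180.0)


def circ_diff(a_deg, b_deg):
    """Signed circular difference a - b in (-180, 180]."""
    return wrap_180(np.asarray(a_deg, dtype=float) - np.asarray(b_deg, dtype=float))


def circ_mean(angles_deg, axis=None):
    """Circular mean in [0, 360)."""
    a = np.asarray(angles_deg, dtype=float) * DEG2RAD
    m = np.angle(np.exp(1j * a).mean(axis=axis)) * RAD2DEG
    return np.asarray(m) % 360.0


def unwrap_about_mean(angles_deg):
    """Represent angles as signed offsets from their circular mean.

    Returns (mean_deg, offsets_deg) with offsets in (-180, 180]. Valid when the
    sample is concentrated (offsets well away from +-180).
    """
    m = float(circ_mean(angles_deg))
    return m, circ_diff(angles_deg, m)


def nearest_common_color(colors_deg, common_colors_deg):
    """For each color, the common color minimizing |circular distance|."""
    c = np.atleast_1d(np.asarray(colors_deg, dtype=float))
    cc = np.asarray(common_colors_deg, dtype=float)
    d = np.abs(circ_diff(c[:, None], cc[None, :]))
    idx = np.argmin(d, axis=1)
    out = cc[idx]
    if np.isscalar(colors_deg) or np.ndim(colors_deg) == 0:
        return float(out[0])
    return out
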