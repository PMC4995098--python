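"""Axial-angle arithmetic shared by shape descriptors and radial statistics.

Conventions used throughout the package:

* image coordinates are 0-based ``(row, col)`` with rows increasing downward;
* orientations of elongated structures are *axial* angles in degrees in
  ``[0, 180)``, measured from the +column axis (an ellipse at 30 deg and one
  at 210 deg are the same object);
* full (directional) angles, where needed, are ``atan2(d_row, d_col)`` in
  degrees wrapped to ``(-180, 180]``.
"""

from __future__ import annotations

import numpy as np


def axial_angle_deg(d_row, d_col):
    """Axial angle of vector(s) ``(d_row, d_col)`` in degrees in [0, 180)."""
    a = np.degrees(np.arctan2(d_row, d_col)) % 180.0
    # tiny negative angles round to exactly 180.0 under the modulo
    return np.where(a >= 180.0, 0.0, a)


def full_angle_deg(d_row, d_col):
    """Directional angle of vector(s) in degrees in (-180, 180]."""
    return np.degrees(np.arctan2(d_row, d_col))


def axial_difference_deg(a, b):
    """Unsigned difference between two axial angles, folded into [0, 90].

    Both arguments are in degrees; the result is the acute angle between the
    two undirected axes.
    """
    d = np.abs(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % 180.0
    return np.where(d > 90.0, 180.0 - d, d)


def wrap_signed_deg(angle):
    """Wrap a directional angle difference into (-180, 180]."""
    a = (np.asarray(angle, dtype=float) + 180.0) % 360.0 - 180.0
    return np.where(a == -180.0, 180.0, a)


def circular_mean_deg(angles_deg):
    """Circular mean of directional angles (degrees in (-180, 180])."""
    ang = np.radians(np.asarray(angles_deg, dtype=float))
    return float(np.degrees(np.angle(np.mean(np.exp(1j * ang)))))
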