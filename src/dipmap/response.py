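"""Intensity-response (Naka-Rushton) fitting and derived quantities.

The response amplitude of a cortical activation as a function of stimulus
intensity c (luminance in cd/m^2 or current in uA) is modeled by the
Naka-Rushton law

    R(c) = Rmax * c^n / (c^n + C50^n)

with semi-saturation constant C50 and exponent n. Two derived quantities:

* the 10-90% operational range, C50 * (9^(1/n) - 9^(-1/n)), the intensity
  span over which the response rises from 10% to 90% of Rmax;
* the equivalent intensity of an observed amplitude, the inverse function
  c = C50 * (R / (Rmax - R))^(1/n), used to express prosthetic response
  amplitudes as equivalent visual luminances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .synthetic import naka_rushton


class FitError(RuntimeError):
    """Raised when the bounded multi-start optimization fails to converge."""


class SaturatedResponseError(ValueError):
    """Raised when an amplitude at or above Rmax has no finite inverse."""


@dataclass
class NakaRushtonFit:
    rmax: float
    c50: float
    n: float
    baseline: float = 0.0
    residual_ss: float = np.nan
    n_points: int = 0

    def predict(self, c):
        return self.baseline + naka_rushton(c, self.rmax, self.c50, self.n)


def fit_naka_rushton(intensity, amplitude,
                     with_baseline: bool = False) -> NakaRushtonFit:
    """Bounded multi-start least-squares fit of the Naka-Rushton law.

    ``amplitude`` should be the positive response magnitude (callers pass
    |dip|). Starts combine C50 at the 25/50/75th intensity percentiles with
    exponents {1, 2, 4}; the best converged start by SSE wins.
    """
    c = np.asarray(intensity, dtype=float)
    r = np.asarray(amplitude, dtype=float)
    if c.size != r.size or c.size < 4:
        raise ValueError("need >= 4 (intensity, amplitude) points")
    if np.any(c < 0):
        raise ValueError("intensities must be non-negative")

    rmax0 = max(float(r.max()), 1e-12)
    pos = c[c > 0]
    c50_starts = np.percentile(pos, [25, 50, 75])
    scale = float(pos.max())

    def resid(p):
        rmax, c50, n = p[:3]
        base = p[3] if with_baseline else 0.0
        return base + naka_rushton(c, rmax, c50, n) - r

    lower = [1e-12, 1e-9 * scale, 1e-3]
    upper = [10 * rmax0 + 1e-9, 100 * scale, 50.0]
    if with_baseline:
        lower.append(-rmax0)
        upper.append(rmax0)

    best = None
    for c50_0 in c50_starts:
        for n0 in (1.0, 2.0, 4.0):
            p0 = [rmax0, float(c50_0), n0] + ([0.0] if with_baseline else [])
            try:
                sol = least_squares(resid, p0, bounds=(lower, upper))
            except ValueError:
                continue
            if not sol.success:
                continue
            sse = float(2 * sol.cost)
            if best is None or sse < best[0]:
                best = (sse, sol.x)
    if best is None:
        raise FitError(
            f"Naka-Rushton fit did not converge (n={c.size}, "
            f"intensity span {c.min():g}-{c.max():g})")
    sse, p = best
    return NakaRushtonFit(rmax=float(p[0]), c50=float(p[1]), n=float(p[2]),
                          baseline=float(p[3]) if with_baseline else 0.0,
                          residual_ss=sse, n_points=int(c.size))


def operational_range(fit: NakaRushtonFit) -> float:
    """10-90% operational range: C50 * (9^(1/n) - 9^(-1/n))."""
    return float(fit.c50 * (9.0 ** (1.0 / fit.n) - 9.0 ** (-1.0 / fit.n)))


def equivalent_intensity(fit: NakaRushtonFit, amplitude: float) -> float:
    """Inverse of the fitted law: the intensity producing ``amplitude``.

    Amplitudes at or above Rmax are saturated and raise
    :class:`SaturatedResponseError`.
    """
    a = amplitude - fit.baseline
    if a <= 0:
        raise ValueError("amplitude must exceed the baseline")
    if a >= fit.rmax:
        raise SaturatedResponseError(
            f"amplitude {amplitude:g} >= Rmax {fit.rmax:g}: saturated")
    return float(fit.c50 * (a / (fit.rmax - a)) ** (1.0 / fit.n))
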