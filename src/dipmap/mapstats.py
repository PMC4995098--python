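"""Position, size and shape descriptors of cortical activations.

Coordinates are 0-based ``(row, col)`` pixels, rows increasing downward;
conversion to millimetres is via the acquisition pixel pitch. Orientations
are axial degrees in [0, 180) measured from the +column axis (see
:mod:`dipmap.geometry`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .geometry import axial_angle_deg
from .preprocess import ActivationRegion, ZScoreMap

__all__ = [
    "ActivationRegion", "EquivalentEllipse", "PolarMaps", "PositionMetrics",
    "center_of_mass", "equivalent_ellipse", "build_polar_maps",
    "expected_cortical_position", "positional_error", "fit_magnification",
    "fit_size_tuning", "visual_to_cortical_distance",
    "LinearFit", "SizeTuningFit",
]


@dataclass
class EquivalentEllipse:
    """Ellipse with the same normalized second central moments as a mask.

    Axis lengths and the equivalent diameter (diameter of the circle of equal
    area) are in mm; ``orientation`` is the axial angle of the major axis.
    """

    geometric_center: tuple[float, float]   # (row, col) pixels
    major_axis_len: float                   # mm
    minor_axis_len: float                   # mm
    orientation: float                      # axial degrees [0, 180)
    equivalent_diameter: float              # mm
    aspect_ratio: float                     # major / minor, >= 1
    area_px: int
    degenerate: bool = False


@dataclass
class PolarMaps:
    """Per-pixel preferred stimulus position (retinotopic polar maps)."""

    azimuth_pref: np.ndarray      # deg, NaN where unresponsive
    elevation_pref: np.ndarray    # deg
    response_strength: np.ndarray # peak rectified response (|z| units)
    pixel_pitch: float


@dataclass
class PositionMetrics:
    center_of_mass: tuple[float, float]     # (row, col) pixels
    center_of_mass_mm: tuple[float, float]
    expected_position_mm: tuple[float, float]
    error_mm: float
    error_deg_eq: float


def center_of_mass(zmap: ZScoreMap, region: ActivationRegion
                   ) -> Optional[tuple[float, float]]:
    """|z|-weighted centroid of the (unsmoothed) z map over the region.

    Returns ``None`` for an empty region — an explicit no-activation result.
    """
    if region.is_empty:
        return None
    rr, cc = np.nonzero(region.mask)
    w = np.abs(zmap.values[rr, cc])
    w = np.where(np.isfinite(w), w, 0.0)
    if w.sum() == 0:
        return float(rr.mean()), float(cc.mean())
    return float(np.average(rr, weights=w)), float(np.average(cc, weights=w))


def _mask_second_moments(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centroid and central second-moment matrix of a binary mask.

    Each pixel is treated as a unit square, contributing 1/12 to each
    diagonal moment, so that a solid w x h rectangle has exactly the
    continuous moments (w^2/12, h^2/12).
    """
    rr, cc = np.nonzero(mask)
    centroid = np.array([rr.mean(), cc.mean()])
    dr = rr - centroid[0]
    dc = cc - centroid[1]
    n = rr.size
    m_rr = (dr @ dr) / n + 1.0 / 12.0
    m_cc = (dc @ dc) / n + 1.0 / 12.0
    m_rc = (dr @ dc) / n
    return centroid, np.array([[m_rr, m_rc], [m_rc, m_cc]])


def equivalent_ellipse(region: ActivationRegion,
                       pixel_pitch: Optional[float] = None) -> EquivalentEllipse:
    """Equivalent ellipse of the activation mask.

    Axis lengths are ``4 sqrt(eigenvalue)`` of the second-moment matrix (the
    relation that makes a disc of radius r return axes 2r). A degenerate
    (collinear) mask gets a minor-axis floor of one pixel and is flagged.
    """
    if pixel_pitch is None:
        pixel_pitch = region.pixel_pitch
    if region.area_px < 3:
        raise ValueError("region must contain at least 3 pixels")
    centroid, m = _mask_second_moments(region.mask)
    evals, evecs = np.linalg.eigh(m)          # ascending
    lam_minor, lam_major = float(evals[0]), float(evals[1])
    v = evecs[:, 1]                           # (row, col) of major axis
    orientation = float(axial_angle_deg(v[0], v[1]))
    major = 4.0 * np.sqrt(lam_major)
    minor = 4.0 * np.sqrt(lam_minor)
    # collinear mask: all spread comes from the 1/12 unit-pixel term
    degenerate = lam_minor <= 1.0 / 12.0 + 1e-12
    if degenerate:
        minor = 1.0
        warnings.warn("degenerate (nearly collinear) region; "
                      "minor axis floored at 1 pixel", stacklevel=2)
    area = region.area_px
    eq_diam = 2.0 * np.sqrt(area / np.pi)
    return EquivalentEllipse(
        geometric_center=(float(centroid[0]), float(centroid[1])),
        major_axis_len=major * pixel_pitch,
        minor_axis_len=minor * pixel_pitch,
        orientation=orientation,
        equivalent_diameter=eq_diam * pixel_pitch,
        aspect_ratio=major / minor,
        area_px=area,
        degenerate=degenerate,
    )


def build_polar_maps(zmaps: Sequence[ZScoreMap],
                     positions_deg: Sequence[tuple[float, float]],
                     response_floor: float = 3.09) -> PolarMaps:
    """Retinotopic polar maps from one z map per stimulus grid position.

    Per pixel, the response to each position is the rectified activation
    ``max(-z, 0)``; the preferred azimuth/elevation is the response-weighted
    centroid of the stimulus positions (the pixel's visual center-of-mass),
    and the strength is the peak response. Pixels with zero total response
    are masked to NaN.

    Rectified responses below ``response_floor`` (|z| units; default the
    significance threshold magnitude) are zeroed before the centroid:
    otherwise rectified noise at the non-preferred positions biases every
    preference toward the grid centroid.
    """
    if len(zmaps) != len(positions_deg) or not zmaps:
        raise ValueError("need one z map per grid position")
    resp = np.stack([np.clip(-m.values, 0.0, None) for m in zmaps])
    resp = np.where(np.isfinite(resp), resp, 0.0)
    resp = np.where(resp >= response_floor, resp, 0.0)
    pos = np.asarray(positions_deg, dtype=float)    # k x 2 (az, el)
    total = resp.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        az = np.tensordot(pos[:, 0], resp, axes=1) / total
        el = np.tensordot(pos[:, 1], resp, axes=1) / total
    dead = total <= 0
    az[dead] = np.nan
    el[dead] = np.nan
    return PolarMaps(azimuth_pref=az, elevation_pref=el,
                     response_strength=resp.max(axis=0),
                     pixel_pitch=zmaps[0].pixel_pitch)


def expected_cortical_position(pm: PolarMaps,
                               visual_pos: tuple[float, float],
                               min_strength_frac: float = 0.25
                               ) -> tuple[int, int]:
    """Pixel whose (azimuth, elevation) preference is nearest ``visual_pos``
    (the intersection of the two cardinal polar maps).

    Only responsive pixels compete: those whose response strength reaches
    ``min_strength_frac`` of the map's peak strength, which excludes isolated
    noise pixels that happen to carry a valid preference.
    """
    az, el = visual_pos
    ok = np.isfinite(pm.azimuth_pref) & np.isfinite(pm.elevation_pref)
    ok &= pm.response_strength >= min_strength_frac * \
        float(np.nanmax(pm.response_strength))
    if not ok.any():
        raise ValueError("no responsive pixels in the polar maps")
    lo_az, hi_az = np.nanmin(pm.azimuth_pref), np.nanmax(pm.azimuth_pref)
    lo_el, hi_el = np.nanmin(pm.elevation_pref), np.nanmax(pm.elevation_pref)
    if not (lo_az <= az <= hi_az and lo_el <= el <= hi_el):
        raise ValueError(f"visual position {visual_pos} outside mapped span")
    d2 = (pm.azimuth_pref - az) ** 2 + (pm.elevation_pref - el) ** 2
    d2 = np.where(ok, d2, np.inf)
    flat = int(np.argmin(d2))                 # row-major: deterministic ties
    return np.unravel_index(flat, d2.shape)


def positional_error(expected_mm: tuple[float, float],
                     com_mm: tuple[float, float],
                     magnification: float,
                     com_px: tuple[float, float] | None = None
                     ) -> PositionMetrics:
    """Euclidean distance between expected and observed centers, in mm and in
    equivalent degrees of visual angle (mm / magnification)."""
    if magnification <= 0:
        raise ValueError("magnification must be positive")
    e = np.asarray(expected_mm, dtype=float)
    c = np.asarray(com_mm, dtype=float)
    d = float(np.hypot(*(e - c)))
    return PositionMetrics(
        center_of_mass=tuple(com_px) if com_px is not None else (np.nan, np.nan),
        center_of_mass_mm=(float(c[0]), float(c[1])),
        expected_position_mm=(float(e[0]), float(e[1])),
        error_mm=d,
        error_deg_eq=d / magnification,
    )


@dataclass
class LinearFit:
    slope: float
    intercept: float
    r_value: float
    stderr: float
    n: int

    def predict(self, x):
        return self.slope * np.asarray(x, dtype=float) + self.intercept


def fit_magnification(pairs: Sequence[tuple[float, float]],
                      fit_intercept: bool = True) -> LinearFit:
    """Least-squares slope of cortical distance (mm) vs visual distance (deg).

    The slope is the retino-cortical magnification factor in mm/deg.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("need at least 2 (visual, cortical) pairs")
    x, y = arr[:, 0], arr[:, 1]
    if np.unique(x).size < 2:
        raise ValueError("degenerate abscissae: need >= 2 distinct distances")
    if fit_intercept:
        res = stats.linregress(x, y)
        return LinearFit(slope=float(res.slope), intercept=float(res.intercept),
                         r_value=float(res.rvalue), stderr=float(res.stderr),
                         n=len(x))
    slope = float((x @ y) / (x @ x))
    resid = y - slope * x
    dof = max(len(x) - 1, 1)
    stderr = float(np.sqrt((resid @ resid) / dof / (x @ x)))
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r = float(np.sqrt(max(0.0, 1.0 - (resid @ resid) / ss_tot))) if ss_tot else 1.0
    return LinearFit(slope=slope, intercept=0.0, r_value=r, stderr=stderr,
                     n=len(x))


@dataclass
class SizeTuningFit:
    """Linear relation between visual stimulus size (deg) and cortical
    activation extent (mm), with the inverse mapping back to degrees."""

    fit: LinearFit
    size_span: tuple[float, float]

    @property
    def slope(self) -> float:
        return self.fit.slope

    @property
    def intercept(self) -> float:
        return self.fit.intercept

    def extent_for_size(self, size_deg):
        return self.fit.predict(size_deg)

    def equivalent_visual_size(self, extent_mm: float) -> float:
        """Visual size (deg) whose fitted cortical extent equals ``extent_mm``.

        Warns when the answer extrapolates beyond twice the fitted size span.
        """
        size = (extent_mm - self.fit.intercept) / self.fit.slope
        lo, hi = self.size_span
        span = hi - lo
        if size < lo - span or size > hi + span:
            warnings.warn(
                f"equivalent size {size:.1f} deg extrapolates beyond 2x the "
                f"fitted span [{lo}, {hi}] deg", stacklevel=2)
        return float(size)


def fit_size_tuning(sizes_deg: Sequence[float],
                    extents_mm: Sequence[float]) -> SizeTuningFit:
    sizes = np.asarray(sizes_deg, dtype=float)
    if sizes.size < 2 or np.unique(sizes).size < 2:
        raise ValueError("need >= 2 distinct sizes")
    lf = fit_magnification(list(zip(sizes, extents_mm)), fit_intercept=True)
    return SizeTuningFit(fit=lf, size_span=(float(sizes.min()),
                                            float(sizes.max())))


def visual_to_cortical_distance(distance_deg: float,
                                magnification: float) -> float:
    """Cortical distance (mm) spanned by a visual distance, at a linear
    magnification factor (mm/deg)."""
    if magnification <= 0:
        raise ValueError("magnification must be positive")
    return float(distance_deg * magnification)
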