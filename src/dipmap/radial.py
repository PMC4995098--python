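"""Radial organization of elongated cortical activations.

If prosthetic activations recruit ganglion-cell axons en route to the optic
disk, the elongation axes of the evoked cortical activations should all point
toward the cortical representation of the disk. These statistics test that:

* the *optimal radial center* is the cortical position minimizing the median
  axial difference between each activation's orientation and the direction
  from the activation to that position (exhaustive grid search);
* a Monte-Carlo null re-runs the same optimization on sets whose orientations
  are replaced by i.i.d. uniform axial angles at the observed positions,
  giving the distribution of the minimized median deviation expected by
  chance;
* the observed deviation is compared to the null both empirically (fraction
  of null values at or below it) and through a Gaussian fit to the null;
* the center-of-mass offsets of the activations are expressed in a per-site
  frame whose 0 deg axis points toward the radial center (so +/-180 deg means
  displaced directly away from it);
* maps can be re-centered, rotated so their radial axis is horizontal with
  the radial center to the right, and averaged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .geometry import (axial_angle_deg, axial_difference_deg,
                       circular_mean_deg, full_angle_deg, wrap_signed_deg)


@dataclass
class ElongatedActivationSet:
    """Positions and axial orientations of elongated activations.

    ``centers`` are (row, col) in mm, ``orientations`` axial degrees in
    [0, 180); ``ar_values`` the aspect ratios used for inclusion (the
    assembly helper applies the AR >= 1.6 criterion); ``com_offsets`` the
    vectors from each geometric center to its center-of-mass (mm).
    """

    centers: np.ndarray
    orientations: np.ndarray
    ar_values: Optional[np.ndarray] = None
    com_offsets: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        self.orientations = np.asarray(self.orientations, dtype=float) % 180.0
        if len(self.centers) != len(self.orientations):
            raise ValueError("centers and orientations must have equal length")
        for name in ("ar_values", "com_offsets"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if len(v) != len(self.centers):
                    raise ValueError(f"{name} length mismatch")
                setattr(self, name, v)

    def __len__(self) -> int:
        return len(self.centers)

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame({
            "center_row_mm": self.centers[:, 0],
            "center_col_mm": self.centers[:, 1],
            "orientation_deg": self.orientations,
            "ar": self.ar_values if self.ar_values is not None
                  else np.full(len(self), np.nan),
            "com_dr": self.com_offsets[:, 0] if self.com_offsets is not None
                      else np.full(len(self), np.nan),
            "com_dc": self.com_offsets[:, 1] if self.com_offsets is not None
                      else np.full(len(self), np.nan),
        })
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ElongatedActivationSet":
        df = pd.read_csv(path)
        com = df[["com_dr", "com_dc"]].to_numpy()
        return cls(centers=df[["center_row_mm", "center_col_mm"]].to_numpy(),
                   orientations=df["orientation_deg"].to_numpy(),
                   ar_values=df["ar"].to_numpy(),
                   com_offsets=None if np.isnan(com).all() else com)


AR_INCLUSION_THRESHOLD = 1.6


def select_elongated(centers, orientations, ar_values, com_offsets=None,
                     ar_threshold: float = AR_INCLUSION_THRESHOLD
                     ) -> ElongatedActivationSet:
    """Keep only sufficiently elongated activations (AR >= threshold)."""
    ar = np.asarray(ar_values, dtype=float)
    keep = ar >= ar_threshold
    return ElongatedActivationSet(
        centers=np.asarray(centers, dtype=float)[keep],
        orientations=np.asarray(orientations, dtype=float)[keep],
        ar_values=ar[keep],
        com_offsets=None if com_offsets is None
        else np.asarray(com_offsets, dtype=float)[keep])


@dataclass
class RadialFitResult:
    optimal_center: tuple[float, float]
    median_deviation: float              # degrees in [0, 90]
    per_site_deviation: np.ndarray
    grid_shape: tuple[int, int] = (0, 0)


@dataclass
class MonteCarloNull:
    n_iter: int
    null_deviations: np.ndarray
    mean: float
    sd: float
    seed: Optional[int] = None


_EPS = 1e-9


def median_angular_deviation(aset: ElongatedActivationSet,
                             candidate: tuple[float, float]) -> float:
    """Median axial difference between site orientations and the directions
    from each site to ``candidate`` (degrees, in [0, 90]).

    Sites coincident with the candidate are skipped with a warning.
    """
    dev = _site_deviations(aset, candidate)
    return float(np.median(dev))


def _site_deviations(aset: ElongatedActivationSet,
                     candidate: tuple[float, float]) -> np.ndarray:
    d = np.asarray(candidate, dtype=float) - aset.centers
    dist = np.hypot(d[:, 0], d[:, 1])
    ok = dist > _EPS
    if not ok.all():
        warnings.warn("candidate coincides with a site center; site skipped",
                      stacklevel=2)
    if not ok.any():
        raise ValueError("candidate coincides with every site center")
    dirs = axial_angle_deg(d[ok, 0], d[ok, 1])
    return axial_difference_deg(aset.orientations[ok], dirs)


def _grid_points(aset: ElongatedActivationSet,
                 row_range: Optional[tuple[float, float]],
                 col_range: Optional[tuple[float, float]],
                 resolution: float):
    if row_range is None or col_range is None:
        r = aset.centers
        pad = 1.0  # mm beyond the bounding box of the sites
        row_range = row_range or (r[:, 0].min() - pad, r[:, 0].max() + pad)
        col_range = col_range or (r[:, 1].min() - pad, r[:, 1].max() + pad)
    rows = np.arange(row_range[0], row_range[1] + resolution / 2, resolution)
    cols = np.arange(col_range[0], col_range[1] + resolution / 2, resolution)
    return rows, cols


def _direction_matrix(rows: np.ndarray, cols: np.ndarray,
                      centers: np.ndarray) -> np.ndarray:
    """Axial direction (deg) from each site toward each grid point.

    Returns an array of shape (n_grid, n_sites), grid flattened row-major.
    """
    gr = np.repeat(rows, len(cols))
    gc = np.tile(cols, len(rows))
    dr = gr[:, None] - centers[None, :, 0]
    dc = gc[:, None] - centers[None, :, 1]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        dirs = axial_angle_deg(dr, dc)
    coincident = np.hypot(dr, dc) <= _EPS
    return np.where(coincident, np.nan, dirs)


def optimize_radial_center(aset: ElongatedActivationSet,
                           row_range: Optional[tuple[float, float]] = None,
                           col_range: Optional[tuple[float, float]] = None,
                           resolution: float = 0.1) -> RadialFitResult:
    """Exhaustive grid search for the position that minimizes the median
    angular deviation. Ties are broken by the first grid point in row-major
    order, making the result deterministic."""
    rows, cols = _grid_points(aset, row_range, col_range, resolution)
    dirs = _direction_matrix(rows, cols, aset.centers)
    dev = axial_difference_deg(aset.orientations[None, :], dirs)
    med = np.nanmedian(dev, axis=1)
    best = int(np.argmin(med))
    br, bc = divmod(best, len(cols))
    center = (float(rows[br]), float(cols[bc]))
    per_site = dev[best]
    return RadialFitResult(optimal_center=center,
                           median_deviation=float(med[best]),
                           per_site_deviation=per_site,
                           grid_shape=(len(rows), len(cols)))


def monte_carlo_null(aset: ElongatedActivationSet,
                     n_iter: int = 1000,
                     seed: int = 0,
                     row_range: Optional[tuple[float, float]] = None,
                     col_range: Optional[tuple[float, float]] = None,
                     resolution: float = 0.1,
                     chunk: int = 64) -> MonteCarloNull:
    """Null distribution of the optimized median deviation under uniform
    random axial orientations at the observed positions."""
    if n_iter < 100:
        raise ValueError("need at least 100 iterations")
    rng = np.random.default_rng(seed)
    rows, cols = _grid_points(aset, row_range, col_range, resolution)
    dirs = _direction_matrix(rows, cols, aset.centers)   # (G, n)
    out = np.empty(n_iter)
    done = 0
    while done < n_iter:
        m = min(chunk, n_iter - done)
        orient = rng.uniform(0.0, 180.0, size=(m, len(aset)))
        dev = axial_difference_deg(orient[:, None, :], dirs[None, :, :])
        med = np.nanmedian(dev, axis=2)                  # (m, G)
        out[done:done + m] = med.min(axis=1)
        done += m
    return MonteCarloNull(n_iter=n_iter, null_deviations=out,
                          mean=float(out.mean()), sd=float(out.std(ddof=1)),
                          seed=seed)


def gaussian_tail_p(observed: float, mean: float, sd: float
                    ) -> tuple[float, float]:
    """Lower Gaussian tail probability of ``observed`` and the z score
    (mean - observed)/sd, given the null moments."""
    if sd <= 0:
        raise ValueError("null standard deviation must be positive")
    z = (mean - observed) / sd
    return float(stats.norm.cdf(observed, loc=mean, scale=sd)), float(z)


def gaussian_p(null: MonteCarloNull, observed: float
               ) -> tuple[float, float, float]:
    """(empirical p, Gaussian p, z) of an observed median deviation.

    The empirical p is the fraction of null deviations at or below the
    observation (the area under the null to its left); the Gaussian p is the
    lower tail of a normal fit to the null.
    """
    p_gauss, z = gaussian_tail_p(observed, null.mean, null.sd)
    p_emp = float(np.mean(null.null_deviations <= observed))
    return p_emp, p_gauss, z


@dataclass
class ComDeviationResult:
    angles_deg: np.ndarray      # signed, (-180, 180]; 0 = toward the center
    circular_mean_deg: float
    n_used: int


def com_deviation_analysis(aset: ElongatedActivationSet,
                           radial_center: tuple[float, float]
                           ) -> ComDeviationResult:
    """Angle of each center-of-mass offset in a frame whose 0 deg axis points
    from the site toward ``radial_center``; +/-180 deg means displacement
    directly away from the radial center."""
    if aset.com_offsets is None:
        raise ValueError("set has no center-of-mass offsets")
    to_center = np.asarray(radial_center, dtype=float) - aset.centers
    mag = np.hypot(aset.com_offsets[:, 0], aset.com_offsets[:, 1])
    ok = mag > _EPS
    if not ok.all():
        warnings.warn("zero-length center-of-mass offset; site skipped",
                      stacklevel=2)
    base = full_angle_deg(to_center[ok, 0], to_center[ok, 1])
    off = full_angle_deg(aset.com_offsets[ok, 0], aset.com_offsets[ok, 1])
    angles = wrap_signed_deg(off - base)
    return ComDeviationResult(angles_deg=angles,
                              circular_mean_deg=circular_mean_deg(angles),
                              n_used=int(ok.sum()))


def align_and_average_maps(maps: Sequence[np.ndarray],
                           centers: Sequence[tuple[float, float]],
                           radial_axes_deg: Sequence[float],
                           secondary_contour_z: float = -4.5
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Average maps after centering and rotating their radial axes.

    Each map is translated so its activation center sits at the canvas
    center, then rotated so the direction toward the radial center
    (``radial_axes_deg``, directional degrees as in
    :func:`dipmap.geometry.full_angle_deg`) points along +columns (to the
    right). Returns the pixel-wise nanmean and the mask of the secondary
    contour (average <= ``secondary_contour_z``, z units).
    """
    if len(maps) < 2:
        raise ValueError("need at least 2 maps")
    shape = maps[0].shape
    if any(m.shape != shape for m in maps):
        raise ValueError("maps have mismatched geometry")
    if not (len(centers) == len(radial_axes_deg) == len(maps)):
        raise ValueError("need one center and one axis per map")
    canvas_center = ((shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0)
    aligned = []
    for m, c, ax in zip(maps, centers, radial_axes_deg):
        shifted = ndimage.shift(np.asarray(m, dtype=float),
                                (canvas_center[0] - c[0],
                                 canvas_center[1] - c[1]),
                                order=1, mode="constant", cval=np.nan)
        # ndimage.rotate(angle=a) moves content at directional angle a
        # (atan2(row, col) convention) onto the +column axis.
        rotated = ndimage.rotate(shifted, angle=ax, reshape=False,
                                 order=1, mode="constant", cval=np.nan)
        aligned.append(rotated)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        avg = np.nanmean(np.stack(aligned), axis=0)
    contour = np.where(np.isfinite(avg), avg <= secondary_contour_z, False)
    return avg, contour
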