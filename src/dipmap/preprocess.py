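"""Normalization of raw trial stacks into static z-score and dI/I maps.

The processing chain mirrors standard intrinsic-imaging practice:

1. the spatially averaged time course of the outer border of the image
   (outside the region of interest) is subtracted from every pixel to remove
   non-functional shared temporal noise;
2. each trial/pixel time course is temporally normalized to zero mean and
   unit SD estimated on the pre-stimulus ("frame 0") window;
3. static maps are the trial average over a fixed post-onset window
   (default 1.5-2.5 s, the initial dip);
4. z-score maps subtract, pixel by pixel, the blank condition's static map
   and divide by that map's standard deviation over space;
5. dI/I maps divide each frame by the pre-stimulus baseline and subtract the
   blank frame-by-frame.

Activation regions are pixels at or below a (negative) z threshold on a
smoothed map; the dip is negative-going, so activation means z <= -3.09 by
default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage
from skimage import measure

from .synthetic import TrialStack


@dataclass(frozen=True)
class AnalysisConfig:
    """Analysis parameters with the package defaults.

    ``z_threshold`` of -3.09 defines the activation contour; ``smooth_kernel``
    is the side of the flat (boxcar) smoothing kernel used only for
    contouring; ``static_window`` is in seconds after stimulus onset;
    ``blank_sd_mode`` selects the scalar over-space blank SD (default) or a
    per-pixel SD estimated across blank trials.
    """

    z_threshold: float = -3.09
    smooth_kernel: int = 15
    static_window: tuple[float, float] = (1.5, 2.5)
    border_width: int = 2
    blank_sd_mode: str = "scalar"     # "scalar" | "pixel"

    def __post_init__(self) -> None:
        if self.z_threshold >= 0:
            raise ValueError("z_threshold must be negative (dip polarity)")
        if self.smooth_kernel < 1 or self.smooth_kernel % 2 == 0:
            raise ValueError("smooth_kernel must be odd and positive")
        if self.blank_sd_mode not in ("scalar", "pixel"):
            raise ValueError("blank_sd_mode must be 'scalar' or 'pixel'")


@dataclass
class ZScoreMap:
    values: np.ndarray                 # rows x cols, z units (negative = act.)
    window: tuple[float, float]        # (t_start, t_end) s from trial start
    blank_mean: np.ndarray             # blank static map (per pixel)
    blank_sd: float | np.ndarray       # scalar over space, or per-pixel map
    pixel_pitch: float                 # mm / pixel


@dataclass
class DIIMap:
    values: np.ndarray                 # rows x cols, fractional change
    pixel_pitch: float


@dataclass
class ActivationRegion:
    """Suprathreshold (z <= threshold) region of a smoothed z map.

    ``mask`` is the largest connected component; ``labels`` keeps all
    components for reporting. An empty region is a valid outcome, signalled
    by ``is_empty`` rather than an exception.
    """

    mask: np.ndarray                   # bool, largest component
    component_count: int
    labels: np.ndarray                 # int label image of all components
    smoothed: np.ndarray               # the map the threshold was applied to
    threshold: float
    pixel_pitch: float = 1.0

    @property
    def is_empty(self) -> bool:
        return self.component_count == 0

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())


def _border_mask(rows: int, cols: int, width: int) -> np.ndarray:
    m = np.zeros((rows, cols), dtype=bool)
    m[:width, :] = m[-width:, :] = True
    m[:, :width] = m[:, -width:] = True
    return m


def subtract_border_trend(stack: TrialStack, border_width: int = 2) -> TrialStack:
    """Subtract the border ring's mean time course from every pixel, per trial.

    The trend is mean-centered over frames before subtraction so that only
    the shared temporal pattern is removed while each pixel's reflectance
    level (the dI/I baseline) is preserved.
    """
    if border_width <= 0:
        raise ValueError("border_width must be positive")
    acq = stack.acquisition
    if acq.image_rows <= 2 * border_width or acq.image_cols <= 2 * border_width:
        raise ValueError("image too small for the requested border width")
    ring = _border_mask(acq.image_rows, acq.image_cols, border_width)
    trend = stack.data[:, :, ring].mean(axis=2)          # trials x frames
    trend = trend - trend.mean(axis=1, keepdims=True)
    data = stack.data - trend[:, :, None, None]
    return TrialStack(data=data.astype(stack.data.dtype, copy=False),
                      condition_label=stack.condition_label,
                      acquisition=acq, truth=stack.truth)


def temporal_normalize(stack: TrialStack) -> TrialStack:
    """Zero-mean/unit-SD normalization on the pre-stimulus window.

    Per trial and per pixel, the mean and (sample) SD are estimated from the
    frames before stimulus onset. Pixels with zero pre-stimulus variance in a
    trial are masked to NaN rather than producing infinities.
    """
    acq = stack.acquisition
    f0 = acq.onset_frame
    if f0 < 2:
        raise ValueError("need at least 2 pre-stimulus frames")
    pre = stack.data[:, :f0].astype(np.float64)
    mu = pre.mean(axis=1)
    sd = pre.std(axis=1, ddof=1)
    data = (stack.data.astype(np.float64) - mu[:, None]) \
        / np.where(sd > 0, sd, np.nan)[:, None]
    out = TrialStack.__new__(TrialStack)
    out.data = data
    out.condition_label = stack.condition_label
    out.acquisition = acq
    out.truth = stack.truth
    return out


def _static_window_frames(acq, cfg: AnalysisConfig) -> np.ndarray:
    t = acq.frame_times() - acq.stim_onset
    lo, hi = cfg.static_window
    idx = np.nonzero((t >= lo) & (t <= hi))[0]
    if idx.size == 0:
        raise ValueError("static window contains no frames")
    return idx


def static_map(stack: TrialStack, cfg: AnalysisConfig) -> np.ndarray:
    """Trial-averaged map of the static (post-onset) analysis window."""
    idx = _static_window_frames(stack.acquisition, cfg)
    return np.nanmean(np.nanmean(stack.data[:, idx], axis=1), axis=0)


def compute_static_zscore_map(stim: TrialStack, blank: TrialStack,
                              cfg: AnalysisConfig) -> ZScoreMap:
    """Blank-normalized static z map.

    The trial-averaged blank static map is subtracted pixel by pixel, and the
    result is divided by the blank's standard deviation over space (scalar by
    default; ``blank_sd_mode='pixel'`` uses a per-pixel SD across blank
    trials instead).
    """
    if stim.data.shape[2:] != blank.data.shape[2:]:
        raise ValueError("stimulated and blank stacks have different geometry")
    if stim.acquisition.pixel_pitch != blank.acquisition.pixel_pitch:
        raise ValueError("stimulated and blank stacks have different geometry")
    s_map = static_map(stim, cfg)
    b_map = static_map(blank, cfg)
    if cfg.blank_sd_mode == "scalar":
        sd = float(np.nanstd(b_map))
        if sd == 0:
            sd = 1.0  # degenerate noiseless blank: difference map in raw units
    else:
        idx = _static_window_frames(blank.acquisition, cfg)
        per_trial = np.nanmean(blank.data[:, idx], axis=1)
        sd = np.nanstd(per_trial, axis=0, ddof=1)
        sd = np.where(sd > 0, sd, np.nan)
    z = (s_map - b_map) / sd
    return ZScoreMap(values=z, window=tuple(cfg.static_window),
                     blank_mean=b_map, blank_sd=sd,
                     pixel_pitch=stim.acquisition.pixel_pitch)


def compute_dii_map(stim: TrialStack, blank: TrialStack,
                    cfg: AnalysisConfig) -> DIIMap:
    """Fractional-change map: (stim/baseline - blank/baseline), frame-by-frame,
    averaged over the static window. Operates on raw (non-z-scored) stacks."""
    if stim.data.shape[2:] != blank.data.shape[2:]:
        raise ValueError("stimulated and blank stacks have different geometry")

    def _norm(stack: TrialStack) -> np.ndarray:
        f0 = stack.acquisition.onset_frame
        base = stack.data[:, :f0].mean(axis=1)           # trials x rows x cols
        base = np.where(base != 0, base, np.nan)
        return (stack.data / base[:, None]).mean(axis=0)  # frames x rows x cols

    idx = _static_window_frames(stim.acquisition, cfg)
    dii = (_norm(stim) - _norm(blank))[idx].mean(axis=0)
    return DIIMap(values=dii, pixel_pitch=stim.acquisition.pixel_pitch)


def smooth_map(values: np.ndarray, kernel: int) -> np.ndarray:
    """Flat-kernel smoothing, renormalized at image borders and around NaNs
    (the mean of in-image, finite pixels under the kernel)."""
    if kernel == 1:
        return values.astype(float, copy=True)
    finite = np.isfinite(values)
    filled = np.where(finite, values, 0.0)
    k = np.ones((kernel, kernel))
    num = ndimage.convolve(filled, k, mode="constant", cval=0.0)
    den = ndimage.convolve(finite.astype(float), k, mode="constant", cval=0.0)
    with np.errstate(invalid="ignore"):
        out = num / den
    out[den == 0] = np.nan
    return out


def extract_activation(zmap: ZScoreMap, cfg: AnalysisConfig) -> ActivationRegion:
    """Threshold the smoothed z map and keep the largest connected component.

    Smoothing is applied only for contouring; metrics such as the
    center-of-mass are taken on the unsmoothed z map. An empty result (no
    pixel at or below threshold) is returned as an explicitly empty region.
    """
    sm = smooth_map(zmap.values, cfg.smooth_kernel)
    with np.errstate(invalid="ignore"):
        binary = sm <= cfg.z_threshold
    labels = measure.label(binary, connectivity=2)
    n = int(labels.max())
    if n == 0:
        return ActivationRegion(mask=np.zeros_like(binary), component_count=0,
                                labels=labels, smoothed=sm,
                                threshold=cfg.z_threshold,
                                pixel_pitch=zmap.pixel_pitch)
    sizes = np.bincount(labels.ravel())[1:]
    largest = int(np.argmax(sizes)) + 1   # ties: smallest label (first found)
    return ActivationRegion(mask=labels == largest, component_count=n,
                            labels=labels, smoothed=sm,
                            threshold=cfg.z_threshold,
                            pixel_pitch=zmap.pixel_pitch)
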