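"""Synthetic intrinsic-imaging sessions with known ground truth.

Intrinsic optical imaging of cortex records, trial by trial, stacks of
reflectance images in which a stimulus-evoked activation appears as a small
*negative* fractional change (the "initial dip", of order -1%) riding on a
baseline of 1. This module fabricates such recordings with a fully known
generative model so that every downstream stage of the pipeline can be tested
against ground truth without any acquired data:

* single-condition trial stacks: an anisotropic Gaussian dip with a
  rise/plateau/decay time course, a slow additive drift shared by all pixels
  (measurable on the signal-free outer border), and i.i.d. pixel noise;
* a retinotopy session (a 5x4 grid of square stimuli whose cortical centers
  are displaced by a linear magnification factor);
* an intensity series whose dip amplitudes follow a Naka-Rushton law;
* sets of elongated activation sites radially organized around a virtual
  optic-disk representation, for the radial-organization statistics.

All generators take an explicit integer seed; there is no hidden global RNG.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .geometry import axial_angle_deg
from .radial import ElongatedActivationSet


@dataclass(frozen=True)
class AcquisitionConfig:
    """Geometry and timing of an imaging session.

    Defaults emulate a 5 x 5 mm cortical window imaged at 100 x 100 pixels
    and ~30 Hz, 8 s trials with the stimulus appearing 0.5 s after trial
    onset and lasting 1 s.
    """

    frame_rate: float = 30.0          # Hz
    trial_duration: float = 8.0       # s
    stim_onset: float = 0.5           # s from trial start ("frame 0" period)
    stim_duration: float = 1.0        # s
    image_rows: int = 100
    image_cols: int = 100
    pixel_pitch: float = 0.05         # mm / pixel
    n_trials: int = 20
    n_blank_trials: int = 20

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if not (0 <= self.stim_onset < self.trial_duration):
            raise ValueError("stim_onset must lie within the trial")
        if self.n_trials < 1 or self.n_blank_trials < 1:
            raise ValueError("need at least one trial per condition")
        if self.image_rows < 1 or self.image_cols < 1 or self.pixel_pitch <= 0:
            raise ValueError("invalid image geometry")

    @property
    def n_frames(self) -> int:
        return int(round(self.trial_duration * self.frame_rate))

    @property
    def onset_frame(self) -> int:
        """First frame at or after stimulus onset; frames before it are the
        pre-stimulus ("frame 0") window."""
        return int(np.ceil(self.stim_onset * self.frame_rate - 1e-9))

    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate


@dataclass(frozen=True)
class ActivationSpec:
    """Ground truth of one synthetic activation blob.

    ``amplitude`` is the peak fractional signal change (negative for the
    initial dip). The time course is a linear rise over ``rise_s`` after
    stimulus onset, a plateau until ``plateau_end_s`` post-onset, then an
    exponential decay with time constant ``decay_tau_s``.
    """

    center: tuple[float, float]       # (row, col) pixels
    sigma_major: float                # pixels
    sigma_minor: float                # pixels
    orientation: float = 0.0          # axial degrees in [0, 180)
    amplitude: float = -0.01          # fraction of baseline
    rise_s: float = 0.5
    plateau_end_s: float = 2.5
    decay_tau_s: float = 1.0

    def __post_init__(self) -> None:
        if not (self.sigma_major >= self.sigma_minor > 0):
            raise ValueError("require sigma_major >= sigma_minor > 0")
        if not (0 <= self.orientation < 180):
            raise ValueError("orientation must be in [0, 180)")


@dataclass
class TrialStack:
    """Raw multi-trial imaging data: trials x frames x rows x cols."""

    data: np.ndarray
    condition_label: str
    acquisition: AcquisitionConfig
    truth: Optional[ActivationSpec] = None

    def __post_init__(self) -> None:
        acq = self.acquisition
        expected = (acq.n_frames, acq.image_rows, acq.image_cols)
        if self.data.ndim != 4 or self.data.shape[1:] != expected:
            raise ValueError(
                f"stack shape {self.data.shape} inconsistent with acquisition "
                f"(expected trials x {expected})"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("stack contains non-finite values")


@dataclass
class SessionBundle:
    """A set of stimulated conditions plus exactly one blank condition."""

    stacks: list[TrialStack]
    blank: TrialStack
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.metadata) != len(self.stacks):
            raise ValueError("metadata must have one row per stimulated stack")


METADATA_COLUMNS = [
    "label", "type", "position_deg_x", "position_deg_y",
    "size_deg", "luminance_cd_m2", "current_uA",
]


def _blob_image(acq: AcquisitionConfig, spec: ActivationSpec) -> np.ndarray:
    """Unit-peak anisotropic Gaussian at spec.center (rows x cols)."""
    rows = np.arange(acq.image_rows, dtype=float)[:, None]
    cols = np.arange(acq.image_cols, dtype=float)[None, :]
    dr = rows - spec.center[0]
    dc = cols - spec.center[1]
    # Major axis along the axial orientation measured from the +column axis.
    th = np.radians(spec.orientation)
    u = dc * np.cos(th) + dr * np.sin(th)      # along major axis
    v = -dc * np.sin(th) + dr * np.cos(th)     # along minor axis
    return np.exp(-0.5 * ((u / spec.sigma_major) ** 2
                          + (v / spec.sigma_minor) ** 2))


def temporal_profile(acq: AcquisitionConfig, spec: ActivationSpec) -> np.ndarray:
    """Normalized (peak 1) activation time course sampled at frame times."""
    t = acq.frame_times() - acq.stim_onset
    p = np.zeros_like(t)
    if spec.rise_s > 0:
        rising = (t >= 0) & (t < spec.rise_s)
        p[rising] = t[rising] / spec.rise_s
    plateau = (t >= spec.rise_s) & (t <= spec.plateau_end_s)
    p[plateau] = 1.0
    decay = t > spec.plateau_end_s
    p[decay] = np.exp(-(t[decay] - spec.plateau_end_s) / spec.decay_tau_s)
    return p


def border_drift(acq: AcquisitionConfig, amplitude: float) -> np.ndarray:
    """Slow additive drift shared by every pixel (one value per frame)."""
    t = acq.frame_times()
    return amplitude * np.sin(2.0 * np.pi * t / acq.trial_duration)


def generate_trial_stack(
    acq: AcquisitionConfig,
    spec: ActivationSpec,
    noise_sd: float,
    border_artifact_amp: float,
    seed: int,
    condition_label: str = "stim",
    n_trials: Optional[int] = None,
) -> TrialStack:
    """Simulate one condition's trials.

    Each trial is ``1 * (1 + amplitude * blob * profile(t)) + drift(t) +
    noise``: a multiplicative dip on a baseline of 1 (so both z-score and
    dI/I normalizations are meaningful), a global additive drift whose value
    is observable on the signal-free outer border, and i.i.d. Gaussian pixel
    noise of standard deviation ``noise_sd``.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    r0, c0 = spec.center
    if not (0 <= r0 < acq.image_rows and 0 <= c0 < acq.image_cols):
        raise ValueError("activation center lies outside the image")
    nt = acq.n_trials if n_trials is None else n_trials
    rng = np.random.default_rng(seed)

    blob = _blob_image(acq, spec)
    profile = temporal_profile(acq, spec)
    signal = 1.0 + spec.amplitude * profile[:, None, None] * blob[None, :, :]
    drift = border_drift(acq, border_artifact_amp)
    frames = signal + drift[:, None, None]

    data = np.empty((nt, acq.n_frames, acq.image_rows, acq.image_cols),
                    dtype=np.float32)
    for k in range(nt):
        noise = rng.normal(0.0, noise_sd, size=frames.shape) if noise_sd > 0 \
            else 0.0
        data[k] = frames + noise
    return TrialStack(data=data, condition_label=condition_label,
                      acquisition=acq, truth=spec)


def generate_blank_stack(
    acq: AcquisitionConfig,
    noise_sd: float,
    border_artifact_amp: float,
    seed: int,
) -> TrialStack:
    """Blank condition: baseline + drift + noise, no activation."""
    spec = ActivationSpec(center=(acq.image_rows / 2, acq.image_cols / 2),
                          sigma_major=1.0, sigma_minor=1.0, amplitude=0.0)
    stack = generate_trial_stack(acq, spec, noise_sd, border_artifact_amp,
                                 seed, condition_label="blank",
                                 n_trials=acq.n_blank_trials)
    stack.truth = None
    return stack


DEFAULT_GRID_AZIMUTHS = (-40.0, -20.0, 0.0, 20.0, 40.0)
DEFAULT_GRID_ELEVATIONS = (-30.0, -10.0, 10.0, 30.0)


def generate_retinotopy_session(
    acq: AcquisitionConfig,
    grid_azimuths: Sequence[float] = DEFAULT_GRID_AZIMUTHS,
    grid_elevations: Sequence[float] = DEFAULT_GRID_ELEVATIONS,
    magnification: float = 0.022,
    stim_size_deg: float = 20.0,
    amplitude: float = -0.01,
    noise_sd: float = 0.002,
    border_artifact_amp: float = 0.0,
    seed: int = 0,
) -> SessionBundle:
    """Retinotopic-mapping session: one condition per grid position.

    The cortical center of each condition is displaced from the image center
    (which represents azimuth 0, elevation 0) by ``offset_deg *
    magnification / pixel_pitch`` pixels: +azimuth increases the column,
    +elevation decreases the row. Blob size scales with the stimulus size.
    """
    if magnification <= 0:
        raise ValueError("magnification must be positive")
    ref = (acq.image_rows / 2.0, acq.image_cols / 2.0)
    px_per_deg = magnification / acq.pixel_pitch
    sigma = max(stim_size_deg * px_per_deg / 4.0, 1.0)

    stacks: list[TrialStack] = []
    rows_meta = []
    rng = np.random.default_rng(seed)
    for az in grid_azimuths:
        for el in grid_elevations:
            center = (ref[0] - el * px_per_deg, ref[1] + az * px_per_deg)
            if not (0 <= center[0] < acq.image_rows
                    and 0 <= center[1] < acq.image_cols):
                raise ValueError(
                    f"grid position ({az},{el}) deg maps outside the image")
            spec = ActivationSpec(center=center, sigma_major=sigma,
                                  sigma_minor=sigma, amplitude=amplitude)
            label = f"az{az:+g}_el{el:+g}"
            sub_seed = int(rng.integers(0, 2**31 - 1))
            stacks.append(generate_trial_stack(
                acq, spec, noise_sd, border_artifact_amp, sub_seed,
                condition_label=label))
            rows_meta.append(dict(label=label, type="visual",
                                  position_deg_x=az, position_deg_y=el,
                                  size_deg=stim_size_deg,
                                  luminance_cd_m2=49.0, current_uA=np.nan))
    blank = generate_blank_stack(acq, noise_sd, border_artifact_amp,
                                 int(rng.integers(0, 2**31 - 1)))
    meta = pd.DataFrame(rows_meta, columns=METADATA_COLUMNS)
    return SessionBundle(stacks=stacks, blank=blank, metadata=meta)


def naka_rushton(c, rmax: float, c50: float, n: float):
    """Saturating response law R(c) = Rmax c^n / (c^n + C50^n)."""
    c = np.asarray(c, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        cn = np.power(c, n)
        out = rmax * cn / (cn + c50 ** n)
    return np.where(c == 0, 0.0, out)


def generate_intensity_series(
    acq: AcquisitionConfig,
    levels: Sequence[float] = (2.0, 13.75, 25.5, 37.25, 49.0),
    rmax: float = 0.01,
    c50: float = 9.6,
    n: float = 6.05,
    stimulus_type: str = "visual",
    sigma_px: float = 8.0,
    noise_sd: float = 0.002,
    border_artifact_amp: float = 0.0,
    seed: int = 0,
) -> SessionBundle:
    """Intensity series whose dip amplitudes follow a Naka-Rushton law.

    ``rmax`` is the saturating dip amplitude (fraction of baseline); the
    default semi-saturation and exponent emulate a luminance series.
    """
    levels = list(levels)
    if not levels:
        raise ValueError("levels must be non-empty")
    arr = np.asarray(levels, dtype=float)
    if np.any(arr < 0) or np.any(np.diff(arr) <= 0):
        raise ValueError("levels must be non-negative and strictly ascending")

    center = (acq.image_rows / 2.0, acq.image_cols / 2.0)
    rng = np.random.default_rng(seed)
    stacks: list[TrialStack] = []
    rows_meta = []
    for c in levels:
        amp = -float(naka_rushton(c, rmax, c50, n))
        label = f"{stimulus_type}_{c:g}"
        if amp == 0.0:
            spec = ActivationSpec(center=center, sigma_major=sigma_px,
                                  sigma_minor=sigma_px, amplitude=0.0)
        else:
            spec = ActivationSpec(center=center, sigma_major=sigma_px,
                                  sigma_minor=sigma_px, amplitude=amp)
        sub_seed = int(rng.integers(0, 2**31 - 1))
        stacks.append(generate_trial_stack(
            acq, spec, noise_sd, border_artifact_amp, sub_seed,
            condition_label=label))
        is_visual = stimulus_type == "visual"
        rows_meta.append(dict(
            label=label, type=stimulus_type,
            position_deg_x=0.0, position_deg_y=0.0, size_deg=20.0,
            luminance_cd_m2=c if is_visual else np.nan,
            current_uA=np.nan if is_visual else c))
    blank = generate_blank_stack(acq, noise_sd, border_artifact_amp,
                                 int(rng.integers(0, 2**31 - 1)))
    meta = pd.DataFrame(rows_meta, columns=METADATA_COLUMNS)
    return SessionBundle(stacks=stacks, blank=blank, metadata=meta)


def generate_size_series(
    acq: AcquisitionConfig,
    sizes_deg: Sequence[float] = (2.0, 6.0, 10.0, 14.0, 18.0),
    size_slope: float = 0.081,
    amplitude: float = -0.01,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> SessionBundle:
    """Size-tuning session: blob full-width-at-half-maximum (mm) equals
    ``size_slope * size_deg`` (Gaussian FWHM = 2 sqrt(2 ln 2) sigma)."""
    center = (acq.image_rows / 2.0, acq.image_cols / 2.0)
    fwhm_factor = 2.0 * np.sqrt(2.0 * np.log(2.0))
    rng = np.random.default_rng(seed)
    stacks, rows_meta = [], []
    for s in sizes_deg:
        sigma_px = size_slope * s / fwhm_factor / acq.pixel_pitch
        spec = ActivationSpec(center=center, sigma_major=sigma_px,
                              sigma_minor=sigma_px, amplitude=amplitude)
        label = f"size_{s:g}"
        stacks.append(generate_trial_stack(
            acq, spec, noise_sd, 0.0, int(rng.integers(0, 2**31 - 1)),
            condition_label=label))
        rows_meta.append(dict(label=label, type="visual",
                              position_deg_x=0.0, position_deg_y=0.0,
                              size_deg=s, luminance_cd_m2=49.0,
                              current_uA=np.nan))
    blank = generate_blank_stack(acq, noise_sd, 0.0,
                                 int(rng.integers(0, 2**31 - 1)))
    return SessionBundle(stacks=stacks, blank=blank,
                         metadata=pd.DataFrame(rows_meta,
                                               columns=METADATA_COLUMNS))


def generate_elongated_set(
    n_sites: int,
    od_position: tuple[float, float],
    eccentricity_range: tuple[float, float],
    angular_jitter_sd: float,
    seed: int,
    ar_mean: float = 2.0,
    com_offset_mag: float = 0.1,
) -> ElongatedActivationSet:
    """Elongated activation sites radially organized around ``od_position``.

    Positions are uniform in the annulus ``eccentricity_range`` around the
    virtual optic-disk representation; each site's axial orientation is the
    radial direction toward the disk plus Gaussian axial jitter of SD
    ``angular_jitter_sd`` degrees. Center-of-mass offsets point directly away
    from the disk with magnitude ``com_offset_mag`` (same units as centers).
    """
    if n_sites < 3:
        raise ValueError("need at least 3 sites")
    r0, r1 = eccentricity_range
    if not (0 < r0 < r1):
        raise ValueError("eccentricity_range must be 0 < inner < outer")
    rng = np.random.default_rng(seed)
    # Uniform over the annulus area.
    radii = np.sqrt(rng.uniform(r0 ** 2, r1 ** 2, size=n_sites))
    theta = rng.uniform(0.0, 2.0 * np.pi, size=n_sites)
    od = np.asarray(od_position, dtype=float)
    centers = od + np.column_stack([radii * np.sin(theta),
                                    radii * np.cos(theta)])
    radial = axial_angle_deg(od[0] - centers[:, 0], od[1] - centers[:, 1])
    orientations = (radial + rng.normal(0.0, angular_jitter_sd,
                                        size=n_sites)) % 180.0
    away = (centers - od) / radii[:, None]
    com_offsets = away * com_offset_mag
    ar_values = np.maximum(ar_mean + rng.normal(0.0, 0.1, size=n_sites), 1.6)
    return ElongatedActivationSet(centers=centers, orientations=orientations,
                                  ar_values=ar_values,
                                  com_offsets=com_offsets)


# ---------------------------------------------------------------------------
# On-disk representation: .npz (or multi-page TIFF) with a JSON sidecar.

def save_stack(stack: TrialStack, path: str | Path) -> None:
    path = Path(path)
    meta = {
        "condition_label": stack.condition_label,
        "acquisition": vars(stack.acquisition).copy(),
        "truth": None if stack.truth is None else {
            **{k: v for k, v in vars(stack.truth).items() if k != "center"},
            "center": list(stack.truth.center),
        },
        "n_trials": int(stack.data.shape[0]),
    }
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile
        nt, nf, nr, nc = stack.data.shape
        tifffile.imwrite(path, stack.data.reshape(nt * nf, nr, nc),
                         metadata=None, description=json.dumps(meta))
    else:
        np.savez_compressed(path, data=stack.data)
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))


def load_stack(path: str | Path) -> TrialStack:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    acq = AcquisitionConfig(**meta["acquisition"])
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile
        flat = tifffile.imread(path)
        data = flat.reshape(meta["n_trials"], acq.n_frames,
                            acq.image_rows, acq.image_cols)
    else:
        data = np.load(path)["data"]
    truth = None
    if meta["truth"] is not None:
        t = dict(meta["truth"])
        t["center"] = tuple(t["center"])
        truth = ActivationSpec(**t)
    return TrialStack(data=data, condition_label=meta["condition_label"],
                      acquisition=acq, truth=truth)
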