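"""Two-source model of retinal activation under sub-retinal stimulation.

An electrode of radius ``S`` (grid units) activates the retina through two
components on an N x N grid:

* **direct diffusion** (``IsoA``): a flat-top Gaussian, 1 inside the
  electrode (Euclidean distance d < S) and exp(-d^2 / (2 (sigma S)^2))
  outside;
* **axons en passant** (``EP``): ganglion-cell axons passing over the
  electrode en route to the optic disk are activated, recruiting somata
  located in a "shadow cone" on the far side of the electrode. EP is the
  product of a broad attenuation ``Att = exp(-(d - S)^2 / (2 N^2))``, a
  logistic gate ``Sig`` that turns on beyond the electrode's distance from
  the optic disk (slope scale S/4), and an angular Gaussian ``Cone`` in the
  angle from the disk-to-electrode axis normalized by the full cone angle
  ``2 asin(S / d_OD-electrode)``, restricted to the half-plane beyond the
  optic disk along that axis.

The combined activation is ``IsoA + alpha * EP``. Shape metrics (radial vs
tangential extent at a fractional contour) quantify the predicted elongation:
small electrodes give radially elongated activations (AR > 1), very large
cone angles give tangential elongation (AR < 1).

Also provided: the shadow-cone angle subtended by the stimulated surface at
the optic disk, and the retino-cortical transform based on a magnification
RCM(R) = 1/(aR + b) mm/deg at eccentricity R deg.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class ModelConfig:
    """Retinal-model parameters (grid units).

    Defaults follow the reference configuration: a 400 x 400 grid with the
    optic disk at (200, 100) and the electrode at (200, 150); ``s`` spans
    3-30 and ``alpha`` 0.1-1 in the published sweeps.
    """

    n: int = 400
    electrode: tuple[float, float] = (200.0, 150.0)
    optic_disk: tuple[float, float] = (200.0, 100.0)
    s: float = 5.0
    sigma: float = 1.0
    alpha: float = 1.0

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")
        if self.s <= 0 or self.sigma <= 0:
            raise ValueError("s and sigma must be positive")
        for name, (i, j) in (("electrode", self.electrode),
                             ("optic_disk", self.optic_disk)):
            if not (0 <= i < self.n and 0 <= j < self.n):
                raise ValueError(f"{name} outside the grid")
        if self.s >= self.od_distance:
            raise ValueError("electrode radius must be smaller than the "
                             "electrode-to-optic-disk distance")

    @property
    def od_distance(self) -> float:
        """Euclidean distance from the electrode to the optic disk."""
        return float(np.hypot(self.electrode[0] - self.optic_disk[0],
                              self.electrode[1] - self.optic_disk[1]))

    @property
    def axis_unit(self) -> tuple[float, float]:
        """Unit vector from the optic disk toward the electrode (row, col)."""
        d = self.od_distance
        return ((self.electrode[0] - self.optic_disk[0]) / d,
                (self.electrode[1] - self.optic_disk[1]) / d)

    @property
    def full_cone_angle_rad(self) -> float:
        """Full shadow-cone angle, 2 asin(S / electrode-OD distance)."""
        return float(2.0 * np.arcsin(self.s / self.od_distance))


@dataclass
class EnPassantFields:
    ep: np.ndarray
    att: np.ndarray
    sig: np.ndarray
    cone: np.ndarray
    cone_ang: np.ndarray   # angle from the OD-electrode axis / full cone angle
    d_od: np.ndarray       # distance to the optic disk


@dataclass
class RetinalMap:
    """All model fields for one configuration."""

    iso: np.ndarray
    ep: np.ndarray
    combined: np.ndarray
    fields: EnPassantFields
    cfg: ModelConfig


@dataclass
class ModelShapeMetrics:
    """Shape of the suprathreshold model activation.

    ``aspect_ratio_radial`` is radial extent / tangential extent (may be < 1);
    ``com_shift`` points from the region's geometric center to its
    intensity-weighted center-of-mass (grid units, (row, col))."""

    aspect_ratio_radial: float
    radial_extent: float
    tangential_extent: float
    equivalent_diameter: float
    com_shift: tuple[float, float]
    area_px: int


def _grid(cfg: ModelConfig):
    i = np.arange(cfg.n, dtype=float)[:, None]
    j = np.arange(cfg.n, dtype=float)[None, :]
    return i, j


def iso_activation(cfg: ModelConfig, continuous: bool = False) -> np.ndarray:
    """Flat-top Gaussian direct activation.

    As printed, the profile is discontinuous at d = S (it drops from 1 to
    exp(-1/2) for sigma = 1); ``continuous=True`` switches to the shifted
    variant exp(-(d - S)^2 / (2 (sigma S)^2)) outside the electrode.
    """
    i, j = _grid(cfg)
    d = np.hypot(i - cfg.electrode[0], j - cfg.electrode[1])
    w = 2.0 * (cfg.sigma * cfg.s) ** 2
    if continuous:
        tail = np.exp(-(d - cfg.s) ** 2 / w)
    else:
        tail = np.exp(-d ** 2 / w)
    return np.where(d < cfg.s, 1.0, tail)


def en_passant_fields(cfg: ModelConfig) -> EnPassantFields:
    """All intermediate fields of the axons-en-passant component."""
    i, j = _grid(cfg)
    d_el = np.hypot(i - cfg.electrode[0], j - cfg.electrode[1])
    d_od = np.hypot(i - cfg.optic_disk[0], j - cfg.optic_disk[1])
    d0 = cfg.od_distance

    att = np.exp(-(d_el - cfg.s) ** 2 / (2.0 * cfg.n ** 2))
    sig = 1.0 / (1.0 + np.exp(-(d_od - d0) / (cfg.s / 4.0)))

    ui, uj = cfg.axis_unit
    proj = (i - cfg.optic_disk[0]) * ui + (j - cfg.optic_disk[1]) * uj
    with np.errstate(invalid="ignore", divide="ignore"):
        cos_ang = np.clip(proj / d_od, -1.0, 1.0)
    ang = np.arccos(np.where(d_od > 0, cos_ang, 1.0))
    cone_ang = ang / cfg.full_cone_angle_rad
    cone = np.where(proj > 0,
                    np.exp(-cone_ang ** 2 / (2.0 * cfg.sigma ** 2)), 0.0)
    return EnPassantFields(ep=att * sig * cone, att=att, sig=sig, cone=cone,
                           cone_ang=cone_ang, d_od=d_od)


def en_passant_activation(cfg: ModelConfig) -> np.ndarray:
    return en_passant_fields(cfg).ep


def combine_activation(iso: np.ndarray, ep: np.ndarray,
                       alpha: float) -> np.ndarray:
    """Weighted sum IsoA + alpha * EP."""
    if iso.shape != ep.shape:
        raise ValueError("iso and ep grids have different geometry")
    return iso + alpha * ep


def retinal_map(cfg: ModelConfig) -> RetinalMap:
    iso = iso_activation(cfg)
    f = en_passant_fields(cfg)
    return RetinalMap(iso=iso, ep=f.ep,
                      combined=combine_activation(iso, f.ep, cfg.alpha),
                      fields=f, cfg=cfg)


def model_shape_metrics(map_grid: np.ndarray, cfg: ModelConfig,
                        contour_level: float = 0.5,
                        reference: str = "unit") -> ModelShapeMetrics:
    """Extent of the activation along and across the optic-disk axis.

    The map is thresholded at ``contour_level`` times a reference amplitude
    and extents are the spans of the suprathreshold pixels projected on the
    radial (disk-to-electrode) axis and its perpendicular.

    Both model components saturate at 1, so the half-maximum contour is taken
    by default on that common activation scale (``reference='unit'``);
    ``reference='max'`` uses the map's own maximum instead, which exceeds 1
    wherever the two components superpose and therefore excludes the
    en-passant fan from the contour.
    """
    if not (0 < contour_level < 1):
        raise ValueError("contour_level must be in (0, 1)")
    if reference == "unit":
        thr = contour_level
    elif reference == "max":
        thr = contour_level * float(np.nanmax(map_grid))
    else:
        raise ValueError("reference must be 'unit' or 'max'")
    mask = map_grid >= thr
    rr, cc = np.nonzero(mask)
    if rr.size == 0:
        raise ValueError("no pixels above the contour level")
    ui, uj = cfg.axis_unit
    radial = rr * ui + cc * uj
    tangential = -rr * uj + cc * ui
    radial_ext = float(radial.max() - radial.min() + 1.0)
    tang_ext = float(tangential.max() - tangential.min() + 1.0)
    geo = np.array([rr.mean(), cc.mean()])
    w = map_grid[rr, cc]
    com = np.array([np.average(rr, weights=w), np.average(cc, weights=w)])
    return ModelShapeMetrics(
        aspect_ratio_radial=radial_ext / tang_ext,
        radial_extent=radial_ext,
        tangential_extent=tang_ext,
        equivalent_diameter=2.0 * np.sqrt(rr.size / np.pi),
        com_shift=(float(com[0] - geo[0]), float(com[1] - geo[1])),
        area_px=int(rr.size),
    )


@dataclass(frozen=True)
class ShadowConeGeometry:
    """Geometry of the stimulated surface seen from the optic disk.

    ``x``: MEA radius (mm); ``y``: distance from the MEA to the optic disk
    (mm); ``z``: diameter of the actually stimulated active surface (mm).
    """

    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        if self.z <= 0 or self.x <= 0:
            raise ValueError("x and z must be positive")
        if self.x > self.y:
            raise ValueError("require 0 < x <= y")


def shadow_cone_angle(geom: ShadowConeGeometry, mode: str = "arcsin") -> float:
    """Shadow-cone angle (degrees) subtended at the optic disk.

    Default ``arcsin`` mode evaluates 2 asin(r / y) with the radius corrected
    to the actual stimulated active surface, r = z/2. The ``linear`` mode
    instead rescales the MEA-radius angle 2 asin(x / y) by z / (2x).
    """
    half = geom.z / 2.0
    if mode == "arcsin":
        if half > geom.y:
            raise ValueError("active-surface radius exceeds the distance "
                             "to the optic disk")
        return float(np.degrees(2.0 * np.arcsin(half / geom.y)))
    if mode == "linear":
        return float(np.degrees(2.0 * np.arcsin(geom.x / geom.y))
                     * half / geom.x)
    raise ValueError("mode must be 'arcsin' or 'linear'")


@dataclass(frozen=True)
class RetinoCorticalParams:
    """Constants of the magnification law RCM(R) = 1/(aR + b) mm/deg.

    Defaults: a=0.7, b=30 along the horizontal meridian; a=0.4, b=40 for the
    vertical dimension.
    """

    a: float
    b: float

    def __post_init__(self) -> None:
        if self.b <= 0 or self.a < 0:
            raise ValueError("require b > 0 and a >= 0")


HORIZONTAL_RCM = RetinoCorticalParams(a=0.7, b=30.0)
VERTICAL_RCM = RetinoCorticalParams(a=0.4, b=40.0)


def rcm(eccentricity_deg, params: RetinoCorticalParams):
    """Local retino-cortical magnification (mm/deg) at eccentricity R."""
    r = np.abs(np.asarray(eccentricity_deg, dtype=float))
    return 1.0 / (params.a * r + params.b)


def retino_cortical_position(eccentricity_deg, params: RetinoCorticalParams):
    """Cortical coordinate (mm) of eccentricity R: integral of RCM from 0.

    Equals (1/a) ln((a|R| + b)/b) with the sign of R, and |R|/b when a = 0.
    """
    r = np.asarray(eccentricity_deg, dtype=float)
    mag = np.abs(r)
    if params.a == 0:
        out = mag / params.b
    else:
        out = np.log((params.a * mag + params.b) / params.b) / params.a
    return np.sign(r) * out


def retino_cortical_transform(points_deg,
                              horizontal: RetinoCorticalParams = HORIZONTAL_RCM,
                              vertical: RetinoCorticalParams = VERTICAL_RCM
                              ) -> np.ndarray:
    """Map (vertical, horizontal) visual positions in degrees to cortical mm,
    axis-wise. Input is an array-like of shape (..., 2) ordered (row=vertical,
    col=horizontal); output has the same shape."""
    p = np.asarray(points_deg, dtype=float)
    out = np.empty_like(p)
    out[..., 0] = retino_cortical_position(p[..., 0], vertical)
    out[..., 1] = retino_cortical_position(p[..., 1], horizontal)
    return out


def transformed_aspect_ratio(map_grid: np.ndarray, cfg: ModelConfig,
                             contour_level: float = 0.5,
                             reference: str = "unit",
                             deg_per_px: float = 0.1,
                             horizontal: RetinoCorticalParams = HORIZONTAL_RCM,
                             vertical: RetinoCorticalParams = VERTICAL_RCM
                             ) -> float:
    """Radial/tangential extent ratio after the retino-cortical transform.

    Pixel coordinates of the suprathreshold region, taken relative to the
    optic disk and scaled by ``deg_per_px``, are mapped axis-wise to cortical
    mm; extents are then measured along the (column) radial axis and across
    it. Requires the column-aligned default geometry (electrode and optic
    disk on the same row), where the transform's axes coincide with the
    radial/tangential axes.
    """
    if cfg.electrode[0] != cfg.optic_disk[0]:
        raise NotImplementedError("transform assumes the column-aligned "
                                  "electrode/optic-disk geometry")
    thr = contour_level if reference == "unit" \
        else contour_level * float(np.nanmax(map_grid))
    rr, cc = np.nonzero(map_grid >= thr)
    if rr.size == 0:
        raise ValueError("no pixels above the contour level")
    v = (rr - cfg.optic_disk[0]) * deg_per_px
    h = (cc - cfg.optic_disk[1]) * deg_per_px
    vm = retino_cortical_position(v, vertical)
    hm = retino_cortical_position(h, horizontal)
    radial = float(hm.max() - hm.min())
    tangential = float(vm.max() - vm.min())
    return radial / tangential


def shape_sweep(s_values, alpha: float = 1.0, n: int = 400,
                electrode=None, optic_disk=None,
                sigma: float = 1.0, contour_level: float = 0.5):
    """Aspect ratio and extent vs electrode size at fixed en-passant weight.

    By default the optic disk sits at (n/2, n/4) and the electrode at
    (n/2, 3n/8), the reference geometry scaled to the grid. Returns a list of
    dicts (s, alpha, cone_angle_deg, ar, extent_px) suitable for a tidy
    DataFrame.
    """
    if optic_disk is None:
        optic_disk = (n / 2.0, n / 4.0)
    if electrode is None:
        electrode = (n / 2.0, 3.0 * n / 8.0)
    rows = []
    for s in s_values:
        cfg = ModelConfig(n=n, electrode=tuple(electrode),
                          optic_disk=tuple(optic_disk), s=float(s),
                          sigma=sigma, alpha=alpha)
        m = model_shape_metrics(retinal_map(cfg).combined, cfg, contour_level)
        rows.append(dict(s=float(s), alpha=float(alpha),
                         cone_angle_deg=float(np.degrees(cfg.full_cone_angle_rad)),
                         ar=m.aspect_ratio_radial,
                         extent_px=m.equivalent_diameter))
    return rows
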