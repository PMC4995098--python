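# Methods

This note documents the models, conventions, parameter defaults and numerical
choices behind `dipmap`, and what the synthetic-data tests do and do not
establish about real recordings.

## Coordinates and angles

Images are indexed 0-based `(row, col)` with rows increasing downward;
physical units come from the acquisition pixel pitch (mm/pixel). Orientations
of elongated structures are *axial* angles in degrees in [0, 180), measured
from the +column axis; directional angles, where needed, are
`atan2(d_row, d_col)`. All axial differences are taken modulo 180° and folded
into [0, 90°] — ellipse axes have no head or tail, so 5° and 175° differ
by 10°, not 170°.

## Synthetic recordings

A trial is simulated as

    I(t, x) = 1 + A · b(x) · p(t) + g(t) + ε

with baseline 1, a unit-peak anisotropic Gaussian footprint `b` (the
activation is multiplicative on the baseline, as intrinsic signals are
fractional reflectance changes), a rise/plateau/decay time course `p`
(linear rise 0.5 s, plateau to 2.5 s post-onset, exponential decay τ = 1 s
— the analysis only fixes the averaging window, so the true dynamics are a
modeling choice), a slow additive drift `g(t)` shared by every pixel (one
sine period per trial), and i.i.d. Gaussian pixel noise ε. The peak
fractional amplitude A defaults to −1%, a typical initial-dip magnitude; the
default pixel noise SD is 0.002 (0.2× the dip, the regime in which the
noisy-recovery tolerances are stated). Default geometry is a 5×5 mm window
at 100×100 pixels (0.05 mm/pixel), ~30 Hz, 8 s trials, stimulus at 0.5 s,
20 trials per condition.

Session generators build on this: a 5×4 retinotopic grid of 20° stimuli
whose true cortical centers are displaced by a linear magnification factor
(default 0.022 mm/°); an intensity series whose dip amplitudes follow a
Naka-Rushton law (defaults Rmax = 1% dip, C50 = 9.6, n = 6.05 on the
luminance levels 2–49 cd/m²); a size series whose blob FWHM in mm is
`slope × size_deg` (default 0.081 mm/°); and sets of elongated activation
sites placed uniformly in an annulus around a virtual optic-disk
representation, oriented radially toward it with Gaussian axial jitter,
with center-of-mass offsets pointing directly away from it.

What the generator does *not* emulate: vascular artifacts, heartbeat-locked
acquisition, inter-trial amplitude correlations (trials are i.i.d.), motion,
and spatially correlated noise. Passing recovery tests therefore demonstrate
the correctness of the estimators under the stated noise model, not their
robustness to structured physiological noise.

## Normalization chain

1. **Border detrend** — the mean time course of the outer 2-pixel ring
   (outside any activation) is subtracted from every pixel, per trial. The
   trend is mean-centered over frames first, so only the shared temporal
   pattern is removed and each pixel's reflectance level (the ΔI/I baseline)
   is preserved.
2. **Frame-0 normalization** — per trial and pixel, subtract the mean and
   divide by the sample SD of the pre-stimulus frames (all frames before
   stimulus onset). Pixels with zero pre-stimulus variance are masked (NaN)
   rather than allowed to produce infinities. This makes the chain exactly
   invariant to per-pixel affine rescaling of the raw data.
3. **Static maps** — trial average over 1.5–2.5 s post-onset (the initial
   dip).
4. **z-score map** — subtract, pixel by pixel, the blank condition's static
   map, and divide by the blank map's SD *over space* (a scalar). This makes
   "blank vs itself" identically zero and "blank + Δ" exactly Δ/SD. A
   per-pixel SD across blank trials is available via
   `AnalysisConfig.blank_sd_mode="pixel"`.
5. **ΔI/I map** — each frame divided by its trial's pre-stimulus baseline,
   blank subtracted frame-by-frame, averaged over the static window.

**Activation region** — pixels with z ≤ −3.09 on a smoothed map (15×15 flat
kernel, renormalized at image borders so edge pixels average only in-image
values), 8-connected, largest component kept (all components retained for
reporting). The −3.09 cutoff is the field's printed convention for these
maps; note that as a normal quantile it corresponds to p ≈ 0.001, not 0.01.
Smoothing is used *only* for contouring; the center of mass is computed on
the unsmoothed z map over the region, weighted by |z|. A noiseless stack
makes the blank's spatial SD zero; the z map then degenerates to a raw
difference map, so zero-noise round-trip tests measure blobs on ΔI/I maps at
fraction-of-peak contours instead.

## Shape descriptors

The equivalent ellipse has the same normalized second central moments as the
binary region. Each pixel is treated as a unit square (adding 1/12 to the
diagonal moments), so a solid w×h rectangle yields exactly the continuous
moments w²/12, h²/12 — and AR exactly w/h. Axis lengths are 4√λ of the
moment-matrix eigenvalues (a disc of radius r returns axes 2r); the
equivalent diameter is that of the circle of equal area. Collinear regions
are flagged degenerate and the minor axis floored at one pixel.
`skimage.measure.regionprops`, which omits the pixel-extension term, serves
as an independent cross-check in the tests, never as the implementation.

## Retinotopy

Polar maps assign each pixel the response-weighted centroid of the stimulus
grid positions, with responses rectified to the activation sign
(max(−z, 0)). Rectified responses below a floor (default 3.09, matching the
significance threshold) are zeroed: without the floor, rectified noise at
the 19 non-preferred positions biases every preference toward the grid
centroid. Expected cortical positions minimize the preference-space distance
to the queried visual position among responsive pixels (those reaching 25%
of the peak response strength — isolated noise pixels otherwise win exact-
match queries). The magnification factor is fitted by least squares on
pairwise (visual distance, cortical distance) points; an intercept-free
variant is available.

## Intensity-response functions

Naka-Rushton fits use bounded least squares with a 3×3 multi-start grid
(C50 at the 25/50/75th intensity percentiles × exponents {1, 2, 4}), Rmax
initialized at the maximum amplitude; the best converged start by SSE wins
and total non-convergence raises an explicit error with diagnostics. No
baseline offset is included by default (the response is measured relative to
blank), but `with_baseline=True` adds one. The operational range
C50·(9^(1/n) − 9^(−1/n)) is validated against numerical 10%/90% root finding
to 1e-6 relative. The inverse (equivalent-intensity) mapping is defined for
amplitudes strictly between 0 and Rmax; saturated amplitudes raise a typed
error.

## Retinal activation model

On an N×N grid (N = 400) with optic disk at (200, 100) and electrode at
(200, 150):

* `IsoA(x) = 1` for d < S, else `exp(−d²/(2(σS)²))`, with d the Euclidean
  distance to the electrode, S the electrode radius in grid units (3–30) and
  σ = 1. As printed, the profile is discontinuous at d = S (drop from 1 to
  e^(−1/2)); a continuous variant `exp(−(d−S)²/(2(σS)²))` is available
  behind a flag. Distance-vs-squared-distance ambiguities in the printed
  formulas are resolved in favor of Euclidean distances: they keep the
  "flat-top Gaussian" dimensionally consistent, and the attenuation term
  then acts, as described, only "very far" from the electrode.
* `EP = Att·Sig·Cone` with `Att = exp(−(d−S)²/(2N²))`,
  `Sig = 1/(1+exp(−(d_OD − D)/(S/4)))` where d_OD is the distance to the
  optic disk and D the electrode-to-disk distance (Euclidean, which reduces
  to the printed column difference for the default column-aligned geometry),
  and `Cone = exp(−θ̂²/(2σ²))` where θ̂ is the angle from the disk-to-
  electrode axis normalized by the full cone angle 2·asin(S/D), restricted
  to the half-plane beyond the optic disk along that axis.
* Combined activation: `IsoA + α·EP`, α ∈ [0.1, 1].

**Contour convention.** Both components saturate at 1, so the half-maximum
contour is taken at 0.5 on that common activation scale. Thresholding at
half the combined map's own maximum (≈ 1+α where the components superpose
near the electrode) would exclude the en-passant fan entirely and suppress
the tangential-elongation regime; that variant remains available via
`reference="max"`. Extents are spans of the suprathreshold pixels projected
on the disk-electrode axis (radial) and its perpendicular (tangential);
AR = radial/tangential.

With these conventions, AR falls monotonically from ≈3.5 (S = 3) through 1
(S ≈ 10) to <1 (S = 20, 30) at α = 1, and grows with α at fixed small S
(1 < AR(α=0.5) < AR(α=1)). Two boundary effects are worth knowing: for
S ≥ 20 both extents saturate at the grid edge, so the ordering *between*
S = 20 and S = 30 is a boundary artifact (both are firmly in the AR < 1
regime); and as α crosses the contour level the fan enters the region
abruptly, so AR is not globally monotone in α across that transition.

The shadow-cone angle of a stimulated surface of diameter z at distance y
from the optic disk is 2·asin((z/2)/y) (the active-surface radius enters the
arcsine; a linear-rescaling variant of the MEA-radius angle is provided).
The retino-cortical transform integrates the magnification
RCM(R) = 1/(aR+b) mm/° to the closed form (1/a)·ln((aR+b)/b), applied
axis-wise with (a, b) = (0.7, 30) horizontally and (0.4, 40) vertically;
applying it to the model maps leaves the sign of AR − 1 unchanged for the
default geometry.

## Radial-organization statistics

For a candidate center, each site contributes the folded axial difference
between its orientation and the direction from the site to the candidate;
the statistic is the median. The optimal center is an exhaustive grid search
(default: the sites' bounding box padded by 1 mm, 0.1 mm resolution — the
published analysis does not state a resolution), ties broken deterministically
in row-major order. The Monte-Carlo null redraws orientations i.i.d. uniform
on [0, 180) at the observed positions (uniformity is the natural reading of
"random orientations") and re-optimizes per iteration — 1000 iterations by
default; the direction matrix between grid points and sites is precomputed
once, so nulls cost little beyond the first search. p values: empirical
(fraction of null ≤ observed, the area under the null to its left) and the
lower Gaussian tail at the observed value given the null's mean and SD, with
z = (mean − observed)/SD. Sets assembled from pipeline output apply the
AR ≥ 1.6 inclusion criterion.

Center-of-mass deviation angles are expressed per site in a frame whose 0°
axis points toward the radial center, so ±180° means displaced directly away
from it; the summary is the circular mean. Map averaging translates each map
so its activation center sits at the canvas center, rotates it (bilinear,
NaN fill) so its radial axis points along +columns, and takes the pixel-wise
nanmean; a secondary contour at z = −4.5 is reported alongside.

## Problem sizes and determinism

Every stochastic routine takes an explicit integer seed (NumPy
`default_rng`); pipeline runs derive per-stage seeds from the run seed and
record them, with the configuration hash, in a manifest, making reruns
bit-identical on the CSV/JSON outputs. The test suite and the demo
configuration use reduced problem sizes — images of 32–60 pixels a side,
4–8 trials per condition, 100–400 Monte-Carlo iterations, nulls on 0.2 mm
search grids — chosen so the full suite runs in well under a minute while
leaving the statistical assertions comfortable margins; the package defaults
remain the full-scale values stated above.

## Known limitations

* The model's shape metrics depend on the contour convention (documented
  above); the published figures do not state their contour level.
* The en-passant component is phenomenological — no axon-bundle geometry,
  conduction thresholds or electric-field modeling.
* The polar-map preference floor and the responsive-pixel criterion are
  practical safeguards against rectified-noise bias; with strong signals
  they are inactive.
* Per-animal population averages reported for real recordings (operational
  ranges, size-increase factors) are not recomputable from summary
  parameters and are out of scope; the tests cover the formulas and
  estimator recoveries instead.
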