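# dipmap

Quantitative analysis of cortical population maps recorded with intrinsic
optical imaging, comparing activations evoked by visual stimuli with those
evoked by sub-retinal prosthetic (micro-electrode array) stimulation. The
package is aimed at visual-neuroscience and retinal-prosthetics labs that
need a reproducible pipeline from raw multi-trial imaging stacks to position,
size, shape and intensity metrics — and at modelers interested in how
activation of retinal ganglion-cell *axons en passant* shapes the evoked
cortical maps.

Because such recordings are rarely shared, the package ships a first-class
synthetic-data generator that emulates the statistical structure of the
recordings (negative-going "initial dip" activations, shared border drift,
pixel noise, retinotopic grids, Naka-Rushton intensity series, radially
organized elongated activations), so every stage is testable against known
ground truth.

## What it computes

**Preprocessing** (`dipmap.preprocess`). Per trial, the mean time course of
the outer 2-pixel border is subtracted to remove shared temporal noise; each
pixel is then normalized to zero mean/unit SD on the pre-stimulus ("frame 0")
window. Static maps average 1.5–2.5 s after stimulus onset. The z-score map
subtracts the blank condition's static map pixel by pixel and divides by the
blank's SD over space; ΔI/I maps follow the standard frame-by-frame,
blank-subtracted fractional-change computation. Activation = connected region
with z ≤ −3.09 on a map smoothed with a 15×15 flat kernel.

**Map statistics** (`dipmap.mapstats`). |z|-weighted center of mass;
equivalent ellipse (same normalized second central moments as the region
mask) giving extent, axis lengths, axial orientation and aspect ratio
AR = major/minor; retinotopic polar maps (per-pixel preferred azimuth /
elevation as the response-weighted centroid over the stimulus grid); expected
cortical positions from the intersection of the two cardinal polar maps;
positional error in mm and equivalent degrees; linear fits for the cortical
magnification factor (mm/°) and size tuning, with the inverse
"equivalent visual size" mapping.

**Intensity-response functions** (`dipmap.response`). Naka-Rushton fits

    R(c) = Rmax · cⁿ / (cⁿ + C50ⁿ)

with the 10–90% operational range C50·(9^(1/n) − 9^(−1/n)) and the inverse
(equivalent-luminance) mapping c = C50·(R/(Rmax−R))^(1/n).

**Retinal activation model** (`dipmap.retina`). A two-source model on an
N×N retinal grid: direct diffusion as a flat-top Gaussian around the
electrode (radius S), plus an axons-en-passant "shadow cone" component
EP = Att·Sig·Cone (attenuation with distance, a logistic gate beyond the
electrode's optic-disk distance, and an angular Gaussian in the cone angle
2·asin(S/d) around the disk-electrode axis), combined as IsoA + α·EP.
Shape metrics (radial vs tangential extent at the half-maximum contour)
quantify the model's central prediction: small electrodes produce radially
elongated activations (AR > 1), very large cone angles tangential ones
(AR < 1). Also here: the shadow-cone angle 2·asin((z/2)/y) of a stimulated
surface of diameter z at distance y from the optic disk, and the
retino-cortical transform with magnification RCM(R) = 1/(aR+b) mm/°.

**Radial-organization statistics** (`dipmap.radial`). Median axial deviation
between activation orientations and the radial directions toward a candidate
center; exhaustive grid search for the optimal radial center; a Monte-Carlo
null (uniform random orientations at the observed positions, re-optimized per
iteration); empirical and Gaussian-fit p values; center-of-mass deviation
angles relative to the radial center; and averaging of maps after centering
and rotation onto a common radial axis.

## Worked example

Run the bundled demonstration configuration (a small synthetic session;
~3 s on one core):

```bash
dipmap run --seed 1 --out runs/demo
```

which prints (abridged):

```json
{
  "magnification_fit_mm_per_deg": 0.01203272628913753,
  "median_error_mm": 0.005092714428321579,
  "naka_rushton": {
    "rmax": 0.009726380803185757,
    "c50": 6.4920877225918465,
    "n": 2.7659186452154043,
    "operational_range": 11.4341248724754
  },
  "model_ar_by_s": {"5.0": 2.1074380165289255, "30.0": 0.735},
  "radial": {
    "median_deviation_deg": 8.694267748690407,
    "null_mean_deg": 22.21387282152621,
    "null_sd_deg": 3.940042989440443,
    "p_gaussian": 0.00030030984982402833,
    "z": 3.4313344065202265,
    "com_circular_mean_deg": -179.41179844866403
  }
}
```

Reading the numbers: the magnification fitted from the measured activation
centers (0.0120 mm/°) recovers the generator's 0.012 mm/°, with a median
positional error of 5 µm — far below the blob size, as expected for
noiseless-ish synthetic data. The Naka-Rushton fit summarizes the intensity
series (semi-saturation 6.5 cd/m², operational range 11.4 cd/m²; the demo
series samples only five levels, so C50 and n are loosely constrained — the
dedicated recovery tests quantify this). The model sweep reproduces the
elongation predictions (AR 2.11 for a small electrode, 0.74 for the largest).
The radial-organization test finds the generated optic-disk representation
(median deviation 8.7° against a chance level of 22.2 ± 3.9°, z = 3.4,
p = 0.0003) and the centers of mass point away from it (circular mean −179°,
where ±180° means directly away).

Per-condition metrics land in `runs/demo/metrics.csv` (one tidy row per
condition: center of mass, extent in mm, aspect ratio, orientation,
positional error in mm and degrees); `manifest.json` records the
configuration hash and seeds so a rerun is bit-identical.

Other entry points: `dipmap model` (shape sweep only), `dipmap radial-stats
--csv sites.csv` (radial test on an activation-set CSV), `dipmap
naka-rushton --csv series.csv`.

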