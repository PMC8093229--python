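# Methods

## The measurement

Time-resolved CT angiography (4D-CTA) reconstructs the same head volume
repeatedly — here every 150 ms (bench emulation) or 50 ms (in-vivo
emulation) over a 5 s acquisition with a 0.3 s tube rotation.  Each
reconstructed stack is converted to a volume estimate of the aneurysm sac:

1. **Isotropic resampling.**  Reconstructions are anisotropic (slice
   spacing Z_v larger than the in-plane pixel X_v = Y_v).  Grey values are
   linearly interpolated along z onto a grid with spacing X_v.
   Interpolation precedes thresholding; edges are clamped to the first/last
   slice centers.
2. **Thresholding.**  One global HU threshold per series converts the grey
   volume to an occupancy grid (HU ≥ threshold → 1; the tie goes to the
   vessel).  The threshold is fixed for the whole time series — varying it
   per timepoint would confound pulsation with threshold drift.  An
   automated surrogate for visual threshold choice is provided: the
   midpoint between the median HU in a small ball at a user seed inside the
   lumen and the modal HU of the volume (the background).
3. **Sac isolation.**  Bench scheme: a crop box removes skull and
   background, and a per-slice elliptic mask that follows the parent vessel
   down the stack (re-centering on the occupied centroid inside the
   previous ellipse dilated 1.5×) removes the vessel.  In-vivo scheme:
   simple polygons on the XY/XZ/YZ plane families, each bound to a slab of
   slices; a voxel is kept iff it is inside every applicable polygon
   (even-odd rule, membership at the voxel center).
4. **Volumetry.**  Volume = N_w · X_v · Y_v · Z_v with N_w the white-voxel
   count (after resampling, spacing³ with the isotropic spacing).

On the resulting volume-versus-time curve, pulses are alternating local
maxima (zeniths) and minima (nadirs) of the *raw* samples — no smoothing,
because nadir truncation by coarse temporal sampling is a real phenomenon
the analysis must expose.  Same-type extrema closer than half the expected
period are pruned (the larger survives), then alternation is enforced.

Two amplitude definitions:

* **mode A** (bench): amplitude = zenith − following nadir;
* **mode B** (in vivo): amplitude = zenith − mean of the two adjacent
  nadirs.  For a drift linear in time the symmetric mean cancels the drift
  term exactly *when the zenith sample is equidistant from its flanking
  nadir samples* (true for symmetric periodic sampling); in general the
  residual is slope · (t_zenith − mean nadir time), bounded by half a
  sampling interval times the slope.

Summary statistics: AVP (mean amplitude), SD (sample standard deviation),
CoV = 100·SD/AVP (reported to the nearest integer percent, stored at full
precision).  Detection requires AVP ≥ a noise floor (default 3 mm³ — the
smallest amplitude unequivocally distinguishable from background noise on
the bench) *and* the median inter-zenith interval to match the driving
period (pump or heart rate) within a tolerance (default 20 %; the source
measurements give no number, so this is an implementation constant,
configurable).  Apparent pulsation failing either criterion is artefactual.

A least-squares line through (pulse pressure, AVP) pairs with r² (squared
Pearson correlation) quantifies the linearity of pulsation versus driving
pressure.  For in-vivo display, volumes in a user-chosen analysis window
are normalized by subtracting the least-squares line of the contrast
washout slope; amplitudes themselves are computed on raw volumes with mode
B, which is drift-invariant, so the window choice affects display only.

ECG support: R-peaks (synchronized to the scanner clock up to a
configurable offset) are paired zenith-by-zenith with the nearest preceding
peak; on a pulsating volume the lag is about a quarter period, and a stable
lag across pulses is the signature that apparent pulsation tracks the
heart.

## Dose accounting

Head-CT conventions: skin dose ≈ CTDI₁₀₀ = CTDI_vol × 1; effective dose =
DLP × 0.0023 mSv/(mGy·cm); DLP = CTDI_vol × irradiated length (3.84 cm =
64 × 0.6 mm slices by default).  Factors are named constants, overridable
for other body regions.  Full precision internally; 2 decimals in
summaries, 4 in tables.

## The synthetic phantom

The generator emulates the imaging side of a hydraulic bench: a spherical
contrast-filled sac whose volume follows V(t) = V₀ + (ΔV/2)·sin(2πft), a
parent vessel running along z whose centerline wanders sinusoidally in x,
and an optional bone shell, over a uniform background.  The sac radius is
solved exactly from V(t) (cube root), so ground truth is analytic.

* **Amplitude parameterization.**  ΔV is programmed directly; optionally a
  pulse pressure is mapped to ΔV through a linear compliance slope, by
  default the least-squares slope of the published bench sweep
  (≈0.181 mm³/mmHg).
* **Partial volume.**  Structure boundaries carry a linear HU ramp one
  in-plane voxel wide, so surface voxels take intermediate values as on a
  real scanner.
* **Slice-sensitivity profile.**  Each stored slice is the box average of
  the scene over its thickness (Z_v/X_v fine planes per slice by default).
  Sampling slice centers instead would alias the scene along z and distort
  downstream volumetry by several percent.
* **Reconstruction footprint.**  Each emitted volume is the boxcar average
  of the scene over the footprint T (default rotation_time/2 — the span of
  the 180° of projections entering one reconstruction), via 7 sub-frames.
  7 sub-frames keep the attenuation-law error below 1 % at 1.5 Hz: a boxcar
  attenuates a sinusoid by sinc(f·T), e.g. 0.919 at f = 1.5 Hz,
  T = 150 ms, so a programmed 10 mm³ excursion appears as 9.19 mm³ in the
  emitted samples.  This closed form is exposed by the ground-truth object
  and verified against brute-force time averaging.
* **Noise.**  White Gaussian HU noise, stationary in time, added per voxel
  after footprint averaging.  The default of 30 HU is calibrated so that a
  non-pulsating scene produces an artefactual apparent pulsation of
  0.5–1 mm³ through the full chain — the bench's observed noise floor.
  Noise also dithers the voxel-count staircase: noiseless volumetry shows a
  deterministic quantization bias of up to ±1 mm³ that disappears under
  realistic noise.
* **Contrast drift** (in-vivo emulation): the lumen HU holds a plateau for
  40 % of the scan, then decays linearly to 85 % by default — the washout
  of the iodine bolus.  An ECG can be emitted with R-peaks at the
  nadir-to-zenith upstrokes (t = k/f), with configurable clock offset and
  timing jitter.
* **Defaults.**  Sac baseline 310 mm³ (the volume of the imaged patient
  aneurysm; the bench sac's true volume is not published, so this is a
  documented, configurable choice), lumen 300 HU, background 30 HU, bone
  1200 HU, pump 1.5 Hz, voxels 0.45×0.45×0.6 mm.  The vessel is tangent to
  the sac by default (`vessel_gap` = 0); tests that need the elliptic mask
  to leave the pulsating surface untouched use a 1.5 mm gap, since the
  tracked ellipse's 1.5× search region would otherwise overlap the sac and
  pull the mask into it (on the real bench this neck bias is part of the
  measurement; amplitude, being differential, is largely insensitive to
  it).

## Problem sizes and numerical choices

Quantitative recovery tests run at 0.25 mm in-plane spacing on a
96×96×56 grid: `rasterized_volume_error` puts the voxel-counting error of
the 4.2 mm sac below 0.5 % there, and the residual staircase noise
(±0.3 mm³) is small against the tolerance of the recovery checks.  Unit
tests use smaller scenes (~50 mm³ sac on 64³-scale grids).  Under the bench
conditions (1.5 Hz, 150 ms sampling, ~4.4 samples per period) zenith/nadir
truncation attenuates recovered AVP by ~8 % relative to the
footprint-corrected truth; at 50 ms sampling this drops below 1 % — the
motivation for the faster in-vivo reconstruction interval.

Tie-breaks and conventions: HU exactly at the threshold counts as vessel;
voxel membership in masks is decided at the voxel center; between two
same-type extrema the more extreme survives; mode A pairs each zenith with
the nadir that follows it; the in-vivo analysis window is user-specified
(an automatic longest-downward-slope helper is deliberately not the
default, since window choice is an inspection step).

## What passing tests do and do not show

The phantom has sharp two-level contrast, stationary white noise, a
perfectly periodic driver and no patient or table motion.  Passing
recovery tests therefore demonstrates that the *analysis chain* is
unbiased at bench-like contrast and noise — not that segmentation is
robust to beam hardening, motion, inhomogeneous contrast filling or
threshold mis-choice on real scans.  Known limitations: no registration or
motion correction; a single global threshold (adaptive thresholding is out
of scope); polygon masks combine across planes by intersection (the
in-vivo masking procedure's combination rule is an interpretation); the
period criterion on noise-driven extrema is shaped by the half-period
separation rule, so artefactual series are mostly rejected by the
amplitude floor rather than the period mismatch.
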