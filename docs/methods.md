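# Methods

`myofq` quantifies the morphology of fibrillar flight muscle from two classes
of fluorescence micrograph: longitudinal views, where myofibrils appear as
parallel striped bands, and transverse cross-sections, where each myofibril
appears as a bright disk.  This note records the measurement models, the
numerical choices behind them, and what the synthetic phantoms do and do not
establish.

## Measurement models

### Sarcomere repeat (lengthwise)

Striations are periodic along the fibril axis, so the repeat is read from the
power spectrum.  Each micrograph is rotated so fibrils run horizontally
(automatically, from the orientation of spectral power; a manual override is
available), its central region is tiled into nine non-overlapping regions of
interest (ROIs), and per ROI the image is mean-subtracted, Hann-windowed per
row, 2-D Fourier transformed, and the power averaged over all vertical
frequencies.  The repeat is the reciprocal of the dominant horizontal
frequency inside a configurable period band (default 1–5 µm, bracketing all
reported developmental stages at 1.8–3.5 µm), refined to sub-bin precision by
parabolic interpolation of the log-power through the three bins around the
argmax.

Because Z-discs are rendered (and stained) as narrow bright bands, their
spectral harmonics decay slowly, and the raw argmax can land on the second
harmonic when window scalloping penalises a fundamental that does not divide
the ROI width — the octave error familiar from pitch detection.  The
estimator therefore steps down to half the chosen frequency whenever a
genuine local spectral maximum with at least one third of the chosen peak's
power lies there, and repeats until no such subharmonic exists.  The
local-maximum requirement prevents the monotone leakage skirt of a strong
low-frequency component from triggering a spurious step-down.

Each ROI also reports a prominence score (peak power over median in-band
power) and an on-band-edge flag; ROI failures are recorded and the summary is
taken over surviving ROIs (at least five required).

### Myofibril width (lengthwise)

The width is the lag of the first local minimum of the vertical intensity
profile of the image autocorrelation.  For stripes of width w repeating every
s, this minimum sits at lag w exactly when the duty cycle w/s is 50%; the
duty-cycle dependence is a property of the estimator itself (demonstrated in
the test suite) and the reading should be interpreted as a transverse period
scale, comparable across conditions imaged at similar fibril packing.  The
value is the minimum's lag itself, not a half-width — the literal definition
of this autocorrelation statistic.

The autocorrelation is circular (computed through the power spectrum after
mean subtraction, normalized to 1 at zero lag).  Circularity introduces an
O(1/n) wrap-around distortion when the frame holds a non-integer number n of
transverse periods; at 2.5 periods per ROI we measured a bias of about one
pixel for 1.5 µm fibrils.  ROIs should therefore contain at least ~4
transverse periods for pixel-accurate width readings; recovery tests use
512-row frames for this reason.  A linear (zero-padded) dialect halves the
residual at the cost of breaking the exact unit normalization and symmetry
bounds, and is deliberately not exposed.

### Myofibril diameter, count and density (crosswise)

1. *Scale estimate d0*: first local minimum of the radially averaged
   autocorrelation of the full image.  This mixes disk size and packing
   distance and is used only to calibrate the later steps (smoothing σ =
   d0/4, peak separation 0.8·d0, crop side 2·d0); when the radial profile is
   monotone, a configured fallback (default 1 µm) is used and flagged.
2. *Detection*: local maxima of the Gaussian-smoothed image, keeping the
   brighter of any pair closer than the minimum separation, discarding
   maxima dimmer than median + 3·MAD and maxima within one crop halfwidth of
   a border.  The median and MAD are computed on the **raw** image and the
   threshold applied to the smoothed one: raw MAD reflects the pixel noise
   amplitude, whereas the MAD of the smoothed image is so small that
   thousands of smoothed background maxima would pass a threshold derived
   from it.
3. *Template averaging*: equal-size crops around every detected centre,
   each recentred (integer shifts) on its intensity centroid within d0/2 to
   remove detection jitter, are averaged into a noise-free template.  The
   residual template noise falls as 1/√N in the number of crops.
4. *Diameter*: the template's radial intensity profile (polar resampling,
   0.25 px radial step, 180 rays, bilinear interpolation) is measured where
   it first crosses min + 0.26·(max − min) downward, with linear
   interpolation between radial samples; the diameter is twice that radius.
   A dialect flag (`range_anchor="zero"`) anchors the threshold at zero
   (26% of the absolute maximum) instead; the two coincide when the profile
   floor is zero.

Density is the detected count divided by the border-margin-excluded search
area, so undetectable near-border disks do not deflate the estimate.

### Derived quantities

Sarcomeres per fibril = fiber length / sarcomere length; fibrils per fiber =
areal density × fiber cross-sectional area; bead-normalized fluorescence =
mean of three fiber ROI intensities / mean of three bead ROI intensities.
All are exact formulas; rounding is left to presentation.  Box summaries use
quartiles by linear interpolation between order statistics (the common
plotting-package convention) with whiskers at the most extreme data point
within 1.5 IQR of the quartiles.

## The phantom generator

Phantoms emulate the two image classes with known ground truth: parallel
fibrils with bright Z-lines every repeat (rectangular or Gaussian transverse
profile, configurable Z-disc contrast, default 50% duty cycle), and
dart-thrown disk packings with a minimum separation.  Both are blurred with
an isotropic Gaussian PSF (default σ 0.15 µm lengthwise / 0.10 µm crosswise,
approximating a high-NA confocal at 50 nm/px) and sampled with Poisson shot
noise (default photon peak 50) over a constant background (default 5) —
an adequate model for photon-limited confocal imaging.  Generation is
bit-reproducible under a fixed seed and the ground-truth record suffices to
re-render the image exactly.

**Diameter convention.**  A fluorescent cross-section has no sharp geometric
edge, and a blurred disk's intensity at its geometric edge sits near 45–50%
of the profile range — so a 26%-of-range full width is an *operational*
diameter definition, about 0.6·σ_psf outside the geometric edge per side.
The phantom's `disk_diameter_um` therefore uses the same operational
definition the measurement reports: the generator inverts the analytic
forward model of a blurred disk (its radial profile is a noncentral-χ²(2)
CDF in the squared radius) to find the tophat render radius whose blurred
blob has the requested 26%-of-range width.  With zero blur the convention
coincides with the geometric diameter.  Recovery tests therefore validate
detection, averaging, recentring, profile extraction and threshold crossing
— everything except the threshold convention itself, which is a definition
rather than an estimate.

**What phantoms do not show.**  Real micrographs have spatially varying
background, out-of-focus haze, fibril curvature and packing disorder,
non-circular cross-sections, and detector read noise; none of these are
modelled.  Passing recovery tests demonstrates the correctness of the
numerics under the stated noise model, not field performance on arbitrary
tissue.

## Numerical choices and degenerate inputs

- Mean subtraction precedes every transform, so the DC term cannot mask
  minima or peaks, and all outputs are invariant under affine intensity
  rescaling a·I + b (a > 0).
- Sub-sample refinement (minima and peaks) is parabolic through three
  samples, vertex offset clipped to ±0.5 samples; ties break toward smaller
  lag / lower frequency for determinism.
- Radial averaging of autocorrelation maps uses 1 px annular bins (means
  over pixels whose distance falls in the bin; empty bins dropped); template
  profiles use polar resampling instead, which is smoother at sub-pixel
  radii.  The two routes are cross-checked against each other in tests.
- Constant images raise a degenerate-input error; monotone profiles raise a
  no-minimum error (the crosswise d0 stage converts this into a flagged
  fallback); an empty detection set raises an error carrying the threshold
  diagnostics.
- Scale equivariance: with identical pixel data, multiplying the pixel size
  by c scales every reported µm quantity by c and every frequency by 1/c,
  exactly, provided physical-unit parameters (bands) are scaled too.  The
  automatic orientation step carries a fixed physical-unit search band, so
  strict equivariance holds when rotation is pinned.

## Problem sizes

Recovery tests use 512×1024 px lengthwise phantoms (nine 153×307 px ROIs)
and 1024²–2048² px crosswise phantoms with 40–400 disks; the headline
recovery script uses 300 disks at 2048².  These sizes give sub-pixel
recovery while keeping the full suite to a few minutes on one CPU.

## Known limitations

- The width reading is duty-cycle dependent (exact only at 50% duty).
- The repeat band and the subharmonic rule assume one dominant periodicity;
  mixtures of stages within one field are not resolved.
- d0 is a heuristic scale, not a measurement; results are insensitive to it
  only within roughly a factor of two (crop and separation factors are
  exposed in configuration).
- Fiber outlines (for cross-sectional area) are not segmented; area is an
  input to the derived quantities.
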