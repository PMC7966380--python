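# Methods

This note documents the models, conventions and numerical choices behind
`tipkit`, including where the design was genuinely open and what the
synthetic generator does and does not establish.

## Coordinate and intensity conventions

Images are `(row, col)` arrays with origin at the top-left; geometry uses
`x = column`, `y = row`, angles measured from the +x axis.  All
intensities are normalized to `[0, 1]` at ingest (integer frames divided
by their dtype maximum).  Geometry is kept in pixels with a `pixel_pitch`
(mm/px) for physical-unit reporting; the default pitch of 0.2 mm/px makes
a 4 mm intestine span 20 px.

## Synthetic transillumination scenes

A frame is composed in a canonical (body-fixed) frame and evaluated at
inverse-transformed pixel coordinates, so rigid poses are exact and free
of interpolation artifacts:

1. background at `background_level` (0.08), an illumination disk at
   `illum_level` (0.9), an elliptical mouse body at `mouse_level` (0.45)
   occupying ~6% of the sensor area;
2. tube attenuation `exp(-mu * chord)` where `chord(r) = 2 sqrt((d/2)^2 -
   r^2)` is the light path through a cylindrical absorber of local
   diameter `d(s, t)` at lateral distance `r` from the centerline.
   `mu = ln(5)/4 per mm` so a resting 4 mm intestine attenuates ~80%.
   Beer–Lambert through the chord is the standard physical choice; its
   one observable consequence is that shadow FWHM is slightly below the
   geometric bore (≈95% at 4 mm, ≈89% at 0.5 mm);
3. Gaussian scattering blur (σ = 1.2 px) and additive Gaussian sensor
   noise, clipped to `[0, 1]`.

### Motor patterns

The local diameter is `d(s, t) = d0 - (d0 - dc) * env(s, t)` with
`d0 = 4 mm` resting and `dc = 0.25 * d0` fully contracted, `env` clipped
to `[0, 1]`:

- **Peristalsis** — a raised-cosine contraction bump (half-width 2 mm)
  travels at `wave_speed` (default 0.25 mm/s, giving a 30 mm transit in a
  120 s window) and wraps at the centerline length.
- **Segmentation** — contraction sites sit every `site_spacing` (6 mm),
  inset half a spacing from the ends.  Even-indexed sites (the flanking
  pair) carry the temporal envelope `(1 + cos 2πft)/2` and odd-indexed
  (in-between) sites `(1 - cos 2πft)/2`, so the flanking pair is
  contracted at phase 0 and the in-between site at phase ½, completing
  one cycle per `1/f` — the classic alternating sequence.  The sinusoidal
  envelope makes each site's signal spectrally concentrated at `f`.
- **Mixed** — the pointwise maximum of both envelopes.

The shape of real contractions is not parameterized by any published
measurement; the raised cosine is a smooth single-lobe stand-in.

## Silhouette extraction and rigid registration

The binarization loop follows the descending-threshold scheme: starting
at τ = 1 and stepping by 0.005, binarize (≥ τ), complement, label with
8-connectivity, and stop at the first τ where the second-largest
component (the largest is the poorly illuminated region outside the
illumination disk) reaches 5% of the sensor area.

Two numerical hardenings were necessary and are on by default:

- a 3×3 binary opening of the complement before labeling, suppressing
  sensor-noise speckle;
- a **threshold back-off**: the stopping τ necessarily sits immediately
  below the illumination level, in the shallow tail of the
  body-to-illumination edge where the intensity gradient (≈0.01/px) is
  comparable to sensor noise.  The selected component is therefore
  re-extracted at τ − 0.05 (keeping the overlapping component), moving
  the mask boundary onto the steep part of the edge.  Without this, at
  the generator's default noise (σ = 0.02) noise blobs attach to the mask
  and orientation errors of several degrees occur; with it, pose recovery
  is ≤0.9° and ≤0.8 px even at twice the default noise.

Orientation comes from the eigen-decomposition of the convex hull's
second-order central moment matrix (per-pixel normalized); the major-axis
angle θ is mapped to [0, 180).  The hull uses pixel-center coordinates
(`offset_coordinates=False`), which makes hulling exactly idempotent.
Registration rotates by (90° − θ) about the image center and translates
the rotated centroid onto the rotated first-frame (anchor) centroid; both
steps are fused into a single bilinear resampling with zero fill.  The
180° axis ambiguity is unwrapped along the sequence (adjacent frames may
not flip head-to-tail); head/tail identity itself is not resolved —
the real system disambiguates with painted markers in hardware.  Frames
with no valid silhouette get poses interpolated from neighbors and are
flagged; frames whose hull eccentricity falls below 0.8 are flagged as
"bent" for similarity-based processing.

## Spatial-temporal maps

CLAHE (8×8 tiles, clip limit 0.01 — unpublished in the source method,
chosen as mild) precedes profile extraction.  The centerline is
arc-length resampled to ~1 px spacing; normals are tangents (central
differences) rotated +90°, all with one fixed length `L` chosen to cover
the intestine cross-section (default 40 px = 8 mm).  Profiles are
bilinearly sampled at unit spacing over `[-L/2, +L/2]` (L+1 samples);
out-of-frame samples are zero.

Maps store contrast-agent **absorbance** (1 − intensity), so relaxations
(more absorber in the cross-section) are high and contractions low.  A
single Otsu threshold over the whole profile stack removes low-amplitude
background before averaging over offsets (averaging, not summation, so
values are stable across normal lengths).  The 2×2 median filter defines
the median of four as the mean of the two middle values, with
edge-replicated borders; it is idempotent on constants and never widens
the value range.

## Frequency analysis and statistics

The cross-section series (mean of a row range per time column) is
detrended (mean + linear), Hann-windowed, and the magnitude spectrum
maximized over a band of 0.1–2.0 Hz — bracketing both reported
physiological rates.  Resolution is one bin, `frame_rate/n` (1/60 Hz for
a 60 s recording).  Preconditions: the frame rate must exceed twice the
band top, and the series must span at least two periods of the band
bottom.

The group comparison is the two-sided Wilcoxon rank-sum test, exact by
full enumeration of all C(n+m, n) rank assignments for min(n, m) ≤ 8
(ties mid-ranked, p = 2·min(lower tail, upper tail) capped at 1), and a
tie-corrected normal approximation above.

## Phantom metrics

Tube phantoms render the Beer–Lambert chord shadow of a straight tube;
scattering **below** the tube (camera side) blurs the shadow (σ grows
0.25 mm per mm of agar), scattering **above** only rescales intensity —
reproducing the two validation modes: contrast `(A_b − A_t)/A_t` decays
strictly with below-tube depth, while FWHM is unchanged by above-tube
depth.  The FWHM baseline is the median of the outer 20% of samples;
crossings are linearly interpolated.  `A_t` is the mean amplitude inside
the FWHM interval.

## Motor-pattern discrimination

A traveling band concentrates the 2D spectral energy of the
(position × time) map in one diagonal quadrant pair; a standing rhythm is
quadrant-symmetric.  The classifier therefore uses the signed quadrant
asymmetry of the 2D power spectrum (after removing each row's temporal
mean), thresholded at |asymmetry| > 0.3.  This is the Fourier-dual form
of the "autocorrelation peak off the time axis" criterion; the raw
autocorrelation argmax is ambiguous for alternating standing patterns,
whose antiphase sites put a genuine peak at (Δs = site spacing,
Δt = half period).  Measured asymmetries are ≈0.9 for peristalsis and
≈0.01 for segmentation — a wide margin.

## Long recordings and dual color

Frame similarity is the Pearson correlation of 4×-block-averaged frames
against the current epoch's first frame; a drop below 0.8 (both defaults
declared, not inferred from any publication) starts a new epoch and
resets the reference.  Epochs shorter than a minimum length merge
forward.  Per-epoch maps (each with its own centerline, since the
intestine profile changes with posture) are stitched column-wise.  With
no pose change the trace stays at 1, one epoch results, and the stitched
map equals the plain map exactly.

Dual-color streams are routed by per-frame wavelength label; each
channel's rate is the acquisition rate times its frame share (2 Hz
alternating → two 1 Hz channels).  Overlays normalize each channel's
absorbance separately into fixed color planes (channel 1 → red); overlay
pairing picks the nearest-in-time partner, ties to the earlier frame.
Cross-talk unmixing is not applied.

## Light field

The lenslet grid is square and axis-aligned; `pitch` is both the lenslet
pitch in sensor pixels and the angular sample count.  The forward model
is a pinhole array: a source at depth z lands in sub-aperture (u, v) at a
lateral offset `slope_per_mm · z · (u − u0, v − v0)` lenslets, so an
in-focus source occupies one lenslet and off-focus sources spread with
|z|.  Shift-and-add refocusing inverts that shift with bilinear
interpolation ('nearest' border mode keeps the interior mean conserved
within 1%); at slope 0 it reduces exactly to the plain sub-aperture mean.
The depth-to-slope calibration is a configuration input — the hardware
calibration procedure is out of scope.  No deconvolution is applied.

The depth index is the argmax over focal-stack slices of the local
variance in a 5×5 window (the estimator in the source system is
unpublished; local contrast is polarity-agnostic and standard).
Confidence is the sharpness peak-to-mean ratio over depth; pixels below
1.5 are masked as featureless.  Lateral/axial kymographs sample the
in-plane normal on the best-focus slice and the depth axis over the same
span, then reduce identically, so their amplitudes are directly
comparable.

## What the synthetic world does not establish

The generator emulates scene geometry, absorption, first-order scattering
blur and sensor noise.  It does **not** model non-rigid body deformation,
breathing, tissue heterogeneity, spectral absorption curves, wave-optics
PSFs, or the in-vivo variability behind the reported group statistics
(n = 5 animals per condition); green recovery tests establish pipeline
correctness on the stated world, not biological effect sizes.  Physical
resolution figures (99.2 µm lateral in 2D, 0.5 mm / 4 mm at 3 mm depth in
3D) are hardware facts and are not claimed by this software.
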