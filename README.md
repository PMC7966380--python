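# tipkit

Analysis pipeline for **transillumination intestine projection (TIP)
imaging** of gut motility in mice.  In this modality, near-infrared light
shone through the abdomen is recorded by a camera on the far side; an
orally administered high-absorbing contrast agent makes the intestinal
lumen cast a shadow, so intestinal motor patterns — propagating
**peristalsis** and stationary, pacemaker-driven **segmentation** — can be
imaged noninvasively, including in awake, freely moving animals.

`tipkit` implements the computational side of this experiment for
researchers in GI motility and biomedical imaging:

- **Synthetic scene generation** with exact ground truth (illumination
  disk, mouse silhouette, Beer–Lambert tube absorption, traveling-wave and
  standing-contraction diameter dynamics, scattering blur, sensor noise) —
  every downstream stage is testable without animal data.
- **Rigid registration** of free-moving-mouse video.  The body silhouette
  is extracted by iterative thresholding (threshold lowered from 1 in
  steps of 0.005 until the second-largest dark component reaches ~5% of
  the sensor area), its convex hull's second-order central moments give
  the covariance matrix

  cov = [[μ′xx, μ′xy], [μ′xy, μ′yy]],   μ′xx = Σ(x − x̄)²/N, …

  whose principal eigenvector defines the body angle θ; each frame is
  rotated by (90° − θ) and translated so the hull centroid lands on the
  first-frame anchor.
- **Spatial-temporal (kymograph) maps**: CLAHE enhancement, minimal
  amplitude projection, cross-section profiles along the unit normals of
  a user-drawn intestine centerline, Otsu suppression of low-amplitude
  signal, offset-averaging and 2×2 median smoothing.  Rows are intestine
  positions, columns time; contractions appear as low-absorbance spots
  (standing rhythm) or sloped bands (propagation).
- **Motility metrics**: Hann-windowed spectral peak of a cross-section
  series, exact two-sided Wilcoxon rank-sum comparison, phantom contrast
  (A_b − A_t)/A_t, profile FWHM and FWHM-based diameter change, and a
  propagating-vs-standing motor-pattern classifier.
- **Long recordings**: Pearson frame-similarity segmentation into
  behavior epochs and column-wise stitching of per-epoch maps.
- **Dual-color imaging**: demultiplexing of alternating-wavelength
  acquisitions and per-channel absorbance overlays.
- **Light-field 3D**: lenslet mosaic decoding, shift-and-add refocusing,
  focal stacks, per-pixel depth-index maps, and lateral/axial kymographs
  of the same intestine.

## Worked example

Generate a motion-free (anesthetized-like) segmentation recording at the
physiological 0.380 Hz rate and recover the frequency through the full
kymograph pipeline:

```python
from tip.pipelines import recover_frequency_anesthetized, measure_diameter_ratio

rec = recover_frequency_anesthetized(frequency_hz=0.380, seed=43, duration=30.0)
print(f"recovered {rec.recovered_hz:.3f} Hz  (generated at {rec.true_hz} Hz, "
      f"spectral bin {rec.bin_width_hz:.4f} Hz, {rec.n_frames} frames)")

out = measure_diameter_ratio()
print(f"contracted/resting FWHM ratio {out['ratio']:.3f}  "
      f"(diameter change {out['change']:.3f})")
```

prints

```
recovered 0.367 Hz  (generated at 0.38 Hz, spectral bin 0.0333 Hz, 450 frames)
contracted/resting FWHM ratio 0.236  (diameter change 0.764)
```

The recovered peak sits within one spectral bin (frame_rate/n = 1/30 Hz)
of the generated rhythm; the phantom FWHM ratio recovers the generator's
25% contracted fraction (a 75% diameter change of the 4 mm resting
intestine), slightly below 25% because the shadow of a cylindrical
absorber is the Beer–Lambert exponential of the chord length, not a
top-hat.

The same stages are scriptable from the shell:

```sh
tip simulate --pattern segmentation --freq 0.772 --duration 60 --seed 42 --out scene/
tip register --in scene/scene.tif --out scene/reg.tif
tip stmap    --in scene/reg.tif --curve scene/centerline.csv --normal-len 40 --out scene/map.tif
tip frequency --map scene/map.tif --rows 10:20 --band 0.1:2.0 --out scene/freq.json
```

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
regenerates the synthetic worlds from scratch and recomputes, end to end:
the segmentation frequency recovered by the full free-moving pipeline
(registration → kymograph → spectral peak) from a 60 s recording generated
at 0.772 Hz under scripted rigid motion; the frequency recovered from a
motion-free recording generated at 0.380 Hz; and the contracted-to-resting
diameter ratio (in percent) measured by FWHM on noiseless tube phantoms.
Results are written as JSON keyed `t1`, `t2`, `t4`.
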