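# Methods

This document records the scene model, the analysis procedures, the default
parameters (with units and rationale), and the numerical choices made in the
implementation. The synthetic generator and the estimators are deliberately
independent: the generator writes shadows pixel-by-pixel from geometry, while
the estimators only ever see rendered images, so agreement between estimate
and ground truth is informative.

## 1. Synthetic scene model (`stripeflick.scene`)

A scene is a field of view (default 128×128 px) imaged at `frame_rate`
(default 44 Hz) containing:

* **Cells** — `n_cells` circular somata (radius `cell_radius` = 3 px) placed
  uniformly at random without overlap. Each cell fires a homogeneous Poisson
  spike train (`spike_rate`, default 0.1 Hz — sparse spontaneous activity).
  Spikes are convolved with a double-exponential calcium-indicator kernel
  (rise τ = 0.1 s, decay τ = 1.5 s, amplitude A = 0.5 dF/F per spike,
  matching a slow nuclear indicator). The resulting fluorescence factor
  multiplies the cell's resting brightness `baseline_F` (400 counts) on top
  of a diffuse background (`background_F` = 100 counts).
* **Latent signals** — optional region-level drives. A `LatentSignal`
  assigns a shared spike train to all cells inside a region mask with mixing
  weight *w*: each cell's train is a superposition of a thinned copy of its
  private train and the shared train, so the expected pairwise correlation
  within the region is controlled by *w*. Ground truth exposes the
  region-mean fluorescence factors and their correlation matrix.
* **Vessels and absorbers** — each vessel is a line path near the
  illumination-proximal side of the plane (blood vessels run along the brain
  surface, i.e. close to where the sheet enters). Absorbers (red-blood-cell
  proxies, height `absorber_height` = 8 px, attenuation 0.6) enter at rate
  `absorber_rate` (1.5 /s) and translate along the path at `absorber_speed`
  px/frame. Their per-frame positions are recorded as ground truth.
* **Static obstacles** — fixed rectangles `(row, col, height, attenuation)`.

### Shadow rendering

Illumination propagates along +columns. A blocker of height *h* at
(row, col) attenuates all pixels in its rows to the right of it:

* **Gaussian**: the shadow extends to the distal image border at the full
  attenuation.
* **Bessel**: the shadow extends only over the self-reconstruction length
  `x = h / (2 tan β)` (β = `cone_angle_beta` = 0.12 rad) and its depth is
  scaled by `bessel_contrast` = 0.3 — the beam's ring system both shortens
  and shallows the shadow.

Shadows from overlapping blockers multiply. An optional Gaussian blur
(`shadow_blur_sigma`, default 1 px) softens shadow edges. Photon shot noise
uses the exact Poisson law below 20 expected counts and a Gaussian
approximation above; Gaussian read noise (`read_noise_sd` = 2 counts) is
added last. The same random-number stream is used for both modalities of one
scene, so a noise-free Bessel render is pixelwise ≥ its Gaussian partner.

Ground truth includes per-modality **flicker truth masks**: the union over
frames of all moving-absorber shadow footprints, which is the quantity the
flicker estimator targets.

## 2. dF/F extraction (`stripeflick.traces`)

1. ROI mean per frame. ROI membership uses the centre-of-pixel rule:
   pixel (r, c) belongs to the ROI iff its centre lies within the radius.
2. Optional background subtraction from a cell-free background ROI.
3. Baseline F₀: within each moving window (`window_frames` = 200,
   `step_frames` = 100) take the `quantile` = 0.10 of the trace; anchor that
   value at the window centre; add a flush-right window so the trace end is
   covered; interpolate anchors with a monotone PCHIP spline; clamp to the
   first/last anchor value beyond the anchor range (no extrapolation
   overshoot).
4. dF/F = (F − F₀)/F₀. Non-positive baselines raise an error listing the
   offending frames rather than producing silent infinities.
5. Temporal averaging: non-overlapping block means, factor 8 (44 → 5.5 Hz),
   dropping the trailing partial block.

The quantile baseline is valid when rest periods dominate each window; for
densely active traces the window must be lengthened or the quantile lowered
(the end-to-end test uses window 600 / step 300 / quantile 0.05 at 44 Hz for
exactly this reason).

## 3. Static-striping quantification (`stripeflick.striping`)

Row-mean line profiles of the Gaussian and Bessel images are each normalised
to mean 1 over the analysed rows, removing overall brightness differences. A
row is *affected* when the absolute profile difference exceeds a threshold θ
(default 0.05, i.e. 5% of mean brightness); the bar code is the boolean row
vector and the affected fraction is its mean. `threshold_sweep` reports the
fraction over a θ grid (non-increasing in θ by construction), and
`proximal_distal_split` computes the fraction separately for the
illumination-proximal and distal halves of the mask's column extent.

## 4. Flicker quantification (`stripeflick.flicker`)

The chain operates on a Gaussian/Bessel stack pair:

1. **STD time-lapse** — per-pixel standard deviation over non-overlapping
   windows (window 5, step 5 frames), turning temporal modulation into
   brightness.
2. **Joint rescale** — min–max rescale to [0, 1] computed jointly over the
   pair, preserving the between-modality ordering.
3. **Enhancement** — gamma 1.1; difference-of-Gaussians bandpass retaining
   structures between 3 and 40 px (the small/large sizes are divided by 2 to
   become the DoG sigmas, the conventional size-to-sigma mapping); local
   variance filter of radius 2 px, which squares contrast and suppresses the
   smooth residue.
4. Second joint rescale, then **STD z-projection** of each enhanced stack to
   one image per modality, then a final joint rescale of that projection
   pair.
5. **Threshold** at 0.20 and label 8-connected particles.
6. **Box extension** — each particle's bounding box is extended along the
   illumination axis: for Gaussian to the full column extent of the analysis
   mask at the box's rows (shadows persist to the border); for Bessel by the
   reconstruction length `x = h / (2 tan β)` with *h* the box height.
7. **Affected fraction** = |union of extended boxes ∩ mask| / |mask|.

### The reconstruction-length formula

The physically meaningful relation is `x = h / (2 tan β)`: a taller obstacle
or a narrower cone angle lengthens the shadow. The literal transcription
`x = tan β · h/2` (dimensionally suspect — it would make wider cones cast
*longer* shadows) is available behind `form="literal"` for comparison; the
physical form is the default everywhere. The result is `ceil`ed to whole
pixels with a 1 × 10⁻⁹ slack so that values like 5.000000000001 arising from
float tangent evaluation do not round up spuriously.

## 5. Noise statistics (`stripeflick.stats`)

The baseline-noise model is multiplicative: for a trace *v* with mean μ,

```
noise = 1 + σ·ε,  ε ~ N(0, 1) i.i.d.
y = (v − μ) · noise
```

Consequences used in the tests and the acceptance script:

* recovered std of a flat-baseline dF/F trace ≈ σ;
* variance inflation: Var(y) = Var(v)·(1 + σ²);
* correlation attenuation: E[r_noisy] ≈ r / (1 + σ²) for equal σ on both
  channels, so the bias grows with σ and the Gaussian-level noise
  (σ = 0.1965) attenuates far more than the Bessel-level noise (σ = 0.0390).

`corr_bias_accuracy` replicates the injection `n_rep` times with an internal
seeded stream, pools the (noisy − clean) correlation differences over pairs ×
replicates, and reports their mean (bias) and std (accuracy).

**Peak counting**: traces are smoothed with a Savitzky–Golay filter
(polynomial order 5, window 7 samples) and peaks are kept when their
topographic prominence exceeds 0.085 dF/F; the rate is reported in
peaks/min. The prominence floor should be raised to the noise amplitude in
use — counting with a fixed floor under larger noise counts noise
excursions, not events.

`paired_t` wraps the paired *t*-test with two guarded edge cases: identical
inputs return (0.0, 1.0); a constant non-zero difference (zero variance) is
an error rather than an infinite statistic.

## 6. Regional PCA (`stripeflick.pca`)

Image-space preprocessing for pixelwise PCA: temporal block averaging by 10
(44 → 4.4 Hz), 2×2 spatial binning, 8-bit min–max conversion, integer
translation registration to a reference frame via phase cross-correlation
(zero-variance frames short-circuit to zero shift).

Trace-space regional PCA: SVD of the mean-centred cell × time matrix of one
region. Sign convention: the loading of largest magnitude is made positive,
removing the SVD sign ambiguity. `top_contributors` returns the
ceil(10%·n) cells with largest |PC1 loading| (ties broken by cell id);
`corr_spread_map` is the per-cell std of its correlations with all partners;
`between_region_pc_corr` is the Pearson correlation of two regions' PC1 time
courses. On scenes with a shared latent drive at weight 0.85, PC1 recovers
the drive and the between-region correlation is high (≈ 0.97); multiplicative
baseline noise attenuates it only by ≈ 1/(1 + σ²).

## 7. Numerical choices

* **STD residue guard** — the windowed std of numerically identical frames
  leaves float residue (~10⁻¹⁴) which a joint min–max rescale would amplify
  to full scale. `std_timelapse` zeroes stds below 10⁻⁹ × |window mean|;
  the relative threshold preserves invariance under global gain.
* **Ceil slack** — see §4; `max(ceil(x − 10⁻⁹), 0)`.
* **DoG mode** — `skimage.filters.difference_of_gaussians` with its default
  `nearest` boundary handling.
* **PCHIP, clamped** — monotone piecewise-cubic interpolation avoids the
  overshoot of cubic splines on quantile anchors; values beyond the anchor
  range are clamped, never extrapolated.
* **Trace CSV precision** — `%.8g`; round trips are exact to ~10⁻⁷ relative,
  and the frame rate is recovered from the median time step.
* **Seeding** — every stochastic routine takes an explicit seed or
  `numpy.random.Generator`; scenes derive their stream from
  `SeedSequence([seed, constant])` so the same seed yields the same scene
  for both modalities.

## 8. Generator scope and limitations

The generator emulates the *geometry and statistics* of single-beam
light-sheet artifacts, not optics:

* Shadows are ideal attenuation wedges along the illumination axis; there is
  no diffraction, refraction, scattering anisotropy, or depth-dependent sheet
  thickness. The Bessel ring-system background is summarised by a single
  contrast factor (0.3) rather than modelled.
* Absorbers move at constant speed along straight vessel paths; real
  capillary flow is pulsatile and vessels are curved.
* The indicator model is linear (spike → kernel superposition) with no
  saturation, bleaching or motion.
* Scene sizes, frame counts, cell densities and vessel placements used in the
  tests and in `scripts/acceptance.py` are this package's own validation
  choices, sized so the full suite runs in well under a minute per stage.
  Two of those choices deserve note: validation scenes use *dense* cell
  coverage (shadow detection relies on illuminated structure behind the
  absorber — rows of empty background carry too little signal through the
  variance filter), and vessels sit near the illumination-proximal edge, as
  surface vessels do, which is also where the Gaussian full-extent box
  extension is a good model.
* The measured baseline-noise levels (19.65% and 3.90% dF/F) are treated as
  empirical inputs to the noise model, not quantities the generator derives.
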