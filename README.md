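# stripeflick

Quantify illumination artifacts in single-beam light-sheet calcium imaging —
static striping and hemodynamic flickering — and measure what those artifacts
cost downstream functional analysis. The package ships a seeded synthetic-scene
generator with exact ground truth, so every estimator can be validated against
numbers that are known by construction.

## The problem

In a digitally scanned light-sheet microscope a single beam illuminates the
sample from one side. Anything absorbing in the beam path (pigment, tissue,
red blood cells) casts a shadow along the illumination axis:

* **Static striping** — fixed absorbers darken entire image rows behind them,
  producing a stationary stripe pattern.
* **Hemodynamic flickering** — red blood cells moving through vessels cast
  *time-varying* stripe shadows. On a calcium reporter this masquerades as
  neural activity: it inflates baseline noise, buries small transients and
  decorrelates simultaneously recorded cells.

A Bessel beam self-reconstructs after an obstacle within a distance

```
x = h / (2 tan β)
```

where `h` is the obstacle height and `β` the half-angle of the Bessel cone, so
its shadows are short line segments instead of full streaks. The package
quantifies both artifacts from Gaussian/Bessel image pairs and propagates the
residual noise into trace statistics (event rates, pairwise correlations,
regional PCA).

## What it provides

| module | purpose |
|---|---|
| `stripeflick.scene` | synthetic scenes: spiking cells, vessels with moving absorbers, static obstacles, modality-specific shadow rendering, exact ground truth |
| `stripeflick.traces` | ROI extraction, moving-quantile baseline (PCHIP-interpolated), dF/F, temporal averaging |
| `stripeflick.striping` | normalised line profiles, bar-code of affected rows, threshold sweep, proximal/distal split |
| `stripeflick.flicker` | STD time-lapse → enhancement (gamma, difference-of-Gaussians bandpass, variance filter) → particle detection → modality-specific box extension → affected-area fraction |
| `stripeflick.stats` | multiplicative noise injection, baseline-noise recovery, prominence-based peak counting, correlation bias/accuracy, paired *t* |
| `stripeflick.pca` | stack preprocessing (temporal averaging, binning, 8-bit, translation registration), regional PCA, top contributors, between-region PC1 correlation |
| `stripeflick.io` | TIFF stacks (metadata-preserving), ROI and trace CSVs |

## Worked example

`examples/quantify_flicker.py` renders an anaesthetised scene (one vessel,
moving absorbers, no spiking) under both modalities and runs the full
flicker-area chain:

```python
from stripeflick import SceneConfig, flicker_area, make_scene, render_timelapse

config = SceneConfig(
    image_shape=(128, 128), n_frames=300, n_cells=80, spike_rate=0.0,
    vessel_paths=(((20, 5), (110, 5)),), absorber_rate=1.5,
    shadow_blur_sigma=0.0, shot_noise_scale=0.0, read_noise_sd=0.0, seed=3,
)
truth = make_scene(config)
gauss = render_timelapse(truth, "gaussian")
bessel = render_timelapse(truth, "bessel")
fm_g, fm_b = flicker_area(gauss, bessel, beta=config.cone_angle_beta)
```

Actual output:

```
flicker area, Gaussian: 78.9% (ground truth 73.0%)
flicker area, Bessel:   0.0%
20 flickering particles found under Gaussian illumination.
Bessel self-reconstruction confines each shadow to a short segment, so its affected area collapses.
```

`examples/noise_statistics.py` shows the downstream cost of the two measured
baseline-noise levels (19.65% vs 3.90% dF/F). Actual output:

```
gaussian  baseline noise:  19.65 +/- 0.07% dF/F (true 19.65%)
bessel    baseline noise:   3.90 +/- 0.01% dF/F (true 3.90%)
gaussian  detectable events: 4.00 peaks/min (prominence floor 0.393)
bessel    detectable events: 9.00 peaks/min (prominence floor 0.085)
gaussian  correlation bias -0.0133, accuracy (std) 0.0079
bessel    correlation bias -0.0006, accuracy (std) 0.0016
```

The other examples (`render_scene.py`, `quantify_striping.py`,
`extract_traces.py`, `regional_pca.py`) each exercise one capability and print
a few numbers with a one-line interpretation; all run in seconds.

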