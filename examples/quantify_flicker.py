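"""Estimate the hemodynamic-flicker area and compare it to scene truth.

Moving absorbers cast time-varying stripe shadows.  The STD-projection
chain localises the flickering particles; Gaussian boxes are extended to
the mask border (persistent shadows), Bessel boxes only by the beam's
reconstruction length x = h / (2 tan beta).
"""

from stripeflick import SceneConfig, flicker_area, make_scene, render_timelapse

config = SceneConfig(
    image_shape=(128, 128),
    n_frames=300,
    n_cells=80,
    spike_rate=0.0,  # anaesthetised: brightness changes are flicker only
    vessel_paths=(((20, 5), (110, 5)),),
    absorber_rate=1.5,
    shadow_blur_sigma=0.0,
    shot_noise_scale=0.0,
    read_noise_sd=0.0,
    seed=3,
)
truth = make_scene(config)
gauss = render_timelapse(truth, "gaussian")
bessel = render_timelapse(truth, "bessel")

fm_g, fm_b = flicker_area(gauss, bessel, beta=config.cone_angle_beta)
truth_pct = 100 * truth.flicker_truth_masks["gaussian"].mean()
print(f"flicker area, Gaussian: {100 * fm_g.affected_fraction:.1f}% "
      f"(ground truth {truth_pct:.1f}%)")
print(f"flicker area, Bessel:   {100 * fm_b.affected_fraction:.1f}%")
print(f"{len(fm_g.particles)} flickering particles found under Gaussian illumination.")
print("Bessel self-reconstruction confines each shadow to a short segment, "
      "so its affected area collapses.")
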