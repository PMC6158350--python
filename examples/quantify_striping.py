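"""Measure the static-striping area from a Gaussian/Bessel image pair.

Static obstacles darken whole rows behind them under Gaussian
illumination.  The bar code marks rows where the two normalised line
profiles differ by more than 5%; the marked fraction is the streaked area
fraction of the plane.
"""

import numpy as np

from stripeflick import (
    SceneConfig,
    bar_code,
    line_profiles,
    make_scene,
    proximal_distal_split,
    render_timelapse,
    threshold_sweep,
)

rng = np.random.default_rng(0)
obstacles = tuple(
    (int(rng.integers(10, 118)), int(rng.integers(0, 60)),
     int(rng.integers(4, 10)), float(rng.uniform(0.3, 0.7)))
    for _ in range(4)
)
config = SceneConfig(
    image_shape=(128, 128), n_frames=1, n_cells=0, spike_rate=0.0,
    static_obstacles=obstacles, shot_noise_scale=0.0, read_noise_sd=0.0, seed=7,
)
truth = make_scene(config)
gauss = render_timelapse(truth, "gaussian").data[0]
bessel = render_timelapse(truth, "bessel").data[0]

profiles = line_profiles(gauss, bessel)
code = bar_code(profiles, threshold=0.05)
print(f"striped area at the 5% threshold: {100 * code.affected_fraction:.1f}% of rows")

prox, dist = proximal_distal_split(gauss, bessel, threshold=0.05)
print(f"proximal half {100 * prox:.1f}%, distal half {100 * dist:.1f}%")

thetas = np.arange(0.01, 0.16, 0.02)
for theta, frac in zip(thetas, threshold_sweep(profiles, thetas)):
    print(f"  threshold {theta:.2f} -> {100 * frac:5.1f}% affected")
print("The fraction falls monotonically as the threshold is raised.")
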