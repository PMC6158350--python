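"""Noise injection, event detectability and correlation fidelity.

Takes clean dF/F traces, injects each illumination modality's measured
multiplicative baseline noise, and shows three consequences: the noise
std is recovered, detectable peaks/min drop when the prominence floor
must clear the larger noise, and pairwise correlations are attenuated by
1 / (1 + sigma^2).
"""

import numpy as np

from stripeflick import (
    NoiseModel,
    baseline_noise_std,
    corr_bias_accuracy,
    count_peaks,
    inject_noise,
)
from stripeflick.traces import DFFTrace

SIGMAS = {"gaussian": 0.1965, "bessel": 0.0390}
rng = np.random.default_rng(12)

# 1. noise-level recovery on flat baselines
for name, sigma in SIGMAS.items():
    flat = [DFFTrace(i, sigma * rng.standard_normal(800), 5.5) for i in range(50)]
    _, mean, sem = baseline_noise_std(flat)
    print(f"{name:9s} baseline noise: {100 * mean:6.2f} +/- {100 * sem:.2f}% dF/F "
          f"(true {100 * sigma:.2f}%)")

# 2. peaks/min above each noise floor, same underlying activity
t44 = np.arange(44 * 120) / 44.0
clean = np.zeros(t44.size)
for ts in rng.uniform(0, 120, size=20):
    dt = np.maximum(t44 - ts, 0.0)
    clean += 0.5 * (1 - np.exp(-dt / 0.1)) * np.exp(-dt / 1.5)
clean55 = DFFTrace(0, clean.reshape(-1, 8).mean(axis=1), 5.5)
for name, sigma in SIGMAS.items():
    noisy = inject_noise(clean55, NoiseModel(sigma), rng=rng)
    prominence = max(0.085, 2.0 * sigma)
    rate = count_peaks(noisy, min_prominence=prominence).peaks_per_minute
    print(f"{name:9s} detectable events: {rate:.2f} peaks/min "
          f"(prominence floor {prominence:.3f})")

# 3. correlation bias and accuracy
shared = rng.standard_normal(1000)
pairable = [
    DFFTrace(i, 0.6 * shared + 0.8 * rng.standard_normal(1000), 5.5) for i in range(8)
]
for name, sigma in SIGMAS.items():
    stats = corr_bias_accuracy(pairable, NoiseModel(sigma), n_rep=50, seed=99)
    print(f"{name:9s} correlation bias {stats.diff_mean:+.4f}, "
          f"accuracy (std) {stats.diff_std:.4f}")
print("Gaussian-level noise attenuates correlations ~ 1/(1+sigma^2) and "
      "hides small events; Bessel-level noise leaves both nearly intact.")
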