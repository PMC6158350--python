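import numpy as np
import pytest

from stripeflick import LatentSignal, SceneConfig, make_scene, render_timelapse


@pytest.fixture(scope="session")
def absorber_config():
    """Small noise-free scene with one vessel of moving absorbers."""
    # dense nuclear labelling (cells throughout) and a vessel running along
    # the illumination-proximal brain surface, as in a transverse larval plane
    return SceneConfig(
        image_shape=(96, 96),
        n_frames=250,
        n_cells=60,
        spike_rate=0.0,
        vessel_paths=(((16, 4), (80, 4)),),
        absorber_rate=1.5,
        absorber_speed=2.0,
        absorber_attenuation=0.6,
        absorber_height=8,
        shadow_blur_sigma=0.0,
        shot_noise_scale=0.0,
        read_noise_sd=0.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def absorber_truth(absorber_config):
    return make_scene(absorber_config)


@pytest.fixture(scope="session")
def absorber_pair(absorber_truth):
    return (
        render_timelapse(absorber_truth, "gaussian"),
        render_timelapse(absorber_truth, "bessel"),
    )


@pytest.fixture(scope="session")
def latent_scene():
    """Two regions sharing a planted latent spike train (no absorbers)."""
    rows, cols = 96, 96
    left = np.zeros((rows, cols), dtype=bool)
    left[:, : cols // 2] = True
    right = ~left
    rng = np.random.default_rng(5)
    shared = np.sort(rng.uniform(0, 30.0, size=25))
    cfg = SceneConfig(
        image_shape=(rows, cols),
        n_frames=1320,
        n_cells=24,
        spike_rate=0.15,
        latent_signals=(
            LatentSignal(region_mask=left, weight=0.85, spike_times=shared),
            LatentSignal(region_mask=right, weight=0.85, spike_times=shared),
        ),
        shot_noise_scale=0.0,
        read_noise_sd=0.0,
        shadow_blur_sigma=0.0,
        seed=21,
    )
    return make_scene(cfg)
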