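"""Synthetic light-sheet calcium-imaging scenes with full ground truth.

No public recordings exist for the artifact analyses this package
implements, so every stage is validated on rendered scenes whose truth is
known exactly: cell nuclei with spiking calcium dynamics (a slow
GCaMP6s-like double-exponential kernel), static absorbing obstacles that
cast stripe shadows along the illumination axis, and moving absorbers
("blood cells") travelling along vessel polylines whose time-varying
shadows produce hemodynamic flickering.

The shadow model is pure column-wise occlusion: a blocker at ``(r, c)``
of height ``h`` attenuates columns behind it (``c' > c``) in rows
``[r - h/2, r + h/2)``.  Under Gaussian illumination the shadow persists
to the image edge; under Bessel illumination the beam self-reconstructs
after :func:`stripeflick.flicker.reconstruction_length` pixels and the
residual shadow contrast is reduced by a configurable factor, so Bessel
flickering is weaker but not zero — mirroring what the physics of
self-reconstructing beams predicts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import BESSEL, GAUSSIAN, MODALITIES, TimeLapse
from .flicker import PHYSICAL, reconstruction_length

_SHOT_GAUSSIAN_ABOVE = 20.0  # counts; Gaussian approximation to Poisson above this mean


@dataclass
class LatentSignal:
    """A shared spike train mixed into the cells of one region.

    ``region_mask`` is a boolean image; every cell whose centre falls in it
    is a member.  Members replace a fraction ``weight`` of their private
    spikes with the shared train (thinning + superposition), so ``weight``
    controls within-region correlation.  ``spike_times`` may be ``None`` to
    draw the shared train from the scene's Poisson rate.
    """

    region_mask: np.ndarray
    weight: float
    spike_times: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.weight <= 1.0:
            raise ValueError("mixing weight must lie in [0, 1]")


@dataclass
class SceneConfig:
    """Complete parameterisation of a synthetic scene.

    Defaults emulate a transverse plane of a larval zebrafish brain imaged
    at 44 Hz: nuclear-localised indicator cells of a few pixels radius,
    sparse spontaneous spiking, and a slow calcium kernel (rise 0.1 s,
    decay 1.5 s, amplitude 0.5 dF/F).  ``seed`` fixes every random draw.
    """

    image_shape: tuple[int, int] = (128, 128)
    frame_rate: float = 44.0
    n_frames: int = 220
    n_cells: int = 30
    cell_radius: float = 3.0
    spike_rate: float = 0.1  # Hz per cell
    kernel_rise: float = 0.1  # s
    kernel_decay: float = 1.5  # s
    spike_amplitude: float = 0.5  # dF/F
    baseline_F: float = 400.0  # counts added by a cell at rest
    background_F: float = 100.0  # diffuse (neuropil-like) counts everywhere
    vessel_paths: tuple = ()  # polylines [(row, col), ...]
    absorber_rate: float = 0.0  # absorbers/s per vessel
    absorber_speed: float = 2.0  # px/frame
    absorber_attenuation: float = 0.6
    absorber_height: int = 8  # px, square absorber of side h
    static_obstacles: tuple = ()  # (row, col, height_px, attenuation)
    cone_angle_beta: float = 0.12  # rad, Bessel cone half-angle in sample
    bessel_contrast: float = 0.3  # residual Bessel shadow contrast factor
    shadow_blur_sigma: float = 1.0  # px, edge softening of attenuation maps
    shot_noise_scale: float = 1.0
    read_noise_sd: float = 2.0  # counts
    latent_signals: tuple = ()
    eq_form: str = PHYSICAL
    seed: int = 0

    def __post_init__(self) -> None:
        rows, cols = self.image_shape
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if not 0.0 <= self.absorber_attenuation <= 1.0:
            raise ValueError("absorber_attenuation must lie in [0, 1]")
        for r, c, h, att in self.static_obstacles:
            if not 0.0 <= att <= 1.0:
                raise ValueError("obstacle attenuation must lie in [0, 1]")
            if not (0 <= r < rows and 0 <= c < cols):
                raise ValueError(f"obstacle at ({r}, {c}) outside image bounds")
        for path in self.vessel_paths:
            for r, c in path:
                if not (0 <= r < rows and 0 <= c < cols):
                    raise ValueError(f"vessel vertex ({r}, {c}) outside image bounds")
        if self.kernel_rise >= self.kernel_decay:
            raise ValueError("kernel_rise must be smaller than kernel_decay")

    @property
    def duration(self) -> float:
        return self.n_frames / self.frame_rate


@dataclass
class SceneTruth:
    """Everything there is to know about a rendered scene.

    ``flicker_truth_masks[modality]`` is the any-frame union of the dynamic
    shadow footprint under that modality — the ground truth against which
    the flicker-area estimator is scored.  ``latent_corr`` is the Pearson
    correlation matrix of the region-mean fluorescence factors of the
    latent-signal regions (``None`` without at least two regions).
    """

    config: SceneConfig
    cell_table: list  # (id, row, col, radius, spike_times)
    absorber_tracks: np.ndarray  # (vessel, frame, row, col) rows
    static_stripe_masks: dict
    flicker_truth_masks: dict
    fluor_factors: np.ndarray  # (n_cells, n_frames)
    latent_corr: np.ndarray | None = None

    def shadow_mask_stack(self, modality: str) -> np.ndarray:
        """Boolean (frame, row, col) stack of dynamic shadow footprints."""
        cfg = self.config
        stack = np.zeros((cfg.n_frames, *cfg.image_shape), dtype=bool)
        for f in range(cfg.n_frames):
            for row, col, h, att in _dynamic_blockers(self.absorber_tracks, f, cfg):
                for (r0, r1, c0, c1), _ in _blocker_rects(row, col, h, att, modality, cfg):
                    stack[f, r0:r1, c0:c1] = True
        return stack


def spikes_to_fluorescence(
    spike_times: np.ndarray, config: SceneConfig, n_frames: int | None = None
) -> np.ndarray:
    """Per-frame multiplicative fluorescence factor for one cell.

    Each spike at time ``t_s`` contributes
    ``A * (1 - exp(-(t - t_s)/rise)) * exp(-(t - t_s)/decay)`` for
    ``t >= t_s``; the resting factor is 1.
    """
    spike_times = np.asarray(spike_times, dtype=np.float64)
    if spike_times.size and spike_times.min() < 0:
        raise ValueError("spike times must be non-negative")
    if n_frames is None:
        n_frames = config.n_frames
    t = np.arange(n_frames) / config.frame_rate
    factor = np.ones(n_frames)
    for ts in spike_times:
        dt = t - ts
        active = dt >= 0
        factor[active] += (
            config.spike_amplitude
            * (1.0 - np.exp(-dt[active] / config.kernel_rise))
            * np.exp(-dt[active] / config.kernel_decay)
        )
    return factor


def _poisson_train(rng: np.random.Generator, rate: float, duration: float) -> np.ndarray:
    """Homogeneous Poisson spike times in [0, duration), sorted."""
    if rate <= 0:
        return np.empty(0)
    n = rng.poisson(rate * duration)
    return np.sort(rng.uniform(0.0, duration, size=n))


def _mix_trains(
    rng: np.random.Generator, own: np.ndarray, shared: np.ndarray, weight: float
) -> np.ndarray:
    """Thinning + superposition: keep own spikes w.p. 1-w, shared w.p. w."""
    keep_own = own[rng.random(own.size) >= weight] if own.size else own
    keep_shared = shared[rng.random(shared.size) < weight] if shared.size else shared
    return np.sort(np.concatenate([keep_own, keep_shared]))


def make_scene(config: SceneConfig) -> SceneTruth:
    """Lay out cells, draw spike trains and absorber trajectories.

    Deterministic for a given seed.  Cells are placed by rejection
    sampling so that no two overlap; an error names the density limit if
    placement fails after bounded retries.
    """
    rng = np.random.default_rng(config.seed)
    rows, cols = config.image_shape
    radius = config.cell_radius

    # --- non-overlapping cell placement --------------------------------
    centers: list[tuple[int, int]] = []
    max_tries = 300 * max(config.n_cells, 1)
    tries = 0
    margin = int(np.ceil(radius)) + 1
    while len(centers) < config.n_cells:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not place {config.n_cells} non-overlapping cells of radius "
                f"{radius} in a {rows}x{cols} image: density too high"
            )
        r = rng.integers(margin, rows - margin)
        c = rng.integers(margin, cols - margin)
        if all((r - rr) ** 2 + (c - cc) ** 2 > (2 * radius) ** 2 for rr, cc in centers):
            centers.append((int(r), int(c)))

    # --- latent signals: shared trains per region ----------------------
    latents = list(config.latent_signals)
    shared_trains = []
    for sig in latents:
        train = (
            np.sort(np.asarray(sig.spike_times, dtype=float))
            if sig.spike_times is not None
            else _poisson_train(rng, config.spike_rate, config.duration)
        )
        shared_trains.append(train)

    # --- per-cell spike trains -----------------------------------------
    cell_table = []
    for i, (r, c) in enumerate(centers):
        own = _poisson_train(rng, config.spike_rate, config.duration)
        for sig, train in zip(latents, shared_trains):
            if sig.region_mask[r, c]:
                own = _mix_trains(rng, own, train, sig.weight)
        cell_table.append((i, r, c, radius, own))

    # --- absorbers along vessels ---------------------------------------
    tracks = []
    for v, path in enumerate(config.vessel_paths):
        pts = np.asarray(path, dtype=float)
        seg = np.diff(pts, axis=0)
        seg_len = np.hypot(seg[:, 0], seg[:, 1])
        length = seg_len.sum()
        if length == 0:
            continue
        cum = np.concatenate([[0.0], np.cumsum(seg_len)])
        travel_frames = length / config.absorber_speed
        # spawn over [-travel, n_frames) so absorbers can be mid-vessel at t=0
        horizon_s = (config.n_frames + travel_frames) / config.frame_rate
        n_abs = rng.poisson(config.absorber_rate * horizon_s)
        spawns = rng.uniform(-travel_frames, config.n_frames, size=n_abs)
        for t0 in spawns:
            for f in range(config.n_frames):
                s = (f - t0) * config.absorber_speed
                if 0.0 <= s <= length:
                    k = min(np.searchsorted(cum, s, side="right") - 1, len(seg_len) - 1)
                    frac = (s - cum[k]) / seg_len[k]
                    p = pts[k] + frac * seg[k]
                    tracks.append((v, f, int(round(p[0])), int(round(p[1]))))
    absorber_tracks = (
        np.array(sorted(tracks), dtype=np.int64) if tracks else np.empty((0, 4), dtype=np.int64)
    )

    # --- fluorescence factors and latent correlations ------------------
    fluor = np.vstack(
        [spikes_to_fluorescence(spk, config) for (_, _, _, _, spk) in cell_table]
    ) if cell_table else np.empty((0, config.n_frames))

    latent_corr = None
    if len(latents) >= 2:
        region_means = []
        for sig in latents:
            members = [
                i for (i, r, c, _, _) in cell_table if sig.region_mask[r, c]
            ]
            if members:
                region_means.append(fluor[members].mean(axis=0))
            else:
                region_means.append(np.ones(config.n_frames))
        with np.errstate(invalid="ignore"):
            latent_corr = np.corrcoef(np.vstack(region_means))

    # --- ground-truth shadow masks -------------------------------------
    static_masks = {}
    flicker_masks = {}
    for modality in MODALITIES:
        smask = np.zeros(config.image_shape, dtype=bool)
        for r, c, h, att in config.static_obstacles:
            for (r0, r1, c0, c1), _ in _blocker_rects(r, c, h, att, modality, config):
                smask[r0:r1, c0:c1] = True
        static_masks[modality] = smask
        fmask = np.zeros(config.image_shape, dtype=bool)
        for v, f, r, c in absorber_tracks:
            for (r0, r1, c0, c1), _ in _blocker_rects(
                r, c, config.absorber_height, config.absorber_attenuation, modality, config
            ):
                fmask[r0:r1, c0:c1] = True
        flicker_masks[modality] = fmask

    return SceneTruth(
        config=config,
        cell_table=cell_table,
        absorber_tracks=absorber_tracks,
        static_stripe_masks=static_masks,
        flicker_truth_masks=flicker_masks,
        fluor_factors=fluor,
        latent_corr=latent_corr,
    )


def _blocker_rects(row, col, h, attenuation, modality, config):
    """Occlusion rectangles ((r0, r1, c0, c1), effective attenuation) of one blocker."""
    rows, cols = config.image_shape
    r0 = max(int(row - h // 2), 0)
    r1 = min(r0 + int(h), rows)
    c0 = min(int(col) + 1, cols)
    if modality == GAUSSIAN:
        c1 = cols
        att = attenuation
    else:
        x = reconstruction_length(h, config.cone_angle_beta, form=config.eq_form)
        c1 = min(c0 + x, cols)
        att = attenuation * config.bessel_contrast
    if att > 0 and r1 > r0 and c1 > c0:
        yield (r0, r1, c0, c1), att


def _dynamic_blockers(absorber_tracks: np.ndarray, frame: int, config: SceneConfig):
    """Blockers (row, col, h, attenuation) present at one frame."""
    if absorber_tracks.size == 0:
        return []
    sel = absorber_tracks[absorber_tracks[:, 1] == frame]
    return [
        (int(r), int(c), config.absorber_height, config.absorber_attenuation)
        for _, _, r, c in sel
    ]


def shadow_field(
    blockers, modality: str, config: SceneConfig
) -> np.ndarray:
    """Multiplicative attenuation map in [0, 1] for a set of blockers.

    ``blockers`` is an iterable of ``(row, col, height, attenuation)``.
    Overlapping shadows combine multiplicatively; an optional Gaussian blur
    (``config.shadow_blur_sigma``) softens the stripe edges.
    """
    if modality not in MODALITIES:
        raise ValueError(f"unknown modality {modality!r}")
    field_map = np.ones(config.image_shape, dtype=np.float64)
    for row, col, h, att in blockers:
        for (r0, r1, c0, c1), a in _blocker_rects(row, col, h, att, modality, config):
            field_map[r0:r1, c0:c1] *= 1.0 - a
    if config.shadow_blur_sigma > 0 and field_map.min() < 1.0:
        field_map = ndimage.gaussian_filter(field_map, config.shadow_blur_sigma)
        np.clip(field_map, 0.0, 1.0, out=field_map)
    return field_map


def cell_pixel_masks(truth: SceneTruth) -> list[np.ndarray]:
    """Boolean pixel masks of each cell (centre-of-pixel membership)."""
    rows, cols = truth.config.image_shape
    rr, cc = np.mgrid[0:rows, 0:cols]
    masks = []
    for _, r, c, radius, _ in truth.cell_table:
        masks.append((rr - r) ** 2 + (cc - c) ** 2 <= radius**2)
    return masks


def render_timelapse(
    truth: SceneTruth, modality: str, config: SceneConfig | None = None
) -> TimeLapse:
    """Render a scene to a noisy 16-bit time-lapse under one modality.

    A pixel's mean value is ``(background + baseline_F * cell * factor)``
    times the static and dynamic attenuation maps; camera noise is
    Poisson-like shot noise (variance = ``shot_noise_scale`` x mean,
    Gaussian-approximated above 20 counts) plus zero-mean read noise.
    The random stream is derived from the scene seed alone, so the two
    modalities see identical noise draws and differ only in shadows.
    """
    cfg = config or truth.config
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7_919]))
    rows, cols = cfg.image_shape
    masks = cell_pixel_masks(truth)
    base = np.full((rows, cols), float(cfg.background_F))

    static_field = shadow_field(cfg.static_obstacles, modality, cfg)

    frames = np.empty((cfg.n_frames, rows, cols), dtype=np.float64)
    clipped = False
    for f in range(cfg.n_frames):
        img = base.copy()
        for i, mask in enumerate(masks):
            img[mask] += cfg.baseline_F * truth.fluor_factors[i, f]
        blockers = _dynamic_blockers(truth.absorber_tracks, f, cfg)
        if blockers:
            img *= shadow_field(blockers, modality, cfg)
        img *= static_field
        if cfg.shot_noise_scale > 0:
            high = img > _SHOT_GAUSSIAN_ABOVE
            gauss = img + rng.normal(size=img.shape) * np.sqrt(cfg.shot_noise_scale * img)
            low_mean = np.where(high, 0.0, img) / cfg.shot_noise_scale
            pois = cfg.shot_noise_scale * rng.poisson(low_mean)
            img = np.where(high, gauss, pois)
        if cfg.read_noise_sd > 0:
            img = img + rng.normal(0.0, cfg.read_noise_sd, size=img.shape)
        if img.max() > 65535:
            clipped = True
        frames[f] = np.clip(img, 0.0, 65535.0)
    if clipped:
        warnings.warn("intensities exceeded the 16-bit range and were clipped", stacklevel=2)
    return TimeLapse(
        data=frames,
        frame_rate=cfg.frame_rate,
        modality=modality,
        meta={"seed": cfg.seed},
    )
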