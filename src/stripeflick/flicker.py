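"""Quantification of the 2-D area affected by dynamic (hemodynamic) flickering.

Moving absorbers — red blood cells in vasculature — cast time-varying
stripe shadows along the illumination axis.  The affected area is estimated
from a raw time-lapse by a change-detection chain built on standard
deviation (STD) projections:

1. STD time-lapse (per-pixel STD in non-overlapping frame windows),
2. joint rescaling of the Gaussian/Bessel pair to a shared brightness scale,
3. feature enhancement (gamma, bandpass, local variance filter),
4. second joint rescaling, then collapse to a single STD z-projection,
5. thresholding to binary particles and bounding boxes,
6. modality-specific extension of each box along the propagation axis:
   a Gaussian stripe persists to the edge of the specimen mask, while a
   Bessel beam self-reconstructs after a finite distance behind an obstacle,

       x = h / (2 tan beta)        (physical form, default)
       x = tan(beta) * h / 2       (literal form)

   where ``h`` is the bounding-box height and ``beta`` the half-angle of
   the Bessel cone in the sample chamber.

The affected fraction is the area of the union of extended boxes divided by
the area of the encephalon mask.  Identical parameters must be applied to
both modalities; the joint rescaling steps make the whole chain invariant
to a shared global gain.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import difference_of_gaussians
from skimage.measure import label, regionprops

from .core import BESSEL, GAUSSIAN, TimeLapse

PHYSICAL = "physical"
LITERAL = "literal"


@dataclass
class FilterParams:
    """Enhancement-chain parameters, shared by contract across modalities.

    ``bandpass_small``/``bandpass_large`` are structure sizes in pixels:
    the bandpass keeps features between the two scales (implemented as a
    difference of Gaussians with sigmas of half each size).  ``threshold``
    is on the joint [0, 1] brightness scale of the collapsed projection.
    """

    gamma: float = 1.1
    bandpass_small: float = 3.0
    bandpass_large: float = 40.0
    variance_radius: int = 2
    threshold: float = 0.20

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if not self.bandpass_small < self.bandpass_large:
            raise ValueError("bandpass_small must be < bandpass_large")


@dataclass
class StdLapse:
    """Windowed standard-deviation time-lapse."""

    frames: np.ndarray  # (n_windows, rows, cols), >= 0 at creation
    window: int
    step: int


@dataclass
class FlickerMap:
    """Binary flicker mask with particle boxes and the affected-area fraction.

    Boxes are axis-aligned, half-open ``(top, left, height, width)``.
    """

    mask: np.ndarray
    particles: list[tuple[int, int, int, int]]
    extended_boxes: list[tuple[int, int, int, int]] = field(default_factory=list)
    extended_mask: np.ndarray | None = None
    affected_fraction: float = 0.0
    meta: dict = field(default_factory=dict)


def std_timelapse(stack: TimeLapse, window: int = 5, step: int = 5) -> StdLapse:
    """Per-pixel sample STD over frame windows advancing by ``step``.

    Flickering at the native frame rate shows up as high temporal STD;
    no temporal downsampling may be applied beforehand.
    """
    data = np.asarray(stack.data, dtype=np.float64)
    n = data.shape[0]
    if window > n:
        raise ValueError(f"window ({window}) exceeds n_frames ({n})")
    if window < 2:
        raise ValueError("window must be >= 2 for a sample STD")
    n_out = (n - window) // step + 1
    frames = np.empty((n_out, *data.shape[1:]), dtype=np.float64)
    for k in range(n_out):
        win = data[k * step : k * step + window]
        sd = win.std(axis=0, ddof=1)
        # kill float residue of temporally constant pixels so the later
        # rescaling cannot blow pure rounding noise up to full scale
        sd[sd < 1e-9 * np.abs(win.mean(axis=0))] = 0.0
        frames[k] = sd
    return StdLapse(frames=frames, window=window, step=step)


def joint_rescale(a: StdLapse, b: StdLapse) -> tuple[StdLapse, StdLapse]:
    """Map both lapses to [0, 1] using the min and max shared over the pair.

    This puts the two modalities on the same brightness scale so that one
    common threshold means the same physical change in both.
    """
    lo = min(a.frames.min(), b.frames.min())
    hi = max(a.frames.max(), b.frames.max())
    if hi == lo:
        warnings.warn("degenerate brightness range; rescaled to zeros", stacklevel=2)
        return (
            StdLapse(np.zeros_like(a.frames), a.window, a.step),
            StdLapse(np.zeros_like(b.frames), b.window, b.step),
        )
    scale = hi - lo
    return (
        StdLapse((a.frames - lo) / scale, a.window, a.step),
        StdLapse((b.frames - lo) / scale, b.window, b.step),
    )


def apply_gamma(frames: np.ndarray, gamma: float) -> np.ndarray:
    """Power-law contrast ``v -> v**gamma`` for values in [0, 1]."""
    return np.clip(frames, 0.0, None) ** gamma


def bandpass(frame: np.ndarray, small: float, large: float) -> np.ndarray:
    """Difference-of-Gaussians bandpass keeping structures between two scales."""
    return difference_of_gaussians(frame, small / 2.0, large / 2.0)


def variance_filter(frame: np.ndarray, radius: int) -> np.ndarray:
    """Local variance in a square (2*radius+1) neighbourhood."""
    size = 2 * radius + 1
    mean = ndimage.uniform_filter(frame, size=size, mode="reflect")
    mean_sq = ndimage.uniform_filter(frame * frame, size=size, mode="reflect")
    return np.clip(mean_sq - mean * mean, 0.0, None)


def enhance(lapse: StdLapse, params: FilterParams) -> StdLapse:
    """Gamma, bandpass and local-variance filtering of every STD frame."""
    out = np.empty_like(lapse.frames)
    gam = apply_gamma(lapse.frames, params.gamma)
    for k in range(gam.shape[0]):
        bp = bandpass(gam[k], params.bandpass_small, params.bandpass_large)
        out[k] = variance_filter(bp, params.variance_radius)
    return StdLapse(out, lapse.window, lapse.step)


def collapse_std(lapse: StdLapse) -> np.ndarray:
    """Z-projection: per-pixel sample STD across the lapse frames."""
    if lapse.frames.shape[0] < 2:
        raise ValueError("need >= 2 frames to collapse by STD")
    return lapse.frames.std(axis=0, ddof=1)


def binarize_particles(
    img: np.ndarray, threshold: float, encephalon_mask: np.ndarray
) -> FlickerMap:
    """Threshold the collapsed projection and find particle bounding boxes.

    Connected components use 8-connectivity; the same threshold value must
    be applied to both members of a Gaussian/Bessel pair.
    """
    encephalon_mask = np.asarray(encephalon_mask, dtype=bool)
    if not encephalon_mask.any():
        raise ValueError("encephalon mask is empty")
    binary = (img > threshold) & encephalon_mask
    labels = label(binary, connectivity=2)
    particles = []
    for prop in regionprops(labels):
        top, left, bottom, right = prop.bbox
        particles.append((top, left, bottom - top, right - left))
    return FlickerMap(mask=binary, particles=particles)


def reconstruction_length(h: float, beta: float, form: str = PHYSICAL) -> int:
    """Bessel-beam self-reconstruction distance behind an obstacle, in pixels.

    ``h`` is the obstacle (bounding-box) height in pixels and ``beta`` the
    cone half-angle in radians.  The physically consistent form is
    ``x = 0.5 * h / tan(beta)`` (a narrower cone reconstructs more slowly);
    the literal form ``x = tan(beta) * 0.5 * h`` is selectable.  The result
    is rounded up to a whole pixel.
    """
    if h < 0:
        raise ValueError("h must be >= 0")
    if not 0.0 < beta < math.pi / 2:
        raise ValueError("beta must lie in (0, pi/2)")
    if form == PHYSICAL:
        x = 0.5 * h / math.tan(beta)
    elif form == LITERAL:
        x = math.tan(beta) * 0.5 * h
    else:
        raise ValueError(f"form must be {PHYSICAL!r} or {LITERAL!r}")
    # tiny slack so exact-integer lengths are not pushed up by float error
    return max(int(math.ceil(x - 1e-9)), 0)


def extend_boxes(
    fmap: FlickerMap,
    modality: str,
    beta: float,
    encephalon_mask: np.ndarray,
    form: str = PHYSICAL,
) -> FlickerMap:
    """Extend particle boxes along the propagation axis and compute the fraction.

    Gaussian: a shadow persists behind its caster, so each box is stretched
    to the encephalon-mask extent at its rows.  Bessel: the box is
    lengthened by the reconstruction length for its own height.  The
    affected fraction is ``|union of extended boxes ∩ mask| / |mask|``.
    """
    encephalon_mask = np.asarray(encephalon_mask, dtype=bool)
    rows, cols = encephalon_mask.shape
    union = np.zeros_like(encephalon_mask)
    boxes = []
    for top, left, h, w in fmap.particles:
        if modality == GAUSSIAN:
            # stretch to the mask's column support at the box's rows
            row_slice = slice(top, top + h)
            sub = encephalon_mask[row_slice]
            union[row_slice] |= sub
            cols_any = np.flatnonzero(sub.any(axis=0))
            if cols_any.size:
                boxes.append((top, int(cols_any[0]), h, int(cols_any[-1] - cols_any[0] + 1)))
            else:
                boxes.append((top, left, h, w))
        elif modality == BESSEL:
            x = reconstruction_length(h, beta, form=form)
            right = min(left + w + x, cols)
            union[top : top + h, left:right] = True
            boxes.append((top, left, h, right - left))
        else:
            raise ValueError(f"unknown modality {modality!r}")
    area = int((union & encephalon_mask).sum())
    total = int(encephalon_mask.sum())
    return FlickerMap(
        mask=fmap.mask,
        particles=fmap.particles,
        extended_boxes=boxes,
        extended_mask=union & encephalon_mask,
        affected_fraction=area / total,
        meta={"modality": modality, "beta": beta, "eq_form": form},
    )


def flicker_area(
    stack_g: TimeLapse,
    stack_b: TimeLapse,
    params: FilterParams | None = None,
    encephalon_mask: np.ndarray | None = None,
    beta: float = 0.12,
    form: str = PHYSICAL,
    window: int = 5,
    step: int = 5,
) -> tuple[FlickerMap, FlickerMap]:
    """Full flicker-quantification chain for a Gaussian/Bessel stack pair.

    Both stacks must be at the native frame rate (no temporal downsampling)
    and are processed with identical parameters throughout.  Returns the
    per-modality :class:`FlickerMap` with ``affected_fraction`` filled in.
    """
    params = params or FilterParams()
    if encephalon_mask is None:
        encephalon_mask = np.ones(stack_g.shape, dtype=bool)
    sg = std_timelapse(stack_g, window, step)
    sb = std_timelapse(stack_b, window, step)
    sg, sb = joint_rescale(sg, sb)
    sg, sb = enhance(sg, params), enhance(sb, params)
    sg, sb = joint_rescale(sg, sb)
    proj_g, proj_b = collapse_std(sg), collapse_std(sb)
    # one more shared scale so the common threshold is meaningful
    lo = min(proj_g.min(), proj_b.min())
    hi = max(proj_g.max(), proj_b.max())
    if hi > lo:
        proj_g = (proj_g - lo) / (hi - lo)
        proj_b = (proj_b - lo) / (hi - lo)
    fm_g = binarize_particles(proj_g, params.threshold, encephalon_mask)
    fm_b = binarize_particles(proj_b, params.threshold, encephalon_mask)
    fm_g = extend_boxes(fm_g, GAUSSIAN, beta, encephalon_mask, form=form)
    fm_b = extend_boxes(fm_b, BESSEL, beta, encephalon_mask, form=form)
    return fm_g, fm_b
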