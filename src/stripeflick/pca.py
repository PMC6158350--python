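"""PCA of spontaneous activity per anatomical region.

Preprocessing mirrors the standard whole-brain workflow: temporal x10
group-averaging (44 -> 4.4 Hz), 2x2 spatial mean binning, 8-bit min-max
conversion, and integer-pixel translation registration of every frame to a
reference by cross-correlation.  After segmentation and dF/F extraction,
each region's cell x time matrix is mean-centred per cell and decomposed;
the PC1 time trace is the projection onto the first component, with the
sign fixed so the largest-|loading| cell is positive (PCA sign is
otherwise arbitrary).  Comparing PC1 traces between regions — e.g.
hindbrain vs cerebellum — measures whether a shared spontaneous-activity
signal survives each illumination modality's noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.registration import phase_cross_correlation

from .core import TimeLapse
from .traces import ROI, ROISet


@dataclass
class RegionSet:
    """Named binary masks over the preprocessed image grid."""

    masks: dict  # name -> boolean (rows, cols)

    def cells_in(self, name: str, rois: ROISet) -> list[int]:
        """Indices (into rois.rois) of cells whose centre lies in the region."""
        mask = self.masks[name]
        return [
            i
            for i, roi in enumerate(rois.rois)
            if mask[int(round(roi.row)), int(round(roi.col))]
        ]


@dataclass
class PCResult:
    loadings: np.ndarray  # (n_cells, n_components), columns unit-norm
    explained_variance_ratio: np.ndarray  # non-increasing
    pc1_trace: np.ndarray
    cell_ids: np.ndarray
    meta: dict = field(default_factory=dict)


def preprocess_for_pca(
    stack: TimeLapse, t_factor: int = 10, bin_factor: int = 2, reference_frame: int = 0
) -> TimeLapse:
    """Temporal averaging, spatial binning, 8-bit conversion, registration."""
    if stack.n_frames < t_factor:
        raise ValueError("fewer frames than the temporal downsampling factor")
    data = np.asarray(stack.data, dtype=np.float64)
    n = (data.shape[0] // t_factor) * t_factor
    data = data[:n].reshape(n // t_factor, t_factor, *data.shape[1:]).mean(axis=1)
    rows, cols = data.shape[1:]
    r2, c2 = (rows // bin_factor) * bin_factor, (cols // bin_factor) * bin_factor
    cropped = r2 != rows or c2 != cols
    data = data[:, :r2, :c2]
    data = data.reshape(
        data.shape[0], r2 // bin_factor, bin_factor, c2 // bin_factor, bin_factor
    ).mean(axis=(2, 4))
    lo, hi = data.min(), data.max()
    data = np.zeros_like(data) if hi == lo else (data - lo) / (hi - lo) * 255.0
    ref = data[reference_frame]
    shifts = []
    ref_flat = ref.std() == 0
    for k in range(data.shape[0]):
        if ref_flat or data[k].std() == 0:
            shift = np.zeros(2, dtype=int)  # featureless frame: nothing to register
        else:
            shift, _, _ = phase_cross_correlation(ref, data[k], upsample_factor=1)
            shift = np.round(shift).astype(int)
        if shift.any():
            data[k] = ndimage.shift(data[k], shift, order=0, cval=0.0)
        shifts.append(tuple(int(s) for s in shift))
    return TimeLapse(
        data=data,
        frame_rate=stack.frame_rate / t_factor,
        modality=stack.modality,
        meta={
            **stack.meta,
            "shifts": shifts,
            "binned": bin_factor,
            "cropped_to_bin": cropped,
        },
    )


def segment_cells(
    mean_image: np.ndarray,
    radius: float = 3.0,
    smoothing_sigma: float = 1.5,
    intensity_percentile: float = 75.0,
    min_distance: int | None = None,
) -> ROISet:
    """Blob segmentation: smoothed local maxima above an intensity percentile.

    Seeds closer than ``min_distance`` (default 2*radius) are suppressed
    greedily in favour of the brighter one; each seed becomes a circular
    ROI of the configured radius.
    """
    img = np.asarray(mean_image, dtype=np.float64)
    if img.size == 0:
        raise ValueError("empty image")
    if min_distance is None:
        min_distance = max(int(round(2 * radius)), 1)
    smoothed = ndimage.gaussian_filter(img, smoothing_sigma)
    thresh = np.percentile(smoothed, intensity_percentile)
    coords = peak_local_max(
        smoothed, min_distance=min_distance, threshold_abs=thresh, exclude_border=False
    )
    if coords.shape[0] == 0:
        raise ValueError("no cells found above the intensity percentile")
    rois = [ROI(id=i, row=int(r), col=int(c), radius=radius) for i, (r, c) in enumerate(coords)]
    return ROISet(rois=rois)


def region_pca(dff_matrix: np.ndarray, region_cells, n_components: int | None = None) -> PCResult:
    """PCA of a region's mean-centred cell x time dF/F matrix."""
    X = np.asarray(dff_matrix, dtype=np.float64)[list(region_cells)]
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need at least 2 cells and 2 frames in the region")
    Xc = X - X.mean(axis=1, keepdims=True)
    if not np.any(Xc):
        raise ValueError("rank-0 matrix: no variance in the region")
    U, S, _ = np.linalg.svd(Xc, full_matrices=False)
    var = S**2
    ratio = var / var.sum()
    if n_components is not None:
        U, ratio = U[:, :n_components], ratio[:n_components]
    # fix the arbitrary PCA sign: largest-|loading| entry of each PC positive
    for k in range(U.shape[1]):
        j = np.argmax(np.abs(U[:, k]))
        if U[j, k] < 0:
            U[:, k] = -U[:, k]
    pc1_trace = U[:, 0] @ Xc
    return PCResult(
        loadings=U,
        explained_variance_ratio=ratio,
        pc1_trace=pc1_trace,
        cell_ids=np.asarray(list(region_cells)),
    )


def top_contributors(result: PCResult, fraction: float = 0.10) -> np.ndarray:
    """The ceil(fraction*n) cells with largest |PC1 loading|, ties by id."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    load = np.abs(result.loadings[:, 0])
    k = math.ceil(fraction * load.size)
    order = sorted(range(load.size), key=lambda i: (-load[i], result.cell_ids[i]))
    return result.cell_ids[np.array(order[:k])]


def corr_spread_map(corr: np.ndarray) -> np.ndarray:
    """Per cell, the sample STD over partners of its correlation to each other cell."""
    corr = np.asarray(corr, dtype=np.float64)
    n = corr.shape[0]
    if n < 3:
        raise ValueError("need at least 3 cells")
    out = np.empty(n)
    for i in range(n):
        others = np.delete(corr[i], i)
        out[i] = others.std(ddof=1)
    return out


def between_region_pc_corr(a: PCResult, b: PCResult) -> float:
    """Pearson r of two regions' PC1 traces (under the fixed sign convention)."""
    if a.pc1_trace.size != b.pc1_trace.size:
        raise ValueError("PC1 trace lengths differ")
    return float(np.corrcoef(a.pc1_trace, b.pc1_trace)[0, 1])
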