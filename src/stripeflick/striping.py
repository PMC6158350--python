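"""Quantification of the 2-D area affected by static streaking.

Static absorbing obstacles cast dark stripes along the illumination axis
(columns).  Because a stripe spans whole rows of the specimen, the affected
area can be measured from a Gaussian/Bessel image pair of the same plane by

1. averaging each image along the illumination axis to a per-row line
   profile (normalised to mean 1 over the masked rows),
2. binarising the absolute difference of the two profiles at a threshold
   (default 5%) into a per-row "bar code", and
3. reporting the fraction of rows marked affected, which equals the
   affected 2-D area fraction because each marked row spans the full
   masked width.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class LineProfilePair:
    """Per-row normalised mean-intensity profiles of a Gaussian/Bessel pair."""

    gauss_profile: np.ndarray
    bessel_profile: np.ndarray
    rows: np.ndarray  # row indices the profiles are defined on

    @property
    def n_rows(self) -> int:
        return self.rows.size


@dataclass
class BarCode:
    affected: np.ndarray  # boolean per profiled row
    threshold: float
    affected_fraction: float


def line_profiles(
    gauss: np.ndarray, bessel: np.ndarray, mask: np.ndarray | None = None
) -> LineProfilePair:
    """Row-wise mean over masked columns, each profile normalised to mean 1."""
    gauss = np.asarray(gauss, dtype=np.float64)
    bessel = np.asarray(bessel, dtype=np.float64)
    if gauss.shape != bessel.shape:
        raise ValueError("image shapes differ")
    if mask is None:
        mask = np.ones(gauss.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    rows = np.flatnonzero(mask.any(axis=1))
    if rows.size == 0:
        raise ValueError("mask selects no rows")
    counts = mask[rows].sum(axis=1)
    gp = (gauss[rows] * mask[rows]).sum(axis=1) / counts
    bp = (bessel[rows] * mask[rows]).sum(axis=1) / counts
    if gp.mean() <= 0 or bp.mean() <= 0:
        raise ValueError("profiles must have positive mean for normalisation")
    return LineProfilePair(gp / gp.mean(), bp / bp.mean(), rows)


def bar_code(profiles: LineProfilePair, threshold: float = 0.05) -> BarCode:
    """Binarise |gauss - bessel| per row at the given threshold."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    affected = np.abs(profiles.gauss_profile - profiles.bessel_profile) > threshold
    return BarCode(affected, threshold, affected.mean())


def threshold_sweep(profiles: LineProfilePair, thresholds) -> np.ndarray:
    """Affected fraction at each threshold (non-increasing in the threshold)."""
    thresholds = np.asarray(thresholds, dtype=np.float64)
    if np.any(np.diff(thresholds) < 0):
        raise ValueError("thresholds must be sorted ascending")
    return np.array([bar_code(profiles, float(t)).affected_fraction for t in thresholds])


def proximal_distal_split(
    gauss: np.ndarray,
    bessel: np.ndarray,
    mask: np.ndarray | None = None,
    threshold: float = 0.05,
) -> tuple[float, float]:
    """Affected fractions of the halves proximal and distal to the source.

    The mask is split at the column midpoint of its bounding box; the
    light sheet propagates toward increasing columns, so the proximal half
    is the low-column one.  Each half is analysed independently.
    """
    gauss = np.asarray(gauss, dtype=np.float64)
    if mask is None:
        mask = np.ones(gauss.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    cols = np.flatnonzero(mask.any(axis=0))
    if cols.size < 2:
        raise ValueError("mask too narrow to split")
    mid = (cols[0] + cols[-1] + 1) // 2
    prox = mask.copy()
    prox[:, mid:] = False
    dist = mask.copy()
    dist[:, :mid] = False
    if not prox.any() or not dist.any():
        raise ValueError("degenerate half-mask after the split")
    fracs = []
    for half in (prox, dist):
        profiles = line_profiles(gauss, bessel, half)
        fracs.append(bar_code(profiles, threshold).affected_fraction)
    return fracs[0], fracs[1]
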