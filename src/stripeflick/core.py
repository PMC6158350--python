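"""Core containers shared across the analysis stages.

The universal imaging currency is :class:`TimeLapse`: a single transverse
plane imaged over time as a ``(frame, row, col)`` intensity stack, with the
illumination sheet propagating along columns (toward increasing column
index).  All stages index 0-based in ``(frame, row, col)`` order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

GAUSSIAN = "gaussian"
BESSEL = "bessel"
MODALITIES = (GAUSSIAN, BESSEL)


@dataclass
class TimeLapse:
    """A time-lapse of one transverse plane.

    Parameters
    ----------
    data
        Non-negative intensities, shape ``(n_frames, rows, cols)``,
        nominally in 16-bit camera range.
    frame_rate
        Acquisition rate in Hz.
    modality
        ``"gaussian"`` or ``"bessel"`` illumination.
    meta
        Free-form provenance (registration shifts, parameters, ...).
    """

    data: np.ndarray
    frame_rate: float
    modality: str = GAUSSIAN
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"data must be (frame, row, col), got ndim={self.data.ndim}")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.modality not in MODALITIES:
            raise ValueError(f"modality must be one of {MODALITIES}, got {self.modality!r}")
        if np.any(self.data < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1], self.data.shape[2]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_frames / self.frame_rate
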