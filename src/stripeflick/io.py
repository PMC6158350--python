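"""File I/O: multi-page TIFF stacks, ROI tables and trace tables.

Stacks travel as 16-bit multi-page TIFF, ROIs as CSV (id, row, col,
radius), traces as CSV with a leading time column (seconds) and one
column per cell id.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .core import TimeLapse
from .traces import DFFTrace, ROI, ROISet


def write_stack(path, stack: TimeLapse) -> None:
    data = np.clip(np.round(stack.data), 0, 65535).astype(np.uint16)
    tifffile.imwrite(
        path,
        data,
        metadata={"frame_rate": stack.frame_rate, "modality": stack.modality},
    )


def read_stack(path, frame_rate: float | None = None, modality: str = "gaussian") -> TimeLapse:
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
    if data.ndim == 2:
        data = data[None]
    return TimeLapse(
        data=data.astype(np.float64),
        frame_rate=float(frame_rate or meta.get("frame_rate", 1.0)),
        modality=meta.get("modality", modality),
    )


def write_rois(path, rois: ROISet) -> None:
    rows = [(r.id, r.row, r.col, r.radius) for r in rois.rois]
    pd.DataFrame(rows, columns=["id", "row", "col", "radius"]).to_csv(path, index=False)


def read_rois(path) -> ROISet:
    df = pd.read_csv(path)
    rois = [
        ROI(id=int(r.id), row=float(r.row), col=float(r.col), radius=float(r.radius))
        for r in df.itertuples()
    ]
    return ROISet(rois=rois)


def write_traces(path, traces: list[DFFTrace]) -> None:
    n = len(traces[0].values)
    t = np.arange(n) / traces[0].frame_rate
    df = pd.DataFrame({"time_s": t})
    for tr in traces:
        df[str(tr.cell_id)] = tr.values
    df.to_csv(path, index=False, float_format="%.8g")


def read_traces(path) -> list[DFFTrace]:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    frame_rate = 1.0 / float(np.median(np.diff(t))) if t.size > 1 else 1.0
    return [
        DFFTrace(cell_id=int(col), values=df[col].to_numpy(), frame_rate=frame_rate)
        for col in df.columns
        if col != "time_s"
    ]


def read_mask(path) -> np.ndarray:
    """Binary mask from a TIFF/PNG image: nonzero pixels are in the mask."""
    suffix = Path(path).suffix.lower()
    if suffix in (".tif", ".tiff"):
        img = tifffile.imread(path)
    else:
        from imageio.v3 import imread

        img = imread(path)
    if img.ndim == 3:
        img = img[..., 0]
    return np.asarray(img) > 0
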