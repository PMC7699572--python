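"""Per-frame airway morphometry from binary lumen masks.

Outcome measures follow the axial-plane convention: cross-sectional
area in mm² (pixel count x pixel area), anterior-posterior diameter in
mm (mask bounding-box extent over image rows) and transverse diameter
in mm (extent over columns).  Extents use the inclusive pixel-count
convention, so a single-pixel mask has a diameter of one pixel width
rather than zero.  An empty mask (closed airway) contributes zeros —
dropping such frames would bias minima upward.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import METRICS_COLUMNS, CineSequence
from .segmentation import AirwayMask

__all__ = ["FrameMetrics", "frame_metrics", "sequence_metrics"]


@dataclass(frozen=True)
class FrameMetrics:
    frame: int
    time_ms: float
    area_mm2: float
    ap_mm: float
    tx_mm: float


def frame_metrics(
    mask: AirwayMask | np.ndarray,
    pixel_spacing: tuple[float, float],
    frame: int = 0,
    frame_interval: float = 0.0,
) -> FrameMetrics:
    """Area and AP/TX diameters of one mask, in physical units."""
    arr = mask.mask if isinstance(mask, AirwayMask) else np.asarray(mask, dtype=bool)
    sr, sc = pixel_spacing
    if not arr.any():
        return FrameMetrics(frame, frame * frame_interval, 0.0, 0.0, 0.0)
    rows, cols = np.nonzero(arr)
    area = float(arr.sum()) * sr * sc
    ap = float(rows.max() - rows.min() + 1) * sr
    tx = float(cols.max() - cols.min() + 1) * sc
    return FrameMetrics(frame, frame * frame_interval, area, ap, tx)


def sequence_metrics(masks, sequence: CineSequence) -> pd.DataFrame:
    """One metrics row per frame; ``time_ms = frame x frame_interval``."""
    if len(masks) != sequence.n_frames:
        raise ValueError(
            f"{len(masks)} masks for {sequence.n_frames} frames of {sequence.identifier!r}"
        )
    rows = [
        frame_metrics(m, sequence.pixel_spacing, t, sequence.frame_interval)
        for t, m in enumerate(masks)
    ]
    return pd.DataFrame([r.__dict__ for r in rows], columns=METRICS_COLUMNS)
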