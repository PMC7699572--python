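"""Respiratory-cycle summarization of per-frame airway metrics.

A cine metric trace (area or diameter vs. frame) oscillates with
breathing.  Rather than reporting the single smallest or largest frame
— which a noise spike can own — each sequence is summarized by a
"true" minimum (the average over all detected valleys), a mean (the
average of every frame) and a "true" maximum (the average over all
detected peaks).  Peaks and valleys are local extrema with a prominence
of at least a fraction of the series range; endpoints are excluded so
truncated first/last breaths do not bias the averages.  When no
qualifying extremum exists (flat or monotone trace) the global extremum
stands in, which keeps the ordering t_min <= t_mean <= t_max intact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks

from .io import SUMMARY_COLUMNS

__all__ = ["TemporalSummary", "detect_extrema", "summarize"]

#: metrics-table column backing each summarized measure
MEASURE_COLUMNS = {"area": "area_mm2", "ap": "ap_mm", "tx": "tx_mm"}


@dataclass(frozen=True)
class MeasureSummary:
    t_min: float
    t_mean: float
    t_max: float
    n_peaks: int
    n_valleys: int


@dataclass(frozen=True)
class TemporalSummary:
    """Per-sequence true-minimum / mean / maximum of each measure."""

    measures: dict[str, MeasureSummary]

    def __getitem__(self, measure: str) -> MeasureSummary:
        return self.measures[measure]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"measure": m, "t_min": s.t_min, "t_mean": s.t_mean, "t_max": s.t_max,
             "n_peaks": s.n_peaks, "n_valleys": s.n_valleys}
            for m, s in self.measures.items()
        ]
        return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


def detect_extrema(
    series,
    min_prominence: float = 0.1,
    smoothing_window: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Indices of respiratory peaks and valleys of a metric trace.

    ``min_prominence`` is a fraction of the series range.  Endpoints are
    never reported as detected extrema; if a side finds nothing the
    global extremum index is the fallback (for a constant series both
    sides fall back to index 0).
    """
    s = np.asarray(series, dtype=float)
    if s.ndim != 1 or len(s) < 3:
        raise ValueError("series must be 1-D with at least 3 samples")
    if smoothing_window > 1:
        s = uniform_filter1d(s, smoothing_window, mode="nearest")
    rng = float(np.ptp(s))
    prom = min_prominence * rng if rng > 0 else np.inf
    peaks, _ = find_peaks(s, prominence=prom)
    valleys, _ = find_peaks(-s, prominence=prom)
    if len(peaks) == 0:
        peaks = np.array([int(np.argmax(s))])
    if len(valleys) == 0:
        valleys = np.array([int(np.argmin(s))])
    return peaks, valleys


def summarize(
    metrics: pd.DataFrame,
    min_prominence: float = 0.1,
    smoothing_window: int = 1,
) -> TemporalSummary:
    """True-min/mean/max of area, AP and TX series of one sequence.

    Each measure gets its own extrema; t_min and t_max average the raw
    series values at valley and peak indices respectively.
    """
    out = {}
    for measure, col in MEASURE_COLUMNS.items():
        v = metrics[col].to_numpy(dtype=float)
        peaks, valleys = detect_extrema(v, min_prominence, smoothing_window)
        out[measure] = MeasureSummary(
            t_min=float(v[valleys].mean()),
            t_mean=float(v.mean()),
            t_max=float(v[peaks].mean()),
            n_peaks=len(peaks),
            n_valleys=len(valleys),
        )
    return TemporalSummary(out)
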