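"""Semi-automatic airway-lumen segmentation for axial cine MRI.

The method reproduces the classic seeded region-growing workflow used
for dark-lumen airway imaging.  A user places a single seed inside the
lumen on the first frame.  For each frame:

1.  The 1-D intensity profiles through the seed along the transverse
    (image columns) and anterior-posterior (image rows) axes are
    extracted and lightly smoothed.  The airway appears as a dark well
    flanked by bright tissue; the nearest sufficiently prominent local
    intensity peak on each side of the seed marks the tissue flank.
    Those four peak positions define rectangular limits for the airway.
2.  An intensity threshold separating lumen from tissue is chosen
    (Otsu's bimodal split of the in-bounds histogram by default).
3.  The seed grows through 4-connected sub-threshold pixels inside the
    rectangular limits; remaining sub-threshold pixels within the grown
    region's bounding box are then unioned in, so that every low-
    intensity pixel within the detected airway extent is labeled lumen.

Subsequent frames are seeded automatically from the centroid of the
previous frame's mask, falling back to the original user seed when the
airway closes transiently.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.signal import find_peaks
from skimage.filters import threshold_otsu

from .io import CineSequence

logger = logging.getLogger(__name__)

__all__ = [
    "SeedPoint",
    "ProfileBounds",
    "AirwayMask",
    "SegmentationParams",
    "SeedError",
    "SegmentationError",
    "profile_bounds",
    "auto_threshold",
    "region_grow",
    "segment_frame",
    "segment_sequence",
]


class SeedError(ValueError):
    """Seed rejected (outside image, or not inside the dark lumen)."""


class SegmentationError(RuntimeError):
    """Sequence-level segmentation failure."""


@dataclass(frozen=True)
class SeedPoint:
    row: int
    col: int
    frame: int = 0


@dataclass(frozen=True)
class ProfileBounds:
    """Rectangular airway limits from profile-peak detection (inclusive)."""

    row_lo: int
    row_hi: int
    col_lo: int
    col_hi: int
    prominences: tuple[float, ...] = ()

    @property
    def degenerate(self) -> bool:
        return self.row_hi <= self.row_lo or self.col_hi <= self.col_lo

    def contains(self, row: int, col: int) -> bool:
        return self.row_lo <= row <= self.row_hi and self.col_lo <= col <= self.col_hi


@dataclass
class AirwayMask:
    """Per-frame binary lumen labeling with its provenance."""

    mask: np.ndarray
    bounds: ProfileBounds
    threshold: float
    empty: bool = False

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.empty = not self.mask.any()

    @property
    def area_pixels(self) -> int:
        return int(self.mask.sum())

    def centroid(self) -> tuple[int, int] | None:
        if self.empty:
            return None
        rows, cols = np.nonzero(self.mask)
        return int(round(rows.mean())), int(round(cols.mean()))


@dataclass(frozen=True)
class SegmentationParams:
    """Tunables for the per-frame segmentation.

    smoothing_window: moving-average width (pixels) applied to the
        intensity profiles before peak finding.
    min_prominence: required peak prominence in grayscale units; when
        ``None`` it defaults to 10% of the frame's intensity range.
    threshold: fixed lumen/tissue threshold; ``None`` means per-frame
        automatic (Otsu within the rectangular limits).
    fill_mode: ``"union"`` (grow 4-connected from the seed, then union
        sub-threshold pixels inside the grown component's bounding box),
        ``"connected"`` (the seeded component only) or ``"any"`` (every
        sub-threshold pixel inside the rectangular limits).
    """

    smoothing_window: int = 3
    min_prominence: float | None = None
    threshold: float | None = None
    fill_mode: str = "union"

    def __post_init__(self) -> None:
        if self.smoothing_window < 1:
            raise ValueError("smoothing_window must be >= 1")
        if self.fill_mode not in ("union", "connected", "any"):
            raise ValueError(f"unknown fill_mode {self.fill_mode!r}")


def _smooth(profile: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return profile.astype(float)
    return ndimage.uniform_filter1d(profile.astype(float), window, mode="nearest")


def _side_limits(profile: np.ndarray, seed_idx: int, prominence: float) -> tuple[int, int, tuple]:
    """Nearest qualifying peak below and above ``seed_idx`` on one axis.

    A qualifying peak must be prominent *and* brighter than the midpoint
    of the profile's intensity range: the boundary peak is bright tissue
    flanking the dark lumen, so dark-side noise bumps are not boundary
    candidates.  The profile is padded with -inf so that bright tissue
    running into the image border still registers as a peak; for plateau
    peaks the plateau edge nearest the seed is used.  A side with no
    qualifying peak falls back to the image border.  Ties among equally
    distant candidates resolve to the lower index (deterministic).
    """
    height_floor = 0.5 * (float(profile.min()) + float(profile.max()))
    padded = np.concatenate(([-np.inf], profile, [-np.inf]))
    peaks, props = find_peaks(padded, prominence=prominence, height=height_floor,
                              plateau_size=(1, None))
    lefts = props["left_edges"] - 1
    rights = props["right_edges"] - 1
    lo, hi = 0, len(profile) - 1
    lo_prom = hi_prom = np.nan
    best_lo = best_hi = None
    for p, ledge, redge, prom in zip(peaks - 1, lefts, rights, props["prominences"]):
        if redge < seed_idx:  # peak (or its plateau) entirely below the seed
            d = seed_idx - redge
            if best_lo is None or d < best_lo:
                best_lo, lo, lo_prom = d, int(redge), float(prom)
        elif ledge > seed_idx:
            d = ledge - seed_idx
            if best_hi is None or d < best_hi:
                best_hi, hi, hi_prom = d, int(ledge), float(prom)
    return lo, hi, (lo_prom, hi_prom)


def profile_bounds(
    frame: np.ndarray,
    seed: SeedPoint,
    smoothing_window: int = 3,
    min_prominence: float | None = None,
) -> ProfileBounds:
    """Rectangular airway limits from the seed's intensity profiles.

    Raises :class:`SeedError` when the seed pixel is at least as bright
    as the median of its two profiles (i.e. sits in tissue, not lumen).
    """
    frame = np.asarray(frame, dtype=float)
    nrows, ncols = frame.shape
    if not (0 <= seed.row < nrows and 0 <= seed.col < ncols):
        raise SeedError(f"seed ({seed.row}, {seed.col}) outside image {frame.shape}")
    ap_profile = frame[:, seed.col]
    tx_profile = frame[seed.row, :]
    combined = np.concatenate([ap_profile, tx_profile])
    seed_val = frame[seed.row, seed.col]
    if np.ptp(combined) > 0:
        if seed_val >= np.median(combined):
            raise SeedError("seed not in lumen")
    elif np.ptp(frame) > 0 and seed_val >= np.median(frame):
        # both profiles miss the lumen entirely: judge against the frame
        raise SeedError("seed not in lumen")
    # a fully contrast-free frame cannot distinguish lumen from tissue;
    # the border-fallback rule applies instead of rejecting the seed
    if min_prominence is None:
        min_prominence = 0.1 * float(np.ptp(frame))
    ap_s = _smooth(ap_profile, smoothing_window)
    tx_s = _smooth(tx_profile, smoothing_window)
    row_lo, row_hi, ap_prom = _side_limits(ap_s, seed.row, min_prominence)
    col_lo, col_hi, tx_prom = _side_limits(tx_s, seed.col, min_prominence)
    return ProfileBounds(row_lo, row_hi, col_lo, col_hi, prominences=ap_prom + tx_prom)


def auto_threshold(frame: np.ndarray, bounds: ProfileBounds,
                   seed: SeedPoint | None = None) -> float:
    """Lumen/tissue threshold from the in-bounds intensity histogram.

    Otsu's bimodal split by default.  If the split is degenerate (a
    near-empty class, indicating a unimodal in-bounds histogram) the
    threshold falls back to the midpoint between the mean of the seed's
    3x3 neighborhood and the mean intensity at the four bound edges.
    """
    frame = np.asarray(frame, dtype=float)
    region = frame[bounds.row_lo:bounds.row_hi + 1, bounds.col_lo:bounds.col_hi + 1]
    if region.size == 0 or np.ptp(region) == 0:
        raise ValueError("no contrast within bounds")
    thr = float(threshold_otsu(region))
    lo_frac = float((region < thr).mean())
    if 0.02 < lo_frac < 0.98:
        return thr
    # unimodal in-bounds histogram: Otsu split is spurious
    if seed is None:
        return thr
    r0, r1 = max(seed.row - 1, 0), seed.row + 2
    c0, c1 = max(seed.col - 1, 0), seed.col + 2
    lumen_level = float(frame[r0:r1, c0:c1].mean())
    flank_level = float(np.mean([
        frame[bounds.row_lo, seed.col], frame[bounds.row_hi, seed.col],
        frame[seed.row, bounds.col_lo], frame[seed.row, bounds.col_hi],
    ]))
    return 0.5 * (lumen_level + flank_level)


_CROSS = ndimage.generate_binary_structure(2, 1)  # 4-connectivity


def region_grow(
    frame: np.ndarray,
    seed: SeedPoint,
    bounds: ProfileBounds,
    threshold: float,
    fill_mode: str = "union",
) -> AirwayMask:
    """Grow the lumen mask from the seed within the rectangular limits.

    Default ``"union"`` mode: take the 4-connected sub-threshold
    component containing the seed, then union every sub-threshold pixel
    inside that component's bounding rows/columns, so all low-intensity
    pixels within the detected airway extent are labeled.
    """
    frame = np.asarray(frame, dtype=float)
    full = np.zeros(frame.shape, dtype=bool)
    if bounds.degenerate:
        return AirwayMask(full, bounds, threshold, empty=True)
    if not bounds.contains(seed.row, seed.col):
        raise SeedError(f"seed ({seed.row}, {seed.col}) outside bounds {bounds}")
    if frame[seed.row, seed.col] >= threshold:
        return AirwayMask(full, bounds, threshold, empty=True)
    rl, rh, cl, ch = bounds.row_lo, bounds.row_hi, bounds.col_lo, bounds.col_hi
    sub = frame[rl:rh + 1, cl:ch + 1] < threshold
    labels, _ = ndimage.label(sub, structure=_CROSS)
    seed_label = labels[seed.row - rl, seed.col - cl]
    comp = labels == seed_label
    if fill_mode == "connected":
        grown = comp
    elif fill_mode == "any":
        grown = sub
    else:  # union: sub-threshold pixels within the component's bbox
        rows, cols = np.nonzero(comp)
        grown = np.zeros_like(sub)
        grown[rows.min():rows.max() + 1, cols.min():cols.max() + 1] = True
        grown &= sub
        grown |= comp
    full[rl:rh + 1, cl:ch + 1] = grown
    return AirwayMask(full, bounds, threshold)


def segment_frame(frame: np.ndarray, seed: SeedPoint,
                  params: SegmentationParams = SegmentationParams()) -> AirwayMask:
    """Bounds detection + thresholding + region growth for one frame."""
    bounds = profile_bounds(frame, seed, params.smoothing_window, params.min_prominence)
    if params.threshold is not None:
        thr = params.threshold
    else:
        thr = auto_threshold(frame, bounds, seed)
    return region_grow(frame, seed, bounds, thr, fill_mode=params.fill_mode)


def segment_sequence(
    sequence: CineSequence,
    seed: SeedPoint,
    params: SegmentationParams = SegmentationParams(),
) -> list[AirwayMask]:
    """Segment every frame, propagating the seed across frames.

    Frame 0 is segmented from the user seed; each later frame is seeded
    with the rounded centroid of the previous non-empty mask, falling
    back to the original seed when the previous mask was empty or the
    candidate pixel is not sub-threshold.  An empty mask on frame 0
    raises; transiently closed airways later in the sequence yield empty
    masks (logged, not fatal).
    """
    masks: list[AirwayMask] = []
    current_seed = seed
    prev_threshold: float | None = None
    for t in range(sequence.n_frames):
        frame = sequence.frames[t]
        if t > 0:
            cand = masks[-1].centroid()
            thr_ref = prev_threshold if prev_threshold is not None else np.inf
            if cand is not None and frame[cand] < thr_ref:
                current_seed = SeedPoint(cand[0], cand[1], frame=t)
            else:
                current_seed = SeedPoint(seed.row, seed.col, frame=t)
        try:
            mask = segment_frame(frame, current_seed, params)
        except (SeedError, ValueError) as exc:
            if t == 0:
                raise SegmentationError(f"initial seed failed on frame 0: {exc}") from exc
            # airway closed at the propagated seed; retry from the user seed
            try:
                mask = segment_frame(frame, SeedPoint(seed.row, seed.col, frame=t), params)
            except (SeedError, ValueError):
                mask = AirwayMask(np.zeros(sequence.shape, dtype=bool),
                                  ProfileBounds(0, 0, 0, 0),
                                  prev_threshold if prev_threshold is not None else np.nan,
                                  empty=True)
        if t == 0 and mask.empty:
            raise SegmentationError("initial seed failed: empty mask on frame 0")
        if not (mask.empty or np.isnan(mask.threshold)):
            prev_threshold = mask.threshold
        masks.append(mask)
    n_empty = sum(m.empty for m in masks)
    if n_empty > 0.5 * len(masks):
        msg = f"{sequence.identifier}: {n_empty}/{len(masks)} frames empty (airway closure?)"
        logger.warning(msg)
        warnings.warn(msg, RuntimeWarning, stacklevel=2)
    return masks
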