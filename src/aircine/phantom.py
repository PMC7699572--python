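"""Synthetic breathing-airway cine phantoms with analytic ground truth.

The phantom emulates an axial upper-airway cine acquisition: a dark
elliptical lumen embedded in brighter soft tissue, whose semi-axes
oscillate sinusoidally with the respiratory cycle.  Frames are sampled
every 300-400 ms so that a typical 72-frame sequence spans several
breaths.  Because the lumen geometry is analytic, every frame carries an
exact cross-sectional area and exact anterior-posterior (AP, image rows)
and transverse (TX, image columns) diameters, which downstream
segmentation and summarization stages can be validated against.

Cohort-level generation mirrors the repeated-measures design this
package analyzes: each subject is imaged in two axial planes
(nasopharyngeal ``NP`` and retroglossal ``RG``) under four anesthetic
conditions (baseline ``00`` plus 5/10/15 min), with subject-level random
size offsets and per-condition multiplicative effects on lumen size.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .io import CineSequence

__all__ = [
    "PhantomSpec",
    "CohortSpec",
    "make_phantom_frame",
    "make_phantom_sequence",
    "iter_cohort",
    "make_cohort",
    "cohort_truth_table",
    "simulate_cohort_measurements",
    "MEASURES",
    "SUMMARIES",
]

MEASURES = ("area", "ap", "tx")
SUMMARIES = ("min", "mean", "max")


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, contrast and noise of one synthetic cine sequence.

    Lengths are millimetres, times milliseconds, intensities 8-bit
    grayscale.  ``ap_semiaxis`` is the lumen semi-axis along image rows
    (anterior-posterior), ``tx_semiaxis`` along columns (transverse).
    ``modulation_fraction`` is the peak-to-mean relative size change over
    a breath; ``amplitude_drift`` adds cycle-to-cycle variability (the
    per-cycle modulation is scaled by ``1 + drift * z`` with standard
    normal ``z``), since real respiratory traces are not perfectly
    periodic.
    """

    image_shape: tuple[int, int] = (128, 128)
    pixel_spacing: tuple[float, float] = (0.5, 0.5)
    n_frames: int = 72
    frame_interval: float = 350.0
    lumen_center: tuple[float, float] = (64.0, 64.0)
    ap_semiaxis: float = 5.0
    tx_semiaxis: float = 4.0
    modulation_fraction: float = 0.2
    respiratory_period: float = 3000.0
    lumen_intensity: float = 20.0
    tissue_intensity: float = 150.0
    noise_sd: float = 10.0
    psf_sigma: float = 0.5
    amplitude_drift: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lumen_intensity >= self.tissue_intensity:
            raise ValueError("lumen must be darker than tissue")
        if self.ap_semiaxis <= 0 or self.tx_semiaxis <= 0:
            raise ValueError("semi-axes must be positive")
        if not 0 <= self.modulation_fraction < 1:
            raise ValueError("modulation_fraction must be in [0, 1)")
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")
        if self.frame_interval <= 0 or self.respiratory_period <= 0:
            raise ValueError("frame_interval and respiratory_period must be positive")

    def replace(self, **kwargs) -> "PhantomSpec":
        return dataclasses.replace(self, **kwargs)

    def modulation_at(self, t: int) -> float:
        """Instantaneous relative size factor ``1 + m(t)·sin(phase)``."""
        phase = 2.0 * np.pi * t * self.frame_interval / self.respiratory_period
        m = self.modulation_fraction
        if self.amplitude_drift > 0:
            cycle = int(t * self.frame_interval // self.respiratory_period)
            rng = np.random.default_rng([self.seed, 7, cycle])
            m = float(np.clip(m * (1.0 + self.amplitude_drift * rng.standard_normal()), 0.0, 0.95))
        return 1.0 + m * float(np.sin(phase))

    def semiaxes_at(self, t: int) -> tuple[float, float]:
        f = self.modulation_at(t)
        return self.ap_semiaxis * f, self.tx_semiaxis * f


def _truth_row(spec: PhantomSpec, t: int) -> dict:
    a, b = spec.semiaxes_at(t)
    return {
        "frame": t,
        "time_ms": t * spec.frame_interval,
        "area_mm2": np.pi * a * b,
        "ap_mm": 2.0 * a,
        "tx_mm": 2.0 * b,
    }


def make_phantom_frame(spec: PhantomSpec, t: int) -> tuple[np.ndarray, dict]:
    """Rasterize frame ``t`` and return it with its ground-truth row.

    The ellipse is rasterized at pixel centres, blurred by a Gaussian
    point-spread of ``psf_sigma`` pixels, and corrupted by additive
    Gaussian noise.  Noise is seeded per ``(spec.seed, t)`` so a frame is
    reproducible whether generated alone or as part of a sequence.
    """
    if not 0 <= t < spec.n_frames:
        raise ValueError(f"frame index {t} outside [0, {spec.n_frames})")
    a, b = spec.semiaxes_at(t)
    nrows, ncols = spec.image_shape
    sr, sc = spec.pixel_spacing
    r0, c0 = spec.lumen_center
    if (r0 - a / sr < 0 or r0 + a / sr > nrows - 1
            or c0 - b / sc < 0 or c0 + b / sc > ncols - 1):
        raise ValueError(f"lumen ellipse exceeds image bounds at frame {t}")
    rows = (np.arange(nrows) - r0) * sr
    cols = (np.arange(ncols) - c0) * sc
    inside = (rows[:, None] / a) ** 2 + (cols[None, :] / b) ** 2 <= 1.0
    frame = np.where(inside, spec.lumen_intensity, spec.tissue_intensity).astype(float)
    if spec.psf_sigma > 0:
        frame = gaussian_filter(frame, spec.psf_sigma, mode="nearest")
    if spec.noise_sd > 0:
        rng = np.random.default_rng([spec.seed, int(t)])
        frame = frame + rng.normal(0.0, spec.noise_sd, frame.shape)
    return frame, _truth_row(spec, t)


def make_phantom_sequence(
    spec: PhantomSpec, identifier: str = "phantom"
) -> tuple[CineSequence, pd.DataFrame]:
    """Generate a full cine sequence plus its per-frame ground truth.

    Returns the sequence and a DataFrame with columns
    ``frame, time_ms, area_mm2, ap_mm, tx_mm``; the DataFrame's ``attrs``
    carry the per-sequence ``min``/``mean``/``max`` of each measure
    (computed from the analytic semi-axes) under the key ``"summary"``.
    """
    frames, rows = [], []
    for t in range(spec.n_frames):
        frame, row = make_phantom_frame(spec, t)
        frames.append(frame)
        rows.append(row)
    truth = pd.DataFrame(rows)
    summary = {}
    for measure, col in zip(MEASURES, ("area_mm2", "ap_mm", "tx_mm")):
        v = truth[col].to_numpy()
        summary[measure] = {"min": float(v.min()), "mean": float(v.mean()), "max": float(v.max())}
    truth.attrs["summary"] = summary
    seq = CineSequence(
        frames=np.stack(frames),
        pixel_spacing=spec.pixel_spacing,
        frame_interval=spec.frame_interval,
        identifier=identifier,
    )
    return seq, truth


@dataclass(frozen=True)
class CohortSpec:
    """Multi-subject repeated-measures layout for synthetic cohorts.

    ``condition_effects`` are multiplicative changes in lumen semi-axes
    per condition relative to baseline; condition ``"00"`` must map to
    exactly 1.  ``between_subject_sd`` (mm) is the SD of the additive
    random offset applied to each subject-plane's baseline semi-axes.
    """

    n_subjects: int = 22
    conditions: tuple[str, ...] = ("00", "5", "10", "15")
    planes: tuple[str, ...] = ("NP", "RG")
    condition_effects: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0)
    between_subject_sd: float = 0.8
    age_range: tuple[float, float] = (1.0, 12.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        if len(self.condition_effects) != len(self.conditions):
            raise ValueError("one effect per condition required")
        if self.conditions[0] != "00" or self.condition_effects[0] != 1.0:
            raise ValueError("condition '00' must be first with effect exactly 1.0")

    def effect_of(self, condition: str) -> float:
        return self.condition_effects[self.conditions.index(condition)]


def _subject_geometry(cohort: CohortSpec, base: PhantomSpec):
    """Per-(subject, plane) baseline semi-axes, ages, and RNG streams."""
    rng = np.random.default_rng([cohort.seed, 1])
    ages = rng.uniform(*cohort.age_range, size=cohort.n_subjects)
    geom = {}
    for i in range(cohort.n_subjects):
        for plane in cohort.planes:
            srng = np.random.default_rng([cohort.seed, 2, i, cohort.planes.index(plane)])
            offset = srng.normal(0.0, cohort.between_subject_sd)
            ap = max(base.ap_semiaxis + offset, 0.8)
            tx = max(base.tx_semiaxis + offset * base.tx_semiaxis / base.ap_semiaxis, 0.8)
            geom[(i, plane)] = (ap, tx)
    return ages, geom


def iter_cohort(cohort: CohortSpec, base: PhantomSpec):
    """Yield one record per (subject, plane, condition), lazily.

    Each record is a dict with keys ``subject, plane, condition, age,
    spec, sequence, truth``.  Lazy generation keeps the memory footprint
    to a single sequence, which matters for full-size cohorts.
    """
    ages, geom = _subject_geometry(cohort, base)
    for i in range(cohort.n_subjects):
        for plane in cohort.planes:
            ap0, tx0 = geom[(i, plane)]
            for k, cond in enumerate(cohort.conditions):
                eff = cohort.condition_effects[k]
                spec = base.replace(
                    ap_semiaxis=ap0 * eff,
                    tx_semiaxis=tx0 * eff,
                    seed=int(np.random.default_rng(
                        [cohort.seed, 3, i, cohort.planes.index(plane), k]
                    ).integers(2**31)),
                )
                ident = f"sub{i:02d}_{plane}_{cond}"
                seq, truth = make_phantom_sequence(spec, identifier=ident)
                yield {
                    "subject": i, "plane": plane, "condition": cond,
                    "age": float(ages[i]), "spec": spec,
                    "sequence": seq, "truth": truth,
                }


def make_cohort(
    cohort: CohortSpec, base: PhantomSpec
) -> tuple[list[dict], pd.DataFrame]:
    """Generate one cine sequence per (subject, plane, condition).

    Returns ``(records, truth_table)``.  Records are as in
    :func:`iter_cohort`; the truth table is in the long format the
    statistics stage consumes (``subject, plane, condition, measure,
    value, age``) with measure labels like ``area_mean`` or ``ap_min``,
    built from the analytic per-frame ground truth.
    """
    records, table_rows = [], []
    for rec in iter_cohort(cohort, base):
        records.append(rec)
        for measure in MEASURES:
            for stat in SUMMARIES:
                table_rows.append({
                    "subject": rec["subject"], "plane": rec["plane"],
                    "condition": rec["condition"],
                    "measure": f"{measure}_{stat}",
                    "value": rec["truth"].attrs["summary"][measure][stat],
                    "age": rec["age"],
                })
    return records, pd.DataFrame(table_rows)


def _analytic_summaries(spec_like: PhantomSpec) -> dict:
    """min/mean/max of each measure over the sampled sinusoid, no raster."""
    t = np.arange(spec_like.n_frames)
    f = 1.0 + spec_like.modulation_fraction * np.sin(
        2.0 * np.pi * t * spec_like.frame_interval / spec_like.respiratory_period
    )
    a = spec_like.ap_semiaxis * f
    b = spec_like.tx_semiaxis * f
    series = {"area": np.pi * a * b, "ap": 2 * a, "tx": 2 * b}
    return {
        m: {"min": float(v.min()), "mean": float(v.mean()), "max": float(v.max())}
        for m, v in series.items()
    }


def cohort_truth_table(cohort: CohortSpec, base: PhantomSpec) -> pd.DataFrame:
    """Analytic ground-truth cohort table without rasterizing any image.

    Identical layout and values to the truth table of :func:`make_cohort`
    (same RNG streams), but orders of magnitude faster — intended for
    statistical simulation studies.
    """
    ages, geom = _subject_geometry(cohort, base)
    rows = []
    for i in range(cohort.n_subjects):
        for plane in cohort.planes:
            ap0, tx0 = geom[(i, plane)]
            for k, cond in enumerate(cohort.conditions):
                eff = cohort.condition_effects[k]
                summ = _analytic_summaries(
                    base.replace(ap_semiaxis=ap0 * eff, tx_semiaxis=tx0 * eff)
                )
                for measure in MEASURES:
                    for stat in SUMMARIES:
                        rows.append({
                            "subject": i, "plane": plane, "condition": cond,
                            "measure": f"{measure}_{stat}",
                            "value": summ[measure][stat],
                            "age": float(ages[i]),
                        })
    return pd.DataFrame(rows)


def simulate_cohort_measurements(
    cohort: CohortSpec,
    base: PhantomSpec,
    measurement_cv: float = 0.04,
    seed: int | None = None,
) -> pd.DataFrame:
    """Cohort table with multiplicative measurement noise.

    Emulates what the imaging pipeline would deliver: the analytic truth
    per (subject, plane, condition, measure) perturbed by independent
    lognormal-like multiplicative noise of coefficient of variation
    ``measurement_cv`` (default 4%, on the order of the segmentation
    recovery error on phantoms).  Used for calibration and power studies
    of the statistics stage without running image segmentation.
    """
    table = cohort_truth_table(cohort, base)
    rng = np.random.default_rng(cohort.seed if seed is None else seed)
    noise = rng.normal(1.0, measurement_cv, size=len(table))
    out = table.copy()
    out["value"] = out["value"] * np.clip(noise, 0.05, None)
    return out
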