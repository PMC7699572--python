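"""End-to-end orchestration: simulate -> segment -> metrics -> summarize -> stats.

Stages hand data to each other exclusively through files in the run
directory, so any stage can be re-run or inspected on its own:

    run_dir/
      provenance.json            config, config hash, package version
      manifest.csv               one row per sequence (id, labels, seed, path)
      sequences/<id>.tif(.json)  simulated or converted cine stacks
      truth/<id>_truth.csv       analytic per-frame ground truth (simulation)
      truth_cohort.csv           ground-truth long-format cohort table
      masks/<id>_masks.tif       per-frame binary lumen masks
      metrics/<id>_metrics.csv   per-frame area / AP / TX table
      summary/<id>_summary.csv   true-min / mean / max per measure
      cohort_measured.csv        measured long-format cohort table
      paired_results.csv         baseline-vs-follow-up paired comparisons
      lmm_results.csv            mixed-model LSM changes per time level

Everything downstream of the seed is deterministic, so an identical
config reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .io import (
    read_mask_stack,
    read_metrics_csv,
    read_sequence,
    write_mask_stack,
    write_sequence,
)
from .metrics import sequence_metrics
from .phantom import MEASURES, SUMMARIES, CohortSpec, PhantomSpec, iter_cohort
from .segmentation import SeedPoint, SegmentationParams, segment_sequence
from .stats import lmm_results_table, paired_results_table
from .temporal import summarize

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "segment", "metrics", "summarize", "stats")

__all__ = ["RunConfig", "TemporalConfig", "StatsConfig", "run_pipeline", "ALL_STAGES"]


class ConfigError(ValueError):
    """Malformed run configuration."""


@dataclass(frozen=True)
class TemporalConfig:
    min_prominence: float = 0.1
    smoothing_window: int = 1


@dataclass(frozen=True)
class StatsConfig:
    condition: str = "15"
    baseline: str = "00"
    adjust: str = "bonferroni"
    normality_alpha: float = 0.05


def _build(cls, data: dict, where: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown keys in {where}: {sorted(unknown)}")
    # YAML gives lists where the dataclasses expect tuples
    coerced = {}
    for f in dataclasses.fields(cls):
        if f.name in data:
            v = data[f.name]
            coerced[f.name] = tuple(v) if isinstance(v, list) else v
    return cls(**coerced)


@dataclass(frozen=True)
class RunConfig:
    """Serializable description of one full pipeline run."""

    out_dir: str
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    sequences_dir: str | None = None  # external input when not simulating
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    cohort: CohortSpec = field(default_factory=CohortSpec)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    temporal: TemporalConfig = field(default_factory=TemporalConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)

    def __post_init__(self) -> None:
        bad = set(self.stages) - set(ALL_STAGES)
        if bad:
            raise ConfigError(f"unknown stages: {sorted(bad)}")

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        nested = {
            "phantom": PhantomSpec, "cohort": CohortSpec,
            "segmentation": SegmentationParams, "temporal": TemporalConfig,
            "stats": StatsConfig,
        }
        kwargs = {}
        for key, sub_cls in nested.items():
            if key in data:
                kwargs[key] = _build(sub_cls, data.pop(key) or {}, key)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for k, v in data.items():
            kwargs[k] = tuple(v) if isinstance(v, list) else v
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def _stage_simulate(config: RunConfig, run_dir: Path) -> None:
    cohort = dataclasses.replace(config.cohort, seed=config.seed)
    manifest_rows, table_rows = [], []
    for rec in iter_cohort(cohort, config.phantom):
        seq = rec["sequence"]
        path = write_sequence(seq, run_dir / "sequences" / f"{seq.identifier}.tif")
        truth = rec["truth"]
        truth_path = run_dir / "truth" / f"{seq.identifier}_truth.csv"
        truth_path.parent.mkdir(parents=True, exist_ok=True)
        truth.to_csv(truth_path, index=False, float_format="%.6g")
        r0, c0 = rec["spec"].lumen_center
        manifest_rows.append({
            "identifier": seq.identifier, "subject": rec["subject"],
            "plane": rec["plane"], "condition": rec["condition"],
            "age": rec["age"], "path": str(path.relative_to(run_dir)),
            "seed_row": int(round(r0)), "seed_col": int(round(c0)),
        })
        for measure in MEASURES:
            for stat in SUMMARIES:
                table_rows.append({
                    "subject": rec["subject"], "plane": rec["plane"],
                    "condition": rec["condition"],
                    "measure": f"{measure}_{stat}",
                    "value": truth.attrs["summary"][measure][stat],
                    "age": rec["age"],
                })
    pd.DataFrame(manifest_rows).to_csv(run_dir / "manifest.csv", index=False)
    pd.DataFrame(table_rows).to_csv(run_dir / "truth_cohort.csv",
                                    index=False, float_format="%.6g")


def _manifest(run_dir: Path) -> pd.DataFrame:
    path = run_dir / "manifest.csv"
    if not path.exists():
        raise FileNotFoundError(f"missing manifest: {path} (run the simulate stage "
                                "or provide one for external data)")
    return pd.read_csv(path, dtype={"condition": str})


def _stage_segment(config: RunConfig, run_dir: Path) -> None:
    manifest = _manifest(run_dir)
    src_root = Path(config.sequences_dir) if config.sequences_dir else run_dir
    for _, row in manifest.iterrows():
        seq_path = src_root / row["path"]
        if not seq_path.exists():
            raise FileNotFoundError(f"segment stage: missing input {seq_path}")
        seq = read_sequence(seq_path)
        seed = SeedPoint(int(row["seed_row"]), int(row["seed_col"]))
        masks = segment_sequence(seq, seed, config.segmentation)
        write_mask_stack([m.mask for m in masks],
                         run_dir / "masks" / f"{row['identifier']}_masks.tif")


def _stage_metrics(config: RunConfig, run_dir: Path) -> None:
    """Recompute metrics from written masks (verifies the file contract)."""
    manifest = _manifest(run_dir)
    src_root = Path(config.sequences_dir) if config.sequences_dir else run_dir
    for _, row in manifest.iterrows():
        mask_path = run_dir / "masks" / f"{row['identifier']}_masks.tif"
        if not mask_path.exists():
            raise FileNotFoundError(f"metrics stage: missing masks {mask_path}")
        masks = read_mask_stack(mask_path)
        seq = read_sequence(src_root / row["path"])
        metrics = sequence_metrics(list(masks), seq)
        out = run_dir / "metrics" / f"{row['identifier']}_metrics.csv"
        out.parent.mkdir(exist_ok=True)
        metrics.to_csv(out, index=False, float_format="%.6g")


def _stage_summarize(config: RunConfig, run_dir: Path) -> None:
    manifest = _manifest(run_dir)
    cohort_rows = []
    for _, row in manifest.iterrows():
        mpath = run_dir / "metrics" / f"{row['identifier']}_metrics.csv"
        if not mpath.exists():
            raise FileNotFoundError(f"summarize stage: missing metrics {mpath}")
        metrics = read_metrics_csv(mpath)
        summ = summarize(metrics, config.temporal.min_prominence,
                         config.temporal.smoothing_window)
        out = run_dir / "summary" / f"{row['identifier']}_summary.csv"
        out.parent.mkdir(exist_ok=True)
        summ.to_frame().to_csv(out, index=False, float_format="%.6g")
        for measure, s in summ.measures.items():
            for stat, val in (("min", s.t_min), ("mean", s.t_mean), ("max", s.t_max)):
                cohort_rows.append({
                    "subject": row["subject"], "plane": row["plane"],
                    "condition": str(row["condition"]),
                    "measure": f"{measure}_{stat}", "value": val,
                    "age": row["age"],
                })
    pd.DataFrame(cohort_rows).to_csv(run_dir / "cohort_measured.csv",
                                     index=False, float_format="%.6g")


def _stage_stats(config: RunConfig, run_dir: Path) -> None:
    path = run_dir / "cohort_measured.csv"
    if not path.exists():
        raise FileNotFoundError(f"stats stage: missing cohort table {path}")
    cohort = pd.read_csv(path, dtype={"condition": str})
    sc = config.stats
    paired = paired_results_table(cohort, condition=sc.condition, baseline=sc.baseline,
                                  adjust=sc.adjust, normality_alpha=sc.normality_alpha)
    paired.to_csv(run_dir / "paired_results.csv", index=False, float_format="%.6g")
    lmm = lmm_results_table(cohort, adjust=sc.adjust)
    lmm.to_csv(run_dir / "lmm_results.csv", index=False, float_format="%.6g")


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "segment": _stage_segment,
    "metrics": _stage_metrics,
    "summarize": _stage_summarize,
    "stats": _stage_stats,
}


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages in order; returns the run directory.

    A stage failure aborts with the stage name attached; outputs written
    so far are retained for debugging.
    """
    run_dir = Path(config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    provenance = {
        "config": config.to_dict(),
        "config_sha256": _config_hash(config),
        "aircine_version": __version__,
        "stages_run": list(config.stages),
    }
    (run_dir / "provenance.json").write_text(
        json.dumps(provenance, indent=1, sort_keys=True, default=str))
    for stage in ALL_STAGES:
        if stage not in config.stages:
            continue
        logger.info("stage %s ...", stage)
        try:
            _STAGE_FNS[stage](config, run_dir)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    return run_dir
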