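"""Reading and writing cine sequences, masks and metric tables.

Supported containers: DICOM series (read), NIfTI-1 (read/write),
multi-page TIFF with a JSON sidecar (read/write).  Axis convention
throughout: image rows run anterior -> posterior (AP), columns run
transverse (TX).  Physical metadata travels with the pixel data —
pixel spacing in mm and inter-frame interval in ms — and is taken from
the container where it can hold it, else from the sidecar, else the
read fails with an instruction rather than guessing a resolution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

METRICS_COLUMNS = ["frame", "time_ms", "area_mm2", "ap_mm", "tx_mm"]
SUMMARY_COLUMNS = ["measure", "t_min", "t_mean", "t_max", "n_peaks", "n_valleys"]

#: fallback inter-frame interval (ms) when neither container nor sidecar
#: carries timing; midpoint of the typical 300-400 ms cine resolution.
DEFAULT_FRAME_INTERVAL = 350.0


class FormatError(ValueError):
    """Unreadable or inconsistent image container."""


@dataclass
class CineSequence:
    """An ordered stack of 2-D grayscale frames with physical metadata.

    frames: array of shape ``(n_frames, rows, cols)``; row axis is
        anterior-posterior, column axis transverse.
    pixel_spacing: (mm per row-pixel, mm per column-pixel).
    frame_interval: ms between consecutive frames.
    """

    frames: np.ndarray
    pixel_spacing: tuple[float, float]
    frame_interval: float
    identifier: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise FormatError("frames must form a (n_frames, rows, cols) stack")
        if min(self.pixel_spacing) <= 0:
            raise FormatError("pixel spacing must be positive")
        if self.frame_interval <= 0:
            raise FormatError("frame interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def times_ms(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def _load_sidecar(path: Path) -> dict:
    sc = _sidecar_path(path)
    if sc.exists():
        return json.loads(sc.read_text())
    return {}


def read_sequence(
    path: str | Path,
    fmt: str | None = None,
    pixel_spacing: tuple[float, float] | None = None,
    frame_interval: float | None = None,
) -> CineSequence:
    """Read a cine sequence from DICOM dir, NIfTI file or multi-page TIFF.

    ``pixel_spacing`` / ``frame_interval`` override whatever the
    container or sidecar reports.  Format is inferred from the path when
    ``fmt`` (one of ``"dicom"``, ``"nifti"``, ``"tiff"``) is not given.
    """
    path = Path(path)
    if fmt is None:
        if path.is_dir():
            fmt = "dicom"
        elif path.name.endswith((".nii", ".nii.gz")):
            fmt = "nifti"
        elif path.suffix.lower() in (".tif", ".tiff"):
            fmt = "tiff"
        else:
            raise FormatError(f"cannot infer format of {path}")
    reader = {"dicom": _read_dicom, "nifti": _read_nifti, "tiff": _read_tiff}.get(fmt)
    if reader is None:
        raise FormatError(f"unrecognized format {fmt!r}")
    seq = reader(path)
    if pixel_spacing is not None:
        seq.pixel_spacing = tuple(float(s) for s in pixel_spacing)
    if frame_interval is not None:
        seq.frame_interval = float(frame_interval)
    if seq.pixel_spacing is None or min(seq.pixel_spacing) <= 0:
        raise FormatError(
            f"{path}: no pixel spacing in container or sidecar; "
            "pass pixel_spacing=(row_mm, col_mm) or provide a JSON sidecar"
        )
    return seq


def _read_dicom(path: Path) -> CineSequence:
    import pydicom

    files = sorted(p for p in path.iterdir() if p.is_file() and p.suffix != ".json")
    datasets = []
    for f in files:
        try:
            datasets.append(pydicom.dcmread(str(f)))
        except Exception:
            continue
    if not datasets:
        raise FormatError(f"no readable DICOM files in {path}")
    datasets.sort(key=lambda d: int(getattr(d, "InstanceNumber", 0)))
    arrays = [d.pixel_array.astype(float) for d in datasets]
    shapes = {a.shape for a in arrays}
    if len(shapes) > 1:
        raise FormatError(f"mixed frame shapes in {path}: {sorted(shapes)}")
    sidecar = _load_sidecar(path / "sequence")
    d0 = datasets[0]
    if getattr(d0, "PixelSpacing", None) is not None:
        spacing = (float(d0.PixelSpacing[0]), float(d0.PixelSpacing[1]))
    elif "pixel_spacing_mm" in sidecar:
        spacing = tuple(sidecar["pixel_spacing_mm"])
    else:
        raise FormatError(
            f"{path}: DICOM series lacks PixelSpacing and no sidecar found; "
            "provide sequence.json with pixel_spacing_mm"
        )
    if getattr(d0, "FrameTime", None) is not None:
        interval = float(d0.FrameTime)
    else:
        interval = float(sidecar.get("frame_interval_ms", DEFAULT_FRAME_INTERVAL))
    return CineSequence(np.stack(arrays), spacing, interval, identifier=path.name)


def _read_nifti(path: Path) -> CineSequence:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected rows x cols x frames NIfTI, got shape {data.shape}")
    zooms = img.header.get_zooms()
    sidecar = _load_sidecar(Path(str(path).removesuffix(".gz")))
    spacing = tuple(sidecar.get("pixel_spacing_mm", (float(zooms[0]), float(zooms[1]))))
    interval = float(sidecar.get("frame_interval_ms", zooms[2] if len(zooms) > 2 and zooms[2] > 0
                                 else DEFAULT_FRAME_INTERVAL))
    frames = np.moveaxis(data, 2, 0)
    return CineSequence(frames, spacing, interval, identifier=path.stem)


def _read_tiff(path: Path) -> CineSequence:
    import tifffile

    data = tifffile.imread(str(path))
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a multi-page 2-D TIFF, got shape {data.shape}")
    sidecar = _load_sidecar(path)
    if "pixel_spacing_mm" not in sidecar:
        raise FormatError(
            f"{path}: TIFF carries no spacing; provide {_sidecar_path(path).name} "
            "with pixel_spacing_mm (and frame_interval_ms)"
        )
    spacing = tuple(sidecar["pixel_spacing_mm"])
    interval = float(sidecar.get("frame_interval_ms", DEFAULT_FRAME_INTERVAL))
    return CineSequence(data.astype(float), spacing, interval, identifier=path.stem)


def write_sequence(seq: CineSequence, path: str | Path) -> Path:
    """Write a sequence as NIfTI (.nii/.nii.gz) or TIFF + JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        data = np.moveaxis(np.asarray(seq.frames, dtype=np.float32), 0, 2)
        affine = np.diag([seq.pixel_spacing[0], seq.pixel_spacing[1], 1.0, 1.0])
        img = nib.Nifti1Image(data, affine)
        img.header.set_zooms((seq.pixel_spacing[0], seq.pixel_spacing[1], seq.frame_interval))
        nib.save(img, str(path))
    elif path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        arr = np.asarray(seq.frames)
        if arr.dtype.kind == "f":
            arr = np.clip(np.round(arr), 0, 255).astype(np.uint8)
        tifffile.imwrite(str(path), arr, photometric="minisblack")
        _sidecar_path(path).write_text(json.dumps({
            "pixel_spacing_mm": list(seq.pixel_spacing),
            "frame_interval_ms": seq.frame_interval,
            "identifier": seq.identifier,
        }, indent=1, sort_keys=True))
    else:
        raise FormatError(f"unsupported output container: {path}")
    return path


def write_metrics_csv(metrics: pd.DataFrame, path: str | Path) -> Path:
    """Write the per-frame metrics table with its fixed header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    metrics.to_csv(path, index=False, columns=METRICS_COLUMNS, float_format="%.6g")
    return path


def read_metrics_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(METRICS_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: metrics CSV missing columns {sorted(missing)}")
    return df


def write_mask_stack(masks, path: str | Path) -> Path:
    """Write per-frame binary masks as a uint8 label stack (TIFF or NIfTI)."""
    stack = np.stack([np.asarray(m, dtype=np.uint8) for m in masks])
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(str(path), stack, photometric="minisblack")
    elif path.name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        nib.save(nib.Nifti1Image(np.moveaxis(stack, 0, 2), np.eye(4)), str(path))
    else:
        raise FormatError(f"unsupported mask container: {path}")
    return path


def read_mask_stack(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        return tifffile.imread(str(path)).astype(bool)
    if path.name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        return np.moveaxis(np.asarray(nib.load(str(path)).dataobj), 2, 0).astype(bool)
    raise FormatError(f"unsupported mask container: {path}")


def write_outputs(
    identifier: str,
    masks,
    metrics: pd.DataFrame,
    out_dir: str | Path,
    mask_format: str = "tiff",
) -> dict[str, Path]:
    """Write one sequence's masks and metrics table into ``out_dir``.

    Idempotent: identical inputs produce byte-identical files.
    """
    if len(masks) != len(metrics):
        raise ValueError(
            f"{identifier}: {len(masks)} masks but {len(metrics)} metric rows"
        )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ext = {"tiff": ".tif", "nifti": ".nii"}[mask_format]
    mask_path = write_mask_stack(masks, out_dir / f"{identifier}_masks{ext}")
    metrics_path = write_metrics_csv(metrics, out_dir / f"{identifier}_metrics.csv")
    return {"masks": mask_path, "metrics": metrics_path}
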