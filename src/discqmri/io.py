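"""NIfTI and tabular I/O for the pipeline.

Image volumes travel as NIfTI-1 with voxel spacing in the header zooms;
a 4-D stack carries the acquisition axis last with a JSON sidecar listing
the spin-lock times.  Round-trips preserve data and spacing exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .geometry import DiscSegmentation
from .relaxometry import RelaxationMap, SpinLockSeries

__all__ = [
    "write_series",
    "read_series",
    "write_segmentation",
    "read_segmentation",
    "write_map",
    "read_map",
]


class FormatError(ValueError):
    """Inconsistent on-disk inputs (dimension/spacing/TSL mismatches)."""


def _affine(spacing: tuple[float, ...]) -> np.ndarray:
    aff = np.eye(4)
    for i, s in enumerate(spacing[:3]):
        aff[i, i] = s
    return aff


def _save(path: Path, data: np.ndarray, spacing: tuple[float, ...]) -> None:
    img = nib.Nifti1Image(np.asarray(data), _affine(spacing))
    img.header.set_zooms(tuple(spacing[:3]) + ((1.0,) if data.ndim == 4 else ()))
    nib.save(img, str(path))


def _load(path: Path) -> tuple[np.ndarray, tuple[float, ...]]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj), tuple(float(z) for z in img.header.get_zooms()[:3])


def write_series(series: SpinLockSeries, out_dir: str | Path, stem: str | None = None) -> Path:
    """Write a spin-lock series as <stem>.nii.gz plus a TSL sidecar JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = stem or f"series_{series.modality_tag.lower()}"
    _save(out_dir / f"{stem}.nii.gz", series.signals, series.spacing_mm)
    sidecar = {
        "tsl_ms": [float(t) for t in series.tsl_ms],
        "modality": series.modality_tag,
    }
    (out_dir / f"{stem}.json").write_text(json.dumps(sidecar, indent=2))
    return out_dir / f"{stem}.nii.gz"


def read_series(nifti_path: str | Path, sidecar_path: str | Path | None = None) -> SpinLockSeries:
    nifti_path = Path(nifti_path)
    sidecar_path = Path(sidecar_path) if sidecar_path else nifti_path.with_suffix("").with_suffix(".json")
    data, spacing = _load(nifti_path)
    if data.ndim != 4:
        raise FormatError(f"{nifti_path} is not a 4-D series")
    meta = json.loads(Path(sidecar_path).read_text())
    tsl = np.asarray(meta["tsl_ms"], dtype=float)
    if tsl.size != data.shape[-1]:
        raise FormatError(
            f"sidecar lists {tsl.size} TSLs but {nifti_path} has {data.shape[-1]} acquisitions"
        )
    return SpinLockSeries(data, tsl, spacing_mm=spacing, modality_tag=meta.get("modality", "T1rho"))


def write_segmentation(seg: DiscSegmentation, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    _save(path, seg.labels.astype(np.int16), seg.spacing_mm)
    return path


def read_segmentation(path: str | Path, axis_convention: dict | None = None) -> DiscSegmentation:
    data, spacing = _load(Path(path))
    return DiscSegmentation(
        np.rint(np.asarray(data)).astype(np.int16), spacing_mm=spacing, axis_convention=axis_convention
    )


def write_map(rmap: RelaxationMap, out_dir: str | Path, stem: str | None = None) -> dict[str, Path]:
    """Write t_ms / s0 / fit_r2 / valid volumes of a relaxation map."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = stem or f"map_{rmap.modality_tag.lower()}"
    paths = {}
    for name, arr in (
        ("t_ms", rmap.t_ms),
        ("s0", rmap.s0),
        ("fit_r2", rmap.fit_r2),
        ("valid", rmap.valid.astype(np.uint8)),
    ):
        p = out_dir / f"{stem}_{name}.nii.gz"
        _save(p, arr, rmap.spacing_mm)
        paths[name] = p
    return paths


def read_map(out_dir: str | Path, stem: str) -> RelaxationMap:
    out_dir = Path(out_dir)
    vols = {}
    spacing = (1.0, 1.0, 1.0)
    for name in ("t_ms", "s0", "fit_r2", "valid"):
        data, spacing = _load(out_dir / f"{stem}_{name}.nii.gz")
        vols[name] = data
    modality = "T2" if stem.endswith("t2") else "T1rho"
    return RelaxationMap(
        s0=np.asarray(vols["s0"], dtype=float),
        t_ms=np.asarray(vols["t_ms"], dtype=float),
        fit_r2=np.asarray(vols["fit_r2"], dtype=float),
        valid=np.asarray(vols["valid"]).astype(bool),
        modality_tag=modality,
        spacing_mm=spacing,
    )
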