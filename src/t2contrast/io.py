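"""NIfTI and tabular I/O.

Volumes travel as NIfTI-1 via nibabel; echo-time metadata travels in a JSON
sidecar next to the 4D file (``<stem>.json`` with ``echo_times_ms``) rather
than being packed into the NIfTI time-axis spacing, which dialects disagree
on.  All computation happens in voxel space; the affine is carried through
untouched for provenance.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .relaxometry import EchoTrainVolume

__all__ = [
    "save_echo_train",
    "load_echo_train",
    "save_volume",
    "load_volume",
    "save_mask",
    "load_mask",
    "save_subject_table",
    "load_subject_table",
]


def _sidecar_path(nifti_path: Path) -> Path:
    name = nifti_path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return nifti_path.with_name(name[: -len(suffix)] + ".json")
    return nifti_path.with_suffix(".json")


def _affine(voxel_size_mm) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size_mm
    return aff


def save_echo_train(volume: EchoTrainVolume, path: str | Path) -> Path:
    """Write a 4D echo train (echo as 4th axis) plus its echo-time sidecar."""
    path = Path(path)
    aff = volume.affine if volume.affine is not None else _affine(volume.voxel_size_mm)
    nib.save(nib.Nifti1Image(np.asarray(volume.intensities, dtype=np.float32), aff), path)
    sidecar = _sidecar_path(path)
    sidecar.write_text(json.dumps({
        "echo_times_ms": [float(t) for t in volume.echo_times_ms],
        "units": "ms",
    }, indent=2))
    return path


def load_echo_train(path: str | Path) -> EchoTrainVolume:
    path = Path(path)
    img = nib.load(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"echo-time sidecar not found: {sidecar}")
    meta = json.loads(sidecar.read_text())
    zooms = img.header.get_zooms()[:3]
    return EchoTrainVolume(
        intensities=np.asarray(img.dataobj, dtype=float),
        echo_times_ms=np.asarray(meta["echo_times_ms"], dtype=float),
        voxel_size_mm=tuple(float(z) for z in zooms),
        affine=np.asarray(img.affine),
    )


def save_volume(data: np.ndarray, path: str | Path,
                voxel_size_mm=(1.0, 1.0, 1.0), units: str | None = None) -> Path:
    """Write a 3D scalar map; optional units recorded in a sidecar."""
    path = Path(path)
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), _affine(voxel_size_mm)), path)
    if units is not None:
        _sidecar_path(path).write_text(json.dumps({"units": units}, indent=2))
    return path


def load_volume(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(Path(path)).dataobj, dtype=float)


def save_mask(mask: np.ndarray, path: str | Path, voxel_size_mm=(1.0, 1.0, 1.0)) -> Path:
    path = Path(path)
    nib.save(
        nib.Nifti1Image(np.asarray(mask).astype(np.uint8), _affine(voxel_size_mm)), path
    )
    return path


def load_mask(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(Path(path)).dataobj) > 0


def save_subject_table(subjects, path: str | Path, seeds: dict[str, int] | None = None) -> Path:
    """Cohort CSV: subject_id, age_years, sex (and the per-subject seed if known)."""
    path = Path(path)
    rows = [{"subject_id": s.subject_id, "age_years": s.age_years, "sex": s.sex}
            for s in subjects]
    df = pd.DataFrame(rows)
    if seeds is not None:
        df["seed"] = df["subject_id"].map(seeds)
    df.to_csv(path, index=False)
    return path


def load_subject_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(Path(path))
    required = {"subject_id", "age_years"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"subject table missing columns: {sorted(missing)}")
    return df
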