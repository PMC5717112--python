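"""Reading and writing subject data and derived maps.

Each subject is stored as NIfTI volumes — one 4D file per velocity
direction (``vel_x.nii``, ``vel_y.nii``, ``vel_z.nii``) plus a 4D magnitude
file — with voxel spacing and frame timing in the header, a JSON sidecar
holding venc, seeds and the phantom truth summary, and a cohort manifest
listing group membership. Wall-point data travel as plain-text tables.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np
import pandas as pd

from .core import AortaMask, MagnitudeSeries, VelocityField4D, WallPointSet
from .phantom import SubjectData

_VEL_FILES = ("vel_x.nii", "vel_y.nii", "vel_z.nii")


def _affine(spacing) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    return aff


def _write_nifti(path: Path, data_txyz: np.ndarray, spacing, frame_dt_ms: float):
    # NIfTI stores (x, y, z, t)
    img = nib.Nifti1Image(np.moveaxis(data_txyz, 0, -1).astype(np.float32), _affine(spacing))
    zooms = tuple(spacing) + (frame_dt_ms / 1000.0,)
    img.header.set_zooms(zooms)
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))


def _read_nifti_4d(path: Path) -> tuple[np.ndarray, tuple, float]:
    img = nib.load(str(path))
    data = np.moveaxis(np.asarray(img.get_fdata(), float), -1, 0)
    zooms = img.header.get_zooms()
    spacing = tuple(float(z) for z in zooms[:3])
    frame_dt = float(zooms[3]) * 1000.0 if len(zooms) > 3 else 0.0
    return data, spacing, frame_dt


def write_subject(directory: str | Path, subject: SubjectData) -> Path:
    """Write one subject's measured data plus metadata sidecar."""
    d = Path(directory) / subject.subject_id
    d.mkdir(parents=True, exist_ok=True)
    field = subject.velocity
    for axis, name in enumerate(_VEL_FILES):
        _write_nifti(d / name, field.data[..., axis], field.spacing, field.frame_dt)
    _write_nifti(d / "magnitude.nii", subject.magnitude.data, field.spacing, field.frame_dt)
    meta = {
        "subject_id": subject.subject_id,
        "group": subject.group,
        "venc": list(field.venc),
        "frame_dt_ms": field.frame_dt,
        "seed": subject.config.seed,
        "truth": {
            "v_max_true": subject.truth.v_max_true,
            "wall_wss_analytic": _json_num(subject.truth.wall_wss_analytic),
            "el_analytic": _json_num(subject.truth.el_analytic),
        },
    }
    (d / "meta.json").write_text(json.dumps(meta, indent=2))
    write_mask(d / "truth_mask.nii", subject.truth.mask)
    return d


def _json_num(x: float):
    return None if (x is None or not np.isfinite(x)) else float(x)


def read_subject(directory: str | Path) -> tuple[VelocityField4D, MagnitudeSeries, dict]:
    """Read a subject directory written by :func:`write_subject` (or any
    same-layout acquisition)."""
    d = Path(directory)
    meta = json.loads((d / "meta.json").read_text()) if (d / "meta.json").exists() else {}
    comps = []
    spacing = frame_dt = None
    for name in _VEL_FILES:
        path = d / name
        if not path.exists():
            raise FileNotFoundError(f"missing velocity file: {path}")
        data, spacing, frame_dt = _read_nifti_4d(path)
        comps.append(data)
    vel = np.stack(comps, axis=-1)
    venc = tuple(meta.get("venc", (1.5, 1.5, 1.5)))
    frame_dt = meta.get("frame_dt_ms", frame_dt)
    field = VelocityField4D(vel, spacing, frame_dt, venc)
    mag_data, _, _ = _read_nifti_4d(d / "magnitude.nii")
    magnitude = MagnitudeSeries(mag_data, spacing)
    return field, magnitude, meta


def write_mask(path: str | Path, mask: AortaMask):
    img = nib.Nifti1Image(mask.data.astype(np.uint8), _affine(mask.spacing))
    img.header.set_zooms(tuple(mask.spacing))
    nib.save(img, str(path))


def read_mask(path: str | Path) -> AortaMask:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return AortaMask(np.asarray(img.get_fdata()) > 0.5, spacing)


def write_volume(path: str | Path, data: np.ndarray, spacing):
    img = nib.Nifti1Image(np.asarray(data, np.float32), _affine(spacing))
    img.header.set_zooms(tuple(spacing))
    nib.save(img, str(path))


def write_manifest(path: str | Path, subjects: list[SubjectData]):
    manifest = [{"subject_id": s.subject_id, "group": s.group} for s in subjects]
    Path(path).write_text(json.dumps(manifest, indent=2))


def read_manifest(path: str | Path) -> list[dict]:
    return json.loads(Path(path).read_text())


def wall_table(wall: WallPointSet, wss_vectors: Optional[np.ndarray] = None) -> pd.DataFrame:
    """Wall points as a plain table (x, y, z, nx, ny, nz, radius[, wss...])."""
    df = pd.DataFrame(
        {
            "x": wall.points[:, 0],
            "y": wall.points[:, 1],
            "z": wall.points[:, 2],
            "nx": wall.normals[:, 0],
            "ny": wall.normals[:, 1],
            "nz": wall.normals[:, 2],
            "radius": wall.radius,
        }
    )
    if wss_vectors is not None:
        df["wssx"] = wss_vectors[:, 0]
        df["wssy"] = wss_vectors[:, 1]
        df["wssz"] = wss_vectors[:, 2]
    return df


def write_wall_table(path: str | Path, wall: WallPointSet, wss_vectors=None):
    wall_table(wall, wss_vectors).to_csv(path, sep="\t", index=False, float_format="%.6g")
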