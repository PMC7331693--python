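"""Standard-format I/O: NIfTI / multipage-TIFF volumes, 4D vector fields,
JSON sidecars and cohort manifests.

Headers record the package's coordinate convention: 0-based voxel indices,
axis order (z = cranial->caudal, y = dorsal->ventral, x = left->right).
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import tifffile

from .core import VoxelGrid3D, XVError
from .velocimetry import DisplacementField

AXIS_CONVENTION = "0-based voxel indices; axes (z: cranial->caudal, y: dorsal->ventral, x: left->right)"


def _affine(voxel_size: float) -> np.ndarray:
    return np.diag([voxel_size, voxel_size, voxel_size, 1.0])


def save_volume(grid: VoxelGrid3D, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    suffixes = "".join(path.suffixes)
    if suffixes.endswith((".nii", ".nii.gz")):
        img = nib.Nifti1Image(np.asarray(grid.data, dtype=np.float32), _affine(grid.voxel_size))
        img.header["descrip"] = b"xvlung volume"
        nib.save(img, str(path))
    elif path.suffix in (".tif", ".tiff"):
        tifffile.imwrite(str(path), np.asarray(grid.data, dtype=np.float32))
    else:
        raise XVError(f"unsupported volume format: {path.name}")
    return path


def load_volume(path: str | Path, voxel_size: float | None = None) -> VoxelGrid3D:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input volume not found: {path}")
    suffixes = "".join(path.suffixes)
    if suffixes.endswith((".nii", ".nii.gz")):
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=float)
        vs = float(abs(img.affine[0, 0])) if voxel_size is None else voxel_size
        return VoxelGrid3D(data, vs or 1.0)
    if path.suffix in (".tif", ".tiff"):
        data = np.asarray(tifffile.imread(str(path)), dtype=float)
        return VoxelGrid3D(data, voxel_size or 1.0)
    raise XVError(f"unsupported volume format: {path.name}")


def save_field(fld: DisplacementField, path: str | Path, voxel_size: float = 1.0) -> Path:
    """Vector field as 4D NIfTI (components stacked on the 4th axis) plus a
    JSON sidecar carrying the XV grid geometry."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(fld.vectors, dtype=np.float32), _affine(voxel_size))
    nib.save(img, str(path))
    sidecar = {
        "axis_convention": AXIS_CONVENTION,
        "units": "voxels/frame",
        "grid_origin": list(fld.grid_origin),
        "grid_stride": int(fld.grid_stride),
        "window_size": int(fld.window_size),
        "phase_index": int(fld.phase_index),
    }
    with open(path.with_suffix("").with_suffix(".json") if path.name.endswith(".nii.gz") else path.with_suffix(".json"), "w") as fh:
        json.dump(sidecar, fh, indent=2)
    return path


def load_field(path: str | Path) -> DisplacementField:
    path = Path(path)
    img = nib.load(str(path))
    vectors = np.asarray(img.dataobj, dtype=float)
    side = path.with_suffix("").with_suffix(".json") if path.name.endswith(".nii.gz") else path.with_suffix(".json")
    meta = {}
    if Path(side).exists():
        with open(side) as fh:
            meta = json.load(fh)
    valid = np.isfinite(vectors).all(axis=-1)
    return DisplacementField(
        vectors=vectors,
        valid=valid,
        peak_quality=np.full(vectors.shape[:3], np.nan),
        grid_origin=tuple(meta.get("grid_origin", (0.0, 0.0, 0.0))),
        grid_stride=int(meta.get("grid_stride", 1)),
        phase_index=int(meta.get("phase_index", 0)),
        window_size=int(meta.get("window_size", 2 * int(meta.get("grid_stride", 1)))),
        meta=meta,
    )


def write_manifest(rows: list[dict], path: str | Path) -> Path:
    """Cohort manifest CSV: animal id, group label, file paths."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_manifest(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    df = pd.read_csv(path)
    required = {"id", "group"}
    if not required.issubset(df.columns):
        raise XVError(f"manifest must contain columns {sorted(required)}")
    return df


def save_json(obj: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=float)
    return path
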