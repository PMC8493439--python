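"""Readers and writers for the formats the pipeline consumes and emits.

Volumes are NIfTI (via nibabel; voxel dimensions come from the header zooms,
world orientation is otherwise ignored since atlases are assumed grid
aligned); meshes are ASCII OFF (via trimesh); tables are comma-separated
UTF-8 with a header row; per-vertex maps are CSV keyed by vertex index;
manifests and truth records are JSON with sorted keys.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .mesh import SurfaceMesh

REQUIRED_COHORT_COLUMNS = (
    "subject_id",
    "age",
    "female",
    "race_ethnicity",
    "apoe4",
    "entorhinal_baseline",
    "interval_years",
)


def save_nifti(path: str | Path, data: np.ndarray, voxel_size: Sequence[float]) -> None:
    """Write a 3D array as NIfTI with the given voxel dimensions (mm)."""
    data = np.asarray(data)
    if not np.all(np.isfinite(data.astype(float))):
        raise ValueError("refusing to write non-finite voxel values")
    affine = np.diag(list(voxel_size) + [1.0])
    img = nib.Nifti1Image(np.asarray(data), affine)
    img.header.set_zooms(tuple(float(v) for v in voxel_size))
    nib.save(img, str(path))


def load_nifti(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read a 3D NIfTI; returns (array, voxel sizes in mm)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {data.shape}")
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    if any(z <= 0 for z in zooms):
        raise ValueError(f"{path}: malformed header, nonpositive voxel size {zooms}")
    if np.issubdtype(data.dtype, np.floating) and not np.all(np.isfinite(data)):
        raise ValueError(f"{path}: volume contains non-finite values")
    return data, zooms


def save_mesh_off(path: str | Path, mesh: SurfaceMesh) -> None:
    import trimesh

    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    Path(path).write_text(tm.export(file_type="off"))


def load_mesh_off(path: str | Path) -> SurfaceMesh:
    import trimesh

    tm = trimesh.load(str(path), file_type="off", process=False)
    return SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces))


def write_cohort_csv(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def read_cohort_csv(
    path: str | Path, required: Sequence[str] = REQUIRED_COHORT_COLUMNS
) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: cohort CSV missing required columns {missing}")
    return table


def write_vertex_map_csv(path: str | Path, values: np.ndarray, name: str = "value") -> None:
    """Per-vertex scalar map as a two-column CSV keyed by vertex index."""
    pd.DataFrame(
        {"vertex": np.arange(len(values)), name: np.asarray(values)}
    ).to_csv(path, index=False)


def read_vertex_map_csv(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path)
    if "vertex" not in df.columns or df.shape[1] < 2:
        raise ValueError(f"{path}: expected columns 'vertex' and a value column")
    value_col = [c for c in df.columns if c != "vertex"][0]
    out = np.empty(len(df))
    out[df["vertex"].to_numpy()] = df[value_col].to_numpy()
    return out


def write_json(path: str | Path, obj: dict) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
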