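"""File I/O: NIfTI volumes, PLY meshes, legacy-VTK polydata, tag CSVs, JSON sidecars.

The on-disk convention mirrors the in-memory one: meshes and tag points are in
physical mm, volumes carry origin + spacing in an axis-aligned affine.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import trimesh

from .core import SurfaceMesh, VoxelVolume

__all__ = [
    "write_volume",
    "read_volume",
    "write_mesh_ply",
    "read_mesh",
    "write_polydata_vtk",
    "write_tags_csv",
    "read_tags_csv",
    "write_json",
    "read_json",
]


def write_volume(volume: VoxelVolume, path) -> Path:
    """Write a volume as NIfTI; spacing/origin go into a diagonal affine."""
    path = Path(path)
    affine = np.diag(list(volume.spacing_mm) + [1.0])
    affine[:3, 3] = volume.origin_mm
    img = nib.Nifti1Image(volume.intensities.astype(np.float32), affine)
    if volume.time_post_gbca_min is not None:
        img.header["descrip"] = f"t_post_gbca_min={volume.time_post_gbca_min}".encode()
    try:
        nib.save(img, str(path))
    except OSError as exc:  # pragma: no cover - io failure path
        raise OSError(f"failed to write volume to {path}: {exc}") from exc
    return path


def read_volume(path) -> VoxelVolume:
    path = Path(path)
    img = nib.load(str(path))
    affine = img.affine
    if not np.allclose(affine[:3, :3], np.diag(np.diag(affine[:3, :3]))):
        raise ValueError(f"{path}: only axis-aligned (diagonal) affines are supported")
    spacing = np.diag(affine[:3, :3]).copy()
    t_min = None
    descrip = bytes(img.header["descrip"]).split(b"\x00")[0].decode(errors="ignore")
    if descrip.startswith("t_post_gbca_min="):
        t_min = float(descrip.split("=", 1)[1])
    return VoxelVolume(
        intensities=np.asanyarray(img.dataobj).astype(float),
        spacing_mm=spacing,
        origin_mm=affine[:3, 3].copy(),
        time_post_gbca_min=t_min,
    )


def write_mesh_ply(mesh: SurfaceMesh, path) -> Path:
    path = Path(path)
    # ASCII keeps the artefact text-only and diffable
    mesh.to_trimesh().export(str(path), encoding="ascii")
    return path


def read_mesh(path) -> SurfaceMesh:
    """Read a shell from PLY (trimesh) or legacy-ASCII VTK polydata."""
    path = Path(path)
    if path.suffix.lower() == ".vtk":
        return _read_polydata_vtk(path)
    tm = trimesh.load(str(path), process=False, force="mesh")
    return SurfaceMesh.from_trimesh(tm)


def write_polydata_vtk(mesh: SurfaceMesh, path, cell_data: dict[str, np.ndarray] | None = None) -> Path:
    """Write legacy-ASCII VTK polydata with optional per-face (cell) scalars."""
    path = Path(path)
    lines = [
        "# vtk DataFile Version 3.0",
        "atrial shell",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {len(mesh.vertices)} float",
    ]
    lines += [" ".join(f"{c:.6f}" for c in v) for v in mesh.vertices]
    m = mesh.n_faces
    lines.append(f"POLYGONS {m} {4 * m}")
    lines += ["3 " + " ".join(str(i) for i in f) for f in mesh.faces]
    if cell_data:
        lines.append(f"CELL_DATA {m}")
        for name, values in cell_data.items():
            values = np.asarray(values, dtype=float).reshape(m)
            lines.append(f"SCALARS {name} float 1")
            lines.append("LOOKUP_TABLE default")
            lines += [f"{v:.6f}" for v in values]
    path.write_text("\n".join(lines) + "\n")
    return path


def _read_polydata_vtk(path: Path) -> SurfaceMesh:
    tokens = path.read_text().split("\n")
    verts, faces = [], []
    i = 0
    while i < len(tokens):
        line = tokens[i].strip()
        if line.startswith("POINTS"):
            n = int(line.split()[1])
            j = i + 1
            while len(verts) < n:
                verts.append([float(x) for x in tokens[j].split()])
                j += 1
            i = j
            continue
        if line.startswith("POLYGONS"):
            m = int(line.split()[1])
            for j in range(i + 1, i + 1 + m):
                parts = [int(x) for x in tokens[j].split()]
                if parts[0] != 3:
                    raise ValueError(f"{path}: non-triangular polygon in VTK file")
                faces.append(parts[1:])
            i = i + 1 + m
            continue
        i += 1
    return SurfaceMesh(np.array(verts), np.array(faces))


def write_tags_csv(points_mm: np.ndarray, path) -> Path:
    path = Path(path)
    pd.DataFrame(np.atleast_2d(points_mm), columns=["x_mm", "y_mm", "z_mm"]).to_csv(
        path, index=False
    )
    return path


def read_tags_csv(path) -> np.ndarray:
    df = pd.read_csv(path)
    missing = {"x_mm", "y_mm", "z_mm"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: tag CSV missing columns {sorted(missing)}")
    return df[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, (np.bool_,)):
            return bool(obj)
        return super().default(obj)


def write_json(obj, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, cls=_NumpyEncoder) + "\n")
    return path


def read_json(path):
    return json.loads(Path(path).read_text())
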