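"""Core containers: scalar voxel volumes and triangulated surface shells.

Everything downstream (ROI metrics, shell projection, scar thresholding,
co-location) operates on these two types.  Coordinates are physical
millimetres throughout; volumes are axis-aligned with
``world = origin + index * spacing`` and 0-based voxel indices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["VoxelVolume", "SurfaceMesh"]


@dataclass
class VoxelVolume:
    """A 3D scalar intensity grid with physical spacing.

    Parameters
    ----------
    intensities : (nx, ny, nz) float array
        Voxel intensities.
    spacing_mm : (3,) array
        Millimetres per voxel along each axis; all strictly positive.
    origin_mm : (3,) array
        World coordinate of voxel index (0, 0, 0).
    time_post_gbca_min : float, optional
        Minutes since contrast injection, when known.
    """

    intensities: np.ndarray
    spacing_mm: np.ndarray
    origin_mm: np.ndarray = None
    time_post_gbca_min: float | None = None

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 3 or min(self.intensities.shape) < 1:
            raise ValueError("intensities must be a non-empty 3D array")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")
        self.spacing_mm = np.asarray(self.spacing_mm, dtype=float).reshape(3)
        if np.any(self.spacing_mm <= 0):
            raise ValueError("all spacings must be > 0")
        if self.origin_mm is None:
            self.origin_mm = np.zeros(3)
        self.origin_mm = np.asarray(self.origin_mm, dtype=float).reshape(3)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    def world_to_voxel(self, points_mm: np.ndarray) -> np.ndarray:
        """Continuous voxel coordinates of world points (mm)."""
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        return (pts - self.origin_mm) / self.spacing_mm

    def voxel_to_world(self, idx: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        return self.origin_mm + idx * self.spacing_mm

    def voxel_centers_world(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World coordinates of voxel centres along each axis (1D each)."""
        return tuple(
            self.origin_mm[a] + np.arange(self.shape[a]) * self.spacing_mm[a]
            for a in range(3)
        )


@dataclass
class SurfaceMesh:
    """A triangulated shell in physical mm coordinates.

    Face normals are expected to point out of the enclosed blood pool;
    orientation is validated against the vertex centroid on construction and
    auto-corrected with a warning if the mesh appears inward-wound.
    """

    vertices: np.ndarray
    faces: np.ndarray
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (n, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be (m, 3) vertex index triples")
        if self.faces.min(initial=0) < 0 or self.faces.max(initial=-1) >= len(self.vertices):
            raise ValueError("face vertex indices out of range")
        self._validate_orientation()

    # -- derived per-face geometry -------------------------------------------------

    def _tri(self) -> np.ndarray:
        return self.vertices[self.faces]  # (m, 3, 3)

    @property
    def face_centroids(self) -> np.ndarray:
        if "centroids" not in self._cache:
            self._cache["centroids"] = self._tri().mean(axis=1)
        return self._cache["centroids"]

    @property
    def face_areas(self) -> np.ndarray:
        if "areas" not in self._cache:
            t = self._tri()
            cross = np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0])
            self._cache["areas"] = 0.5 * np.linalg.norm(cross, axis=1)
        return self._cache["areas"]

    @property
    def face_normals(self) -> np.ndarray:
        if "normals" not in self._cache:
            t = self._tri()
            cross = np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0])
            norm = np.linalg.norm(cross, axis=1, keepdims=True)
            if np.any(norm == 0):
                raise ValueError("degenerate (zero-area) face in mesh")
            self._cache["normals"] = cross / norm
        return self._cache["normals"]

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def total_area(self) -> float:
        return float(self.face_areas.sum())

    def centroid_tree(self) -> cKDTree:
        if "ctree" not in self._cache:
            self._cache["ctree"] = cKDTree(self.face_centroids)
        return self._cache["ctree"]

    # -- orientation ---------------------------------------------------------------

    def _validate_orientation(self):
        """Flip winding if normals predominantly point at the interior centroid."""
        if len(self.faces) == 0:
            return
        t = self._tri()
        cross = np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0])
        centroid = self.vertices.mean(axis=0)
        outward = t.mean(axis=1) - centroid
        score = np.einsum("ij,ij->i", cross, outward)
        if np.mean(score > 0) < 0.5:
            warnings.warn(
                "mesh winding appears inward; flipping faces so normals point "
                "out of the blood pool",
                stacklevel=3,
            )
            self.faces = self.faces[:, ::-1].copy()
            self._cache.clear()

    # -- conversions ---------------------------------------------------------------

    def to_trimesh(self):
        import trimesh

        return trimesh.Trimesh(self.vertices.copy(), self.faces.copy(), process=False)

    @classmethod
    def from_trimesh(cls, tm) -> "SurfaceMesh":
        return cls(np.asarray(tm.vertices, dtype=float), np.asarray(tm.faces))

    def transformed(self, rotation: np.ndarray, translation_mm: np.ndarray) -> "SurfaceMesh":
        """Return a rigidly transformed copy (rotation then translation)."""
        v = self.vertices @ np.asarray(rotation).T + np.asarray(translation_mm)
        return SurfaceMesh(v, self.faces.copy())
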