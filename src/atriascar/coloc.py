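"""Scar / ablation-lesion co-location.

The imaging-derived shell is fused to the electroanatomic-mapping (EAM) shell
by rigid point-to-point iterative closest point (ICP) registration using
geometry only — registration is blind to the scar values by construction.
Ablation lesion tags (VisiTag-style exported points) mark EAM faces within a
geometric range (default 3 mm), and co-location of thresholded scar with the
tagged faces is scored with a Sørensen–Dice coefficient over face sets:

    DSC = 2 |Scar ∩ Lesion| / (|Scar| + |Lesion|)

with face-count masses by default (area weighting optional).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .core import SurfaceMesh

__all__ = [
    "RigidTransform",
    "LesionTagSet",
    "DscResult",
    "IcpResult",
    "icp_rigid",
    "tag_faces",
    "dsc",
    "coloc_pipeline",
    "CoLocationResult",
]


@dataclass
class RigidTransform:
    """A proper rigid transform: ``p -> rotation @ p + translation_mm``."""

    rotation: np.ndarray
    translation_mm: np.ndarray

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation_mm = np.asarray(self.translation_mm, dtype=float).reshape(3)
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation must be orthonormal (within 1e-8)")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("rotation must be proper (det = +1)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.atleast_2d(points) @ self.rotation.T + self.translation_mm

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation_mm)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation_mm + self.translation_mm,
        )

    def as_matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation_mm
        return m

    @property
    def rotation_angle_deg(self) -> float:
        cos = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(cos, -1.0, 1.0))))


@dataclass
class LesionTagSet:
    """Ablation lesion tag points with their geometric marking radius.

    The mapping system's force / time / percentage filters are applied
    upstream at acquisition; only the geometric ``range_mm`` rule (default
    3 mm) is applied here.
    """

    points_mm: np.ndarray
    range_mm: float = 3.0

    def __post_init__(self):
        self.points_mm = np.atleast_2d(np.asarray(self.points_mm, dtype=float))
        if self.points_mm.size and self.points_mm.shape[1] != 3:
            raise ValueError("tag points must be (n, 3)")
        if self.range_mm <= 0:
            raise ValueError("range_mm must be > 0")

    def transformed(self, transform: RigidTransform) -> "LesionTagSet":
        return LesionTagSet(transform.apply(self.points_mm), self.range_mm)

    def __len__(self) -> int:
        return 0 if self.points_mm.size == 0 else len(self.points_mm)


@dataclass
class DscResult:
    dsc: float
    scar_mass: float
    lesion_mass: float
    overlap_mass: float
    weighting: str


@dataclass
class IcpResult:
    transform: RigidTransform
    mean_distance_mm: float
    n_iter: int
    converged: bool


def _principal_axes_candidates(src: np.ndarray, dst: np.ndarray) -> list[RigidTransform]:
    """Centroid + principal-axes initial alignments.

    The eigenvector sign ambiguity leaves four proper-rotation candidates;
    all are returned so ICP can be multi-started — near-symmetric shapes make
    the pre-registration nearest-neighbour cost an unreliable disambiguator.
    """
    mu_s, mu_d = src.mean(axis=0), dst.mean(axis=0)
    _, vs = np.linalg.eigh(np.cov((src - mu_s).T))
    _, vd = np.linalg.eigh(np.cov((dst - mu_d).T))
    out = []
    for signs in [(1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1)]:
        r = vd @ np.diag(signs) @ vs.T
        if np.linalg.det(r) < 0:
            r = vd @ np.diag([-s for s in signs]) @ vs.T
        out.append(RigidTransform(r, mu_d - r @ mu_s))
    return out


def _kabsch(src: np.ndarray, dst: np.ndarray) -> RigidTransform:
    """Least-squares rigid fit of paired point sets (SVD / Procrustes)."""
    mu_s, mu_d = src.mean(axis=0), dst.mean(axis=0)
    h = (src - mu_s).T @ (dst - mu_d)
    u, s, vt = np.linalg.svd(h)
    if s[1] <= 1e-12 * max(s[0], 1.0):
        raise ValueError("degenerate (rank-deficient) correspondence set")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return RigidTransform(r, mu_d - r @ mu_s)


def icp_rigid(
    source: SurfaceMesh,
    target: SurfaceMesh,
    max_iter: int = 80,
    tol_mm: float = 1e-5,
    init: RigidTransform | None = None,
) -> IcpResult:
    """Rigid point-to-point ICP on the vertex sets.

    Alternates nearest-neighbour correspondence against ``target`` vertices
    with an SVD-based least-squares rigid update.  Without an explicit
    ``init``, ICP is multi-started from all four centroid + principal-axes
    alignments and the refinement with the lowest final RMS correspondence
    distance wins — the pre-registration cost alone cannot disambiguate
    near-symmetric shapes, and RMS (the quantity the least-squares update
    actually minimises) punishes the localised gross errors of a wrong basin
    that a mean would dilute.  Operates on geometry only (never scar values).
    Each refinement stops when the RMS distance improves by less than
    ``tol_mm``.
    """
    src = source.vertices
    dst = target.vertices
    if len(src) < 3 or len(dst) < 3:
        raise ValueError("both meshes must have at least 3 vertices")
    tree = cKDTree(dst)

    def _rms(transform: RigidTransform) -> float:
        d, _ = tree.query(transform.apply(src))
        return float(np.sqrt((d**2).mean()))

    def _refine(start: RigidTransform):
        transform = start
        prev = np.inf
        best = (transform, _rms(transform))
        converged = False
        n_done = 0
        for n_done in range(1, max_iter + 1):
            moved = transform.apply(src)
            _, idx = tree.query(moved)
            transform = _kabsch(src, dst[idx])
            rms = _rms(transform)
            if rms < best[1]:
                best = (transform, rms)
            if prev - rms < tol_mm:
                converged = True
                break
            prev = rms
        return best[0], best[1], n_done, converged

    if init is not None:
        runs = [_refine(init)]
    else:
        runs = [_refine(c) for c in _principal_axes_candidates(src, dst)]
    scale = np.ptp(dst, axis=0).max()
    best_rms = min(r[1] for r in runs)
    # exact ties (perfectly symmetric shapes): prefer the least rotation
    tied = [r for r in runs if r[1] <= best_rms + 1e-9 * scale]
    transform, _, n_done, converged = min(tied, key=lambda r: r[0].rotation_angle_deg)
    if not converged:
        warnings.warn(
            f"ICP did not converge within {max_iter} iterations; "
            "returning best transform so far",
            stacklevel=2,
        )
    mean_dist = float(tree.query(transform.apply(src))[0].mean())
    return IcpResult(transform, mean_dist, n_done, converged)


def tag_faces(eam_mesh: SurfaceMesh, tags: LesionTagSet) -> np.ndarray:
    """Boolean per-face marking: centroid within ``range_mm`` of any tag point."""
    if len(tags) == 0:
        warnings.warn("empty lesion tag set: no faces tagged", stacklevel=2)
        return np.zeros(eam_mesh.n_faces, dtype=bool)
    tree = cKDTree(tags.points_mm)
    d, _ = tree.query(eam_mesh.face_centroids)
    return d <= tags.range_mm


def dsc(
    scar_on_eam: np.ndarray,
    lesions: np.ndarray,
    areas: np.ndarray | None = None,
    weighting: str = "count",
) -> DscResult:
    """Sørensen–Dice coefficient of two boolean face labelings.

    ``weighting='count'`` uses set cardinalities (the displayed-equation
    form); ``'area'`` masses faces by ``areas`` (mm²).  Both sets empty is
    defined as DSC = 1 with a warning.
    """
    scar = np.asarray(scar_on_eam, dtype=bool)
    lesion = np.asarray(lesions, dtype=bool)
    if scar.shape != lesion.shape:
        raise ValueError("labelings must have equal length (same mesh)")
    if weighting == "count":
        w = np.ones(scar.shape)
    elif weighting == "area":
        if areas is None:
            raise ValueError("area weighting requires per-face areas")
        w = np.asarray(areas, dtype=float)
        if w.shape != scar.shape:
            raise ValueError("areas must match labeling length")
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    scar_mass = float(w[scar].sum())
    lesion_mass = float(w[lesion].sum())
    overlap = float(w[scar & lesion].sum())
    if scar_mass == 0 and lesion_mass == 0:
        warnings.warn("both scar and lesion sets empty; DSC defined as 1", stacklevel=2)
        value = 1.0
    else:
        value = 2.0 * overlap / (scar_mass + lesion_mass)
    return DscResult(value, scar_mass, lesion_mass, overlap, weighting)


@dataclass
class CoLocationResult:
    dsc_result: DscResult
    transform: RigidTransform
    icp_mean_distance_mm: float
    n_unmatched_cmr_faces: int
    scar_on_eam: np.ndarray = field(repr=False)
    lesion_on_eam: np.ndarray = field(repr=False)


def coloc_pipeline(
    cmr_mesh: SurfaceMesh,
    scar_labeling,
    eam_mesh: SurfaceMesh,
    tags: LesionTagSet,
    correspondence_cutoff_mm: float = 5.0,
    weighting: str = "count",
    icp_kwargs: dict | None = None,
) -> CoLocationResult:
    """Register the imaging shell to the EAM shell and score co-location.

    ICP sees geometry only.  After fusion each imaging face maps to its
    nearest EAM face by centroid distance; matches beyond the cutoff are
    excluded (and counted), and an EAM face is scar if at least one scar
    imaging face maps onto it.  The result is scored against the tagged
    faces with :func:`dsc`.
    """
    scar = np.asarray(
        getattr(scar_labeling, "scar", scar_labeling), dtype=bool
    )
    if scar.shape != (cmr_mesh.n_faces,):
        raise ValueError("scar labeling does not match the imaging mesh")
    icp = icp_rigid(cmr_mesh, eam_mesh, **(icp_kwargs or {}))
    moved = icp.transform.apply(cmr_mesh.face_centroids)
    d, idx = eam_mesh.centroid_tree().query(moved)
    matched = d <= correspondence_cutoff_mm
    n_unmatched = int((~matched).sum())
    if n_unmatched > 0.2 * cmr_mesh.n_faces:
        raise ValueError(
            f"{n_unmatched}/{cmr_mesh.n_faces} imaging faces beyond the "
            f"{correspondence_cutoff_mm} mm correspondence cutoff: gross misregistration"
        )
    scar_on_eam = np.zeros(eam_mesh.n_faces, dtype=bool)
    np.logical_or.at(scar_on_eam, idx[matched], scar[matched])
    lesion_on_eam = tag_faces(eam_mesh, tags)
    result = dsc(scar_on_eam, lesion_on_eam, areas=eam_mesh.face_areas, weighting=weighting)
    return CoLocationResult(
        result, icp.transform, icp.mean_distance_mm, n_unmatched, scar_on_eam, lesion_on_eam
    )
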