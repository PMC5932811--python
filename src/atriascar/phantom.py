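"""Synthetic left-atrial phantom with contrast washout and known ground truth.

The phantom stands in for patient data: an ellipsoidal atrial shell (bright,
contrast-filled blood pool inside; dark lung background outside) with a wall
2–4 mm thick carrying scar patches along a wide-area circumferential ablation
(WACA) ring with configurable gaps.  Blood and scar intensities evolve under a
phenomenological two-compartment gadolinium washout model,

    blood(t) = blood_amp * exp(-blood_decay * t)
    scar(t)  = wall_base + scar_amp * exp(-scar_decay * t)
    wall(t)  = wall_base

with ``blood_decay > scar_decay`` so the scar-to-blood contrast grows with
time post injection — the regime late-enhancement imaging exploits.
Zero-mean Gaussian noise of known standard deviation is added per voxel, so
the noise magnitude is recoverable from a lung region of interest.

Two deliberate imperfections emulate mechanisms that shape real shell maps
(both default-on, both zeroable):

* wall thickness varies smoothly between 2 and 4 mm, so thin-walled regions
  suffer partial-volume blood contamination of the surface projection;
* the *analysis* shell is a radially perturbed copy of the true wall surface
  (a stand-in for manual segmentation error), so some faces sit closer to the
  blood pool than the anatomy they represent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree
import trimesh

from .coloc import LesionTagSet, RigidTransform
from .core import SurfaceMesh, VoxelVolume
from . import io as asio

__all__ = [
    "ContrastKinetics",
    "Lesion",
    "PhantomConfig",
    "PhantomTruth",
    "default_waca_pattern",
    "signal_at_time",
    "generate_phantom",
    "export_phantom",
    "load_phantom",
    "make_eam_twin",
    "LABEL_LUNG",
    "LABEL_BLOOD",
    "LABEL_WALL",
    "LABEL_SCAR",
]

LABEL_LUNG, LABEL_BLOOD, LABEL_WALL, LABEL_SCAR = 0, 1, 2, 3


@dataclass
class ContrastKinetics:
    """Washout-model parameters (intensity units and 1/min)."""

    blood_amp: float = 120.0
    blood_decay: float = 0.03
    scar_amp: float = 60.0
    scar_decay: float = 0.008
    wall_base: float = 40.0
    noise_sigma: float = 6.0

    def __post_init__(self):
        if min(self.blood_amp, self.scar_amp, self.wall_base) < 0:
            raise ValueError("amplitudes must be >= 0")
        if min(self.blood_decay, self.scar_decay) <= 0:
            raise ValueError("decay rates must be > 0")
        if self.blood_decay <= self.scar_decay:
            raise ValueError(
                "blood_decay must exceed scar_decay (contrast must grow with time)"
            )
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


def signal_at_time(kinetics: ContrastKinetics, compartment: str, t: float) -> float:
    """Noiseless mean intensity of a compartment ``t`` minutes post contrast."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    if compartment == "blood":
        out = kinetics.blood_amp * np.exp(-kinetics.blood_decay * t)
    elif compartment == "scar":
        out = kinetics.wall_base + kinetics.scar_amp * np.exp(-kinetics.scar_decay * t)
    elif compartment == "wall":
        out = kinetics.wall_base * np.ones_like(t)
    else:
        raise ValueError(f"unknown compartment {compartment!r}")
    return float(out) if out.ndim == 0 else out


@dataclass
class Lesion:
    """A circular ablation lesion footprint on the shell.

    ``theta_deg`` is the polar angle from +z, ``phi_deg`` the azimuth; the
    footprint is the cap of faces within ``radius_mm`` of the lesion centre
    (chord distance, which approximates the geodesic for small caps).
    """

    theta_deg: float
    phi_deg: float
    radius_mm: float = 5.0


def default_waca_pattern(
    n_lesions: int = 24,
    band_theta_deg: float = 65.0,
    radius_mm: float = 5.0,
    gap_arcs: tuple = ((100.0, 120.0), (280.0, 300.0)),
) -> list[Lesion]:
    """Circumferential lesion ring with gaps (a WACA-like pattern).

    Lesion centres are evenly spaced in azimuth on a fixed polar band;
    centres falling inside a gap arc are dropped, emulating incomplete or
    reconnected ablation lines.
    """
    lesions = []
    for i in range(n_lesions):
        phi = 360.0 * i / n_lesions
        if any(lo <= phi <= hi for lo, hi in gap_arcs):
            continue
        lesions.append(Lesion(band_theta_deg, phi, radius_mm))
    return lesions


@dataclass
class PhantomConfig:
    grid_shape: tuple = (64, 64, 64)
    spacing_mm: tuple = (1.25, 1.25, 1.25)
    origin_mm: tuple = (0.0, 0.0, 0.0)
    shell_center_mm: tuple = (40.0, 40.0, 40.0)
    shell_radii_mm: tuple = (24.5, 22.0, 19.0)
    appendage_amp_frac: float = 0.15
    appendage_dir: tuple = (-0.91, 0.33, 0.26)
    appendage_width_rad: float = 0.5
    pv_stub_amp_frac: float = 0.10
    wall_thickness_mm: float = 3.0
    wall_thickness_variation_mm: float = 1.0
    segmentation_error_mm: float = 1.5
    lesion_pattern: list = None
    gap_arcs: tuple = ((100.0, 120.0), (280.0, 300.0))
    kinetics: ContrastKinetics = field(default_factory=ContrastKinetics)
    lung_base: float = 15.0
    timepoints_min: tuple = (10.0, 20.0, 30.0)
    mesh_subdivisions: int = 3
    noise_model: str = "gaussian"  # "rician" available behind this flag
    seed: int = 0

    def __post_init__(self):
        if self.lesion_pattern is None:
            self.lesion_pattern = default_waca_pattern(gap_arcs=self.gap_arcs)
        if isinstance(self.kinetics, dict):
            self.kinetics = ContrastKinetics(**self.kinetics)
        self.lesion_pattern = [
            Lesion(**l) if isinstance(l, dict) else l for l in self.lesion_pattern
        ]
        half = self.wall_thickness_mm - self.wall_thickness_variation_mm
        if half <= 0.5:
            raise ValueError("wall thickness minus variation must exceed 0.5 mm")
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if self.appendage_amp_frac < 0 or self.pv_stub_amp_frac < 0:
            raise ValueError("shape-feature amplitudes must be >= 0")
        shape = np.asarray(self.grid_shape)
        spacing = np.asarray(self.spacing_mm, dtype=float)
        center = np.asarray(self.shell_center_mm, dtype=float)
        # effective outer extent includes the shape features
        probe = trimesh.creation.icosphere(subdivisions=2, radius=1.0)
        dirs = np.asarray(probe.vertices, dtype=float)
        max_scale = float(_shape_scale(self, dirs).max())
        radii = np.asarray(self.shell_radii_mm, dtype=float) * max_scale
        origin = np.asarray(self.origin_mm, dtype=float)
        extent_hi = origin + (shape - 1) * spacing
        lo_margin = (center - radii) - origin
        hi_margin = extent_hi - (center + radii)
        if min(lo_margin.min(), hi_margin.min()) < 10.0:
            raise ValueError(
                "shell does not fit in the grid with a >= 10 mm margin "
                "(needed for the 3 mm outer projection ray and a lung region)"
            )

    def as_dict(self) -> dict:
        d = asdict(self)
        return d


@dataclass
class PhantomTruth:
    """Ground truth accompanying a generated phantom."""

    mesh: SurfaceMesh  # the analysis shell (with segmentation error, if any)
    true_mesh: SurfaceMesh  # the exact mid-wall surface (same topology)
    scar_faces_true: np.ndarray
    lesion_tags: LesionTagSet
    label_volume: np.ndarray  # per-voxel {lung, blood, wall, scar}
    true_paas_fraction: float
    config: PhantomConfig


# -- geometry helpers ----------------------------------------------------------------


def _unit_vector(theta_deg: float, phi_deg: float) -> np.ndarray:
    th, ph = np.radians(theta_deg), np.radians(phi_deg)
    return np.array([np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)])


# pulmonary-vein stub directions (polar, azimuth in degrees) and relative
# widths: deliberately irregular, like real PV anatomy, so no rotation or
# flip maps the feature set onto itself
_PV_STUBS = ((42.0, 25.0, 0.25), (38.0, 115.0, 0.22), (46.0, 200.0, 0.28), (40.0, 290.0, 0.24))


def _shape_scale(config: PhantomConfig, unit_dirs: np.ndarray) -> np.ndarray:
    """Direction-dependent radial scale: 1 plus smooth anatomical bulges.

    A pure ellipsoid is exactly symmetric under 180-degree flips about its
    principal axes, and its smooth closed surface leaves rotations weakly
    determined, which makes geometry-only shell registration ill-posed.  An
    appendage-like bulge plus four irregular pulmonary-vein stubs break the
    symmetry and pin rotation the way real atrial anatomy does.
    """
    u = np.atleast_2d(unit_dirs)
    s = np.ones(u.shape[0])
    if config.appendage_amp_frac > 0:
        d0 = np.asarray(config.appendage_dir, dtype=float)
        d0 = d0 / np.linalg.norm(d0)
        ang = np.arccos(np.clip(u @ d0, -1.0, 1.0))
        s = s + config.appendage_amp_frac * np.exp(
            -0.5 * (ang / config.appendage_width_rad) ** 2
        )
    if config.pv_stub_amp_frac > 0:
        for theta_deg, phi_deg, width in _PV_STUBS:
            d = _unit_vector(theta_deg, phi_deg)
            ang = np.arccos(np.clip(u @ d, -1.0, 1.0))
            s = s + config.pv_stub_amp_frac * np.exp(-0.5 * (ang / width) ** 2)
    return s


def _surface_point(config: PhantomConfig, theta_deg: float, phi_deg: float) -> np.ndarray:
    u = _unit_vector(theta_deg, phi_deg)
    s = _shape_scale(config, u[None, :])[0]
    return np.asarray(config.shell_center_mm) + np.asarray(
        config.shell_radii_mm
    ) * (u * s)


def _ellipsoid_mesh(config: PhantomConfig, param_rotation: np.ndarray | None = None) -> SurfaceMesh:
    ico = trimesh.creation.icosphere(subdivisions=config.mesh_subdivisions, radius=1.0)
    u = np.asarray(ico.vertices, dtype=float)
    if param_rotation is not None:
        u = u @ param_rotation.T
    s = _shape_scale(config, u)[:, None]
    v = np.asarray(config.shell_center_mm) + u * s * np.asarray(config.shell_radii_mm)
    return SurfaceMesh(v, np.asarray(ico.faces))


def _thickness_field(config: PhantomConfig, unit_dirs: np.ndarray) -> np.ndarray:
    """Smooth wall-thickness map on unit directions, in [nominal - var, nominal + var]."""
    theta = np.arccos(np.clip(unit_dirs[..., 2], -1.0, 1.0))
    phi = np.arctan2(unit_dirs[..., 1], unit_dirs[..., 0])
    return config.wall_thickness_mm + config.wall_thickness_variation_mm * np.sin(
        2.0 * theta
    ) * np.cos(3.0 * phi)


def _segmentation_field(rng: np.random.Generator, unit_dirs: np.ndarray, amp_mm: float) -> np.ndarray:
    """Smooth seeded radial perturbation with max |amplitude| = amp_mm."""
    if amp_mm == 0:
        return np.zeros(len(unit_dirs))
    dirs = rng.normal(size=(8, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    weights = rng.normal(size=8)
    phases = rng.uniform(0, 2 * np.pi, size=8)
    raw = np.zeros(len(unit_dirs))
    for d, w, ps in zip(dirs, weights, phases):
        raw += w * np.cos(2.5 * (unit_dirs @ d) + ps)
    return amp_mm * raw / np.abs(raw).max()


def _signed_distance(config: PhantomConfig, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """First-order signed distance to the shell surface and unit directions.

    Uses the gradient-normalised implicit ``F(p) = |(p - c)/r| - s(direction)``
    where ``s`` is the appendage shape scale; exact for a sphere without the
    bulge and first-order accurate otherwise, which is all the wall band
    (|d| <= 2 mm) requires.
    """
    c = np.asarray(config.shell_center_mm, dtype=float)
    r = np.asarray(config.shell_radii_mm, dtype=float)
    q = (points - c) / r
    f = np.linalg.norm(q, axis=-1)
    grad_norm = np.linalg.norm(q / r, axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        unit = np.where(
            f[..., None] > 1e-9, q / np.maximum(f, 1e-12)[..., None], [0.0, 0.0, 1.0]
        )
        s = _shape_scale(config, unit.reshape(-1, 3)).reshape(f.shape)
        sdf = np.where(
            f > 1e-9,
            (f - s) * f / np.where(grad_norm > 0, grad_norm, 1.0),
            -r.min(),
        )
    return sdf, unit


def _lesion_mask(config: PhantomConfig, points: np.ndarray) -> np.ndarray:
    """Boolean: point within the chord-distance cap of any lesion."""
    mask = np.zeros(len(points), dtype=bool)
    for lesion in config.lesion_pattern:
        center = _surface_point(config, lesion.theta_deg, lesion.phi_deg)
        mask |= np.linalg.norm(points - center, axis=1) <= lesion.radius_mm
    return mask


# -- generation ----------------------------------------------------------------------


def generate_phantom(config: PhantomConfig) -> tuple[list[VoxelVolume], PhantomTruth]:
    """Generate one volume per timepoint plus ground truth.

    Geometry, labels and truth are identical across timepoints; only the
    compartment intensities and the noise realisation change.  Reproducible
    bit-for-bit for a fixed ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    center = np.asarray(config.shell_center_mm, dtype=float)

    true_mesh = _ellipsoid_mesh(config)
    radial = true_mesh.vertices - center
    radial /= np.linalg.norm(radial, axis=1, keepdims=True)
    unit_param = (true_mesh.vertices - center) / np.asarray(config.shell_radii_mm)
    unit_param /= np.linalg.norm(unit_param, axis=1, keepdims=True)
    delta = _segmentation_field(rng, unit_param, config.segmentation_error_mm)
    analysis_mesh = SurfaceMesh(
        true_mesh.vertices + delta[:, None] * radial, true_mesh.faces.copy()
    )

    scar_faces_true = _lesion_mask(config, true_mesh.face_centroids)
    true_paas = float(
        true_mesh.face_areas[scar_faces_true].sum() / true_mesh.total_area
    )

    # voxel labels
    xs, ys, zs = np.meshgrid(
        *[
            np.asarray(config.origin_mm)[a]
            + np.arange(config.grid_shape[a]) * np.asarray(config.spacing_mm)[a]
            for a in range(3)
        ],
        indexing="ij",
    )
    pts = np.stack([xs, ys, zs], axis=-1).reshape(-1, 3)
    sdf, unit = _signed_distance(config, pts)
    half_t = 0.5 * _thickness_field(config, unit)
    labels = np.full(len(pts), LABEL_LUNG, dtype=np.uint8)
    labels[sdf < -half_t] = LABEL_BLOOD
    wall = np.abs(sdf) <= half_t
    labels[wall] = LABEL_WALL
    if scar_faces_true.any():
        # scar voxels inherit the face-level footprint through nearest-face
        # (territory) assignment, keeping voxel truth and face truth consistent
        tree = cKDTree(true_mesh.face_centroids)
        _, owner = tree.query(pts[wall])
        scar_wall = scar_faces_true[owner]
        idx = np.flatnonzero(wall)
        labels[idx[scar_wall]] = LABEL_SCAR
    label_volume = labels.reshape(config.grid_shape)

    tags = LesionTagSet(
        np.array(
            [
                _surface_point(config, l.theta_deg, l.phi_deg)
                for l in config.lesion_pattern
            ]
        )
        if config.lesion_pattern
        else np.empty((0, 3)),
        range_mm=3.0,
    )

    volumes = []
    k = config.kinetics
    for t in config.timepoints_min:
        means = np.array(
            [
                config.lung_base,
                signal_at_time(k, "blood", t),
                signal_at_time(k, "wall", t),
                signal_at_time(k, "scar", t),
            ]
        )
        clean = means[label_volume]
        if k.noise_sigma > 0:
            if config.noise_model == "rician":
                n1 = rng.normal(0.0, k.noise_sigma, size=clean.shape)
                n2 = rng.normal(0.0, k.noise_sigma, size=clean.shape)
                noisy = np.hypot(clean + n1, n2)
            else:
                noisy = clean + rng.normal(0.0, k.noise_sigma, size=clean.shape)
        else:
            noisy = clean
        volumes.append(
            VoxelVolume(
                noisy,
                spacing_mm=config.spacing_mm,
                origin_mm=config.origin_mm,
                time_post_gbca_min=float(t),
            )
        )

    truth = PhantomTruth(
        mesh=analysis_mesh,
        true_mesh=true_mesh,
        scar_faces_true=scar_faces_true,
        lesion_tags=tags,
        label_volume=label_volume,
        true_paas_fraction=true_paas,
        config=config,
    )
    return volumes, truth


def make_eam_twin(
    truth: PhantomTruth,
    rng: np.random.Generator,
    rotation_deg: float = 8.0,
    translation_mm: tuple = (5.0, -3.0, 2.0),
    vertex_jitter_mm: float = 0.3,
) -> tuple[SurfaceMesh, LesionTagSet, RigidTransform]:
    """An electroanatomic-map stand-in: the same anatomy, independently meshed,
    rigidly displaced and slightly jittered, with the lesion tags carried into
    its frame.  Returns (eam_mesh, tags_in_eam_frame, applied_transform)."""
    config = truth.config
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.radians(rotation_deg)
    kmat = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    rot = np.eye(3) + np.sin(angle) * kmat + (1 - np.cos(angle)) * kmat @ kmat
    transform = RigidTransform(rot, np.asarray(translation_mm, dtype=float))

    # re-tessellate: rotate the unit-sphere parameterisation before scaling
    pang = rng.uniform(0, 2 * np.pi)
    pax = np.array([0.0, 0.0, 1.0])
    pk = np.array([[0, -pax[2], pax[1]], [pax[2], 0, -pax[0]], [-pax[1], pax[0], 0]])
    prot = np.eye(3) + np.sin(pang) * pk + (1 - np.cos(pang)) * pk @ pk
    remeshed = _ellipsoid_mesh(config, param_rotation=prot)

    verts = transform.apply(remeshed.vertices)
    if vertex_jitter_mm > 0:
        verts = verts + rng.normal(0.0, vertex_jitter_mm, size=verts.shape)
    eam_mesh = SurfaceMesh(verts, remeshed.faces.copy())
    tags_eam = truth.lesion_tags.transformed(transform)
    return eam_mesh, tags_eam, transform


# -- export / import -----------------------------------------------------------------


def export_phantom(volumes: list[VoxelVolume], truth: PhantomTruth, directory) -> dict:
    """Write volumes (NIfTI), shells (PLY), tags (CSV) and a truth JSON sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for vol in volumes:
        p = directory / f"lge_t{int(vol.time_post_gbca_min):02d}min.nii.gz"
        asio.write_volume(vol, p)
        paths[f"volume_{int(vol.time_post_gbca_min)}"] = str(p)
    paths["mesh"] = str(asio.write_mesh_ply(truth.mesh, directory / "shell.ply"))
    paths["true_mesh"] = str(
        asio.write_mesh_ply(truth.true_mesh, directory / "true_shell.ply")
    )
    paths["tags"] = str(
        asio.write_tags_csv(truth.lesion_tags.points_mm, directory / "lesion_tags.csv")
    )
    labels = VoxelVolume(
        truth.label_volume.astype(float),
        spacing_mm=truth.config.spacing_mm,
        origin_mm=truth.config.origin_mm,
    )
    paths["labels"] = str(asio.write_volume(labels, directory / "labels.nii.gz"))
    sidecar = {
        "scar_faces_true": truth.scar_faces_true,
        "true_paas_fraction": truth.true_paas_fraction,
        "tag_range_mm": truth.lesion_tags.range_mm,
        "config": truth.config.as_dict(),
    }
    paths["truth"] = str(asio.write_json(sidecar, directory / "truth.json"))
    return paths


def load_phantom(directory) -> tuple[list[VoxelVolume], PhantomTruth]:
    directory = Path(directory)
    sidecar = asio.read_json(directory / "truth.json")
    config = PhantomConfig(**{
        k: v for k, v in sidecar["config"].items()
    })
    volumes = [
        asio.read_volume(directory / f"lge_t{int(t):02d}min.nii.gz")
        for t in config.timepoints_min
    ]
    labels = asio.read_volume(directory / "labels.nii.gz").intensities.astype(np.uint8)
    truth = PhantomTruth(
        mesh=asio.read_mesh(directory / "shell.ply"),
        true_mesh=asio.read_mesh(directory / "true_shell.ply"),
        scar_faces_true=np.asarray(sidecar["scar_faces_true"], dtype=bool),
        lesion_tags=LesionTagSet(
            asio.read_tags_csv(directory / "lesion_tags.csv"),
            range_mm=sidecar["tag_range_mm"],
        ),
        label_volume=labels,
        true_paas_fraction=float(sidecar["true_paas_fraction"]),
        config=config,
    )
    return volumes, truth
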