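"""Apparent SNR / CNR from protocol-defined regions of interest.

The "apparent" qualifier matters: with parallel imaging the noise field is
spatially heterogeneous, so the lung-SD estimator gives an apparent, not a
true, SNR.  The protocol places three circular ROIs in one transverse slice:
a 200 mm² disc in the blood pool, a 5 mm² disc in the most intense scar, and
a 200 mm² disc in the lung; then

    aSNR_scar  = SI_scar / SD_lung
    aSNR_blood = SI_blood / SD_lung
    aCNR       = aSNR_scar - aSNR_blood

where SI are ROI means and SD_lung is the sample standard deviation
(n-1 denominator) of the lung ROI.

ROI membership is voxel-centre-in-disc with no partial-voxel weighting,
matching clinical workstation behaviour.  In real use ROIs come from config;
:func:`auto_place_rois` automates placement on phantoms only, where the
ground-truth label volume is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import yaml
from scipy import ndimage

from .core import VoxelVolume
from .phantom import LABEL_BLOOD, LABEL_LUNG, LABEL_SCAR, PhantomTruth

__all__ = [
    "ROISpec",
    "ApparentMetrics",
    "roi_values",
    "apparent_metrics",
    "auto_place_rois",
    "load_roi_specs",
    "scar_roi_percentile",
]

DEFAULT_AREAS_MM2 = {"blood": 200.0, "scar": 5.0, "lung": 200.0}


@dataclass
class ROISpec:
    """A circular in-plane ROI: disc of given area around ``center_mm`` in the
    slice ``slice_index`` orthogonal to ``plane_axis``."""

    plane_axis: int
    slice_index: int
    center_mm: tuple
    area_mm2: float
    compartment: str

    def __post_init__(self):
        if self.plane_axis not in (0, 1, 2):
            raise ValueError("plane_axis must be 0, 1 or 2")
        if self.area_mm2 <= 0:
            raise ValueError("area_mm2 must be > 0")
        if self.compartment not in ("blood", "scar", "lung"):
            raise ValueError(f"unknown compartment {self.compartment!r}")

    @property
    def radius_mm(self) -> float:
        return float(np.sqrt(self.area_mm2 / np.pi))


@dataclass
class ApparentMetrics:
    si_blood: float
    si_scar: float
    sd_lung: float
    asnr_blood: float
    asnr_scar: float
    acnr: float


def _inplane_axes(plane_axis: int) -> tuple[int, int]:
    return tuple(a for a in range(3) if a != plane_axis)


def roi_values(volume: VoxelVolume, roi: ROISpec) -> np.ndarray:
    """Intensities of all voxels whose in-plane centre lies in the ROI disc."""
    if not 0 <= roi.slice_index < volume.shape[roi.plane_axis]:
        raise ValueError(f"slice {roi.slice_index} outside volume")
    a1, a2 = _inplane_axes(roi.plane_axis)
    centers = volume.voxel_centers_world()
    c1, c2 = np.asarray(roi.center_mm, dtype=float)
    lo1, hi1 = centers[a1][0], centers[a1][-1]
    lo2, hi2 = centers[a2][0], centers[a2][-1]
    r = roi.radius_mm
    if not (lo1 <= c1 <= hi1 and lo2 <= c2 <= hi2):
        raise ValueError("ROI centre lies outside the grid")
    if c1 - r < lo1 or c1 + r > hi1 or c2 - r < lo2 or c2 + r > hi2:
        raise ValueError("ROI disc does not fit inside the slice")
    g1, g2 = np.meshgrid(centers[a1], centers[a2], indexing="ij")
    in_disc = (g1 - c1) ** 2 + (g2 - c2) ** 2 <= r**2
    plane = np.take(volume.intensities, roi.slice_index, axis=roi.plane_axis)
    vals = plane[in_disc]
    if vals.size == 0:
        raise ValueError(
            f"ROI disc (r={r:.2f} mm) contains no voxel centres at this spacing"
        )
    return vals


def apparent_metrics(
    volume: VoxelVolume, blood: ROISpec, scar: ROISpec, lung: ROISpec
) -> ApparentMetrics:
    """aSNR/aCNR from the three protocol ROIs."""
    for roi, name in ((blood, "blood"), (scar, "scar"), (lung, "lung")):
        if roi.compartment != name:
            raise ValueError(f"{name} ROI has compartment {roi.compartment!r}")
    si_blood = float(roi_values(volume, blood).mean())
    si_scar = float(roi_values(volume, scar).mean())
    lung_vals = roi_values(volume, lung)
    sd_lung = float(lung_vals.std(ddof=1)) if lung_vals.size > 1 else 0.0
    if sd_lung <= 0:
        raise ValueError("degenerate noise estimate: lung ROI SD is zero")
    asnr_scar = si_scar / sd_lung
    asnr_blood = si_blood / sd_lung
    return ApparentMetrics(
        si_blood=si_blood,
        si_scar=si_scar,
        sd_lung=sd_lung,
        asnr_blood=asnr_blood,
        asnr_scar=asnr_scar,
        acnr=asnr_scar - asnr_blood,
    )


def auto_place_rois(
    volume: VoxelVolume, truth: PhantomTruth, plane_axis: int = 2
) -> tuple[ROISpec, ROISpec, ROISpec]:
    """Deterministic protocol-style ROI placement on a phantom.

    Blood: disc at the blood-pool centroid of the chosen slice.  Scar: the
    highest-mean 5 mm² disc among scar-labelled wall voxels in the slice
    (the protocol's "most intense region").  Lung: background, as deep into
    the lung as the slice allows.  The slice is the one with the most scar
    voxels.  Phantom use only — requires the truth labels.
    """
    labels = truth.label_volume
    scar_per_slice = (labels == LABEL_SCAR).sum(axis=tuple(_inplane_axes(plane_axis)))
    if scar_per_slice.sum() == 0:
        raise ValueError("scar-free phantom: no scar voxels to place an ROI on")
    slice_index = int(np.argmax(scar_per_slice))
    a1, a2 = _inplane_axes(plane_axis)
    centers = volume.voxel_centers_world()
    lab2d = np.take(labels, slice_index, axis=plane_axis)
    img2d = np.take(volume.intensities, slice_index, axis=plane_axis)
    g1, g2 = np.meshgrid(centers[a1], centers[a2], indexing="ij")

    def _spec(c1, c2, area, comp):
        return ROISpec(plane_axis, slice_index, (float(c1), float(c2)), area, comp)

    # blood: centroid of the blood label in-slice
    bm = lab2d == LABEL_BLOOD
    blood = _spec(g1[bm].mean(), g2[bm].mean(), DEFAULT_AREAS_MM2["blood"], "blood")

    # scar: highest-mean small disc centred on a scar voxel
    r_scar = np.sqrt(DEFAULT_AREAS_MM2["scar"] / np.pi)
    sm = lab2d == LABEL_SCAR
    best, best_mean = None, -np.inf
    for i, j in zip(*np.nonzero(sm)):
        d2 = (g1 - g1[i, j]) ** 2 + (g2 - g2[i, j]) ** 2
        m = img2d[d2 <= r_scar**2].mean()
        if m > best_mean:
            best, best_mean = (g1[i, j], g2[i, j]), m
    scar = _spec(best[0], best[1], DEFAULT_AREAS_MM2["scar"], "scar")

    # lung: deepest background point whose disc stays in-slice
    lung_mask = lab2d == LABEL_LUNG
    depth = ndimage.distance_transform_edt(
        lung_mask, sampling=(volume.spacing_mm[a1], volume.spacing_mm[a2])
    )
    r_lung = np.sqrt(DEFAULT_AREAS_MM2["lung"] / np.pi)
    margin1 = np.minimum(g1 - centers[a1][0], centers[a1][-1] - g1)
    margin2 = np.minimum(g2 - centers[a2][0], centers[a2][-1] - g2)
    ok = (depth >= r_lung) & (margin1 >= r_lung) & (margin2 >= r_lung)
    if not ok.any():
        raise ValueError("no lung region deep enough for a 200 mm^2 ROI")
    flat = np.where(ok, depth, -np.inf)
    i, j = np.unravel_index(np.argmax(flat), flat.shape)
    lung = _spec(g1[i, j], g2[i, j], DEFAULT_AREAS_MM2["lung"], "lung")
    return blood, scar, lung


def scar_roi_percentile(si_scar: float, shell_values: np.ndarray) -> float:
    """Percentile rank of the scar-ROI intensity among all shell face values.

    Reported as a diagnostic for how representative the single small scar ROI
    is of the brightest shell scar; no pass/fail threshold is imposed.
    """
    vals = np.asarray(shell_values, dtype=float)
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError("no valid shell values")
    return float(100.0 * (vals < si_scar).mean())


def load_roi_specs(source) -> dict[str, ROISpec]:
    """Load ROI specs from a YAML/JSON file path or a dict.

    Expected layout::

        blood: {plane_axis: 2, slice_index: 39, center_mm: [40.0, 40.0], area_mm2: 200}
        scar:  {...}
        lung:  {...}
    """
    if not isinstance(source, dict):
        with open(source) as fh:
            source = yaml.safe_load(fh)
    specs = {}
    for comp, spec in source.items():
        spec = dict(spec)
        spec.setdefault("area_mm2", DEFAULT_AREAS_MM2.get(comp))
        spec["center_mm"] = tuple(spec["center_mm"])
        specs[comp] = ROISpec(compartment=comp, **spec)
    return specs
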