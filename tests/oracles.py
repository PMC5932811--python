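"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths they validate: trilinear
interpolation is re-implemented by hand, searches are exhaustive loops, and
surface areas come from Monte-Carlo sampling.
"""

from __future__ import annotations

import math

import numpy as np


def trilinear(intensities: np.ndarray, x: float, y: float, z: float):
    """Hand-rolled trilinear interpolation at a continuous voxel coordinate.

    Returns None outside the grid.
    """
    shape = intensities.shape
    if not (0 <= x <= shape[0] - 1 and 0 <= y <= shape[1] - 1 and 0 <= z <= shape[2] - 1):
        return None
    i, j, k = int(math.floor(x)), int(math.floor(y)), int(math.floor(z))
    i, j, k = min(i, shape[0] - 2), min(j, shape[1] - 2), min(k, shape[2] - 2)
    fx, fy, fz = x - i, y - j, z - k
    out = 0.0
    for di in (0, 1):
        for dj in (0, 1):
            for dk in (0, 1):
                w = (
                    (fx if di else 1 - fx)
                    * (fy if dj else 1 - fy)
                    * (fz if dk else 1 - fz)
                )
                out += w * intensities[i + di, j + dj, k + dk]
    return out


def brute_mip(volume, mesh, outer_mm: float, inner_mm: float, step_mm: float) -> np.ndarray:
    """Loop-based normal-ray MIP at an arbitrary (typically much finer) step."""
    values = np.full(mesh.n_faces, np.nan)
    n_steps = int(round((inner_mm + outer_mm) / step_mm))
    offsets = [-inner_mm + step_mm * s for s in range(n_steps + 1)]
    if offsets[-1] < outer_mm - 1e-9:
        offsets.append(outer_mm)
    for f in range(mesh.n_faces):
        c = mesh.face_centroids[f]
        n = mesh.face_normals[f]
        best = None
        for off in offsets:
            p = c + off * n
            vox = (p - volume.origin_mm) / volume.spacing_mm
            v = trilinear(volume.intensities, *vox)
            if v is not None and (best is None or v > best):
                best = v
        if best is not None:
            values[f] = best
    return values


def exhaustive_match(values: np.ndarray, weights: np.ndarray, target: float):
    """Exhaustive sweep over all unique-face-value cutoffs (strict '>').

    Returns (cutoff, achieved) for the largest cutoff whose achieved fraction
    is still >= target, or None if no candidate reaches the target.
    """
    total = weights.sum()
    best = None
    for c in np.unique(values):
        achieved = weights[values > c].sum() / total
        if achieved >= target and (best is None or c > best[0]):
            best = (float(c), float(achieved))
    return best


def disc_scan(volume, roi) -> int:
    """Count in-slice voxel centres inside the ROI disc by exhaustive scan."""
    a1, a2 = [a for a in range(3) if a != roi.plane_axis]
    count = 0
    r2 = roi.area_mm2 / math.pi
    for i in range(volume.shape[a1]):
        for j in range(volume.shape[a2]):
            c1 = volume.origin_mm[a1] + i * volume.spacing_mm[a1]
            c2 = volume.origin_mm[a2] + j * volume.spacing_mm[a2]
            if (c1 - roi.center_mm[0]) ** 2 + (c2 - roi.center_mm[1]) ** 2 <= r2:
                count += 1
    return count


def mc_surface_scar_fraction(config, rng: np.random.Generator, n: int = 200_000) -> float:
    """Monte-Carlo area fraction of the lesion footprint on the ellipsoid.

    Samples directions uniformly on the unit sphere and importance-weights by
    the sphere-to-ellipsoid area Jacobian r1 r2 r3 sqrt(sum u_i^2 / r_i^2).
    """
    from atriascar.phantom import _lesion_mask

    r = np.asarray(config.shell_radii_mm, dtype=float)
    c = np.asarray(config.shell_center_mm, dtype=float)
    u = rng.normal(size=(n, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    w = np.sqrt(((u / r) ** 2).sum(axis=1))
    pts = c + u * r
    inside = _lesion_mask(config, pts)
    return float((w * inside).sum() / w.sum())


def dsc_formula(scar: np.ndarray, lesion: np.ndarray, weights: np.ndarray) -> float:
    """Direct evaluation of 2|A∩B| / (|A| + |B|) with explicit loops."""
    a = b = inter = 0.0
    for s, l, w in zip(scar, lesion, weights):
        if s:
            a += w
        if l:
            b += w
        if s and l:
            inter += w
    if a + b == 0:
        return 1.0
    return 2.0 * inter / (a + b)
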