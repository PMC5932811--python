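"""Scar thresholding, %PAAS, and cross-timepoint threshold matching.

Two thresholding modes, both anchored on blood-pool statistics:

* z-score: scar where the shell value exceeds ``bp_mean + k * bp_sd``
  (fixed k = 3.3 in the standard analysis);
* image intensity ratio (IIR): scar where the value exceeds ``r * bp_mean``
  (r = 1.32 at 20 min in the standard analysis).

Scar burden (%PAAS) is the scar fraction of total shell surface area.
``match_threshold`` solves the inverse problem: the threshold at another
timepoint that reproduces a reference scar burden, searched exactly on the
empirical step function of unique face values.

Boundary handling is strict (``value > cutoff``), so the k -> inf and
all-faces limits behave predictably.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .shell_projection import ShellScalarMap

__all__ = [
    "ScarLabeling",
    "PaasResult",
    "MatchedThreshold",
    "threshold_zscore",
    "threshold_iir",
    "threshold_absolute",
    "paas",
    "match_threshold",
]


@dataclass
class ScarLabeling:
    mesh: object
    scar: np.ndarray
    mode: str
    threshold_value: float
    absolute_cutoff: float

    def __post_init__(self):
        self.scar = np.asarray(self.scar, dtype=bool)
        if self.scar.shape != (self.mesh.n_faces,):
            raise ValueError("labeling length must equal face count")


@dataclass
class PaasResult:
    paas_fraction: float
    scar_area_mm2: float
    total_area_mm2: float
    excluded_faces: int


@dataclass
class MatchedThreshold:
    mode: str
    threshold_value: float
    absolute_cutoff: float
    achieved_paas: float
    target_paas: float


def _label(shell_map: ShellScalarMap, cutoff: float, mode: str, value: float) -> ScarLabeling:
    with np.errstate(invalid="ignore"):
        scar = shell_map.values > cutoff  # NaN (missing) faces are never scar
    return ScarLabeling(shell_map.mesh, scar, mode, value, cutoff)


def threshold_zscore(shell_map: ShellScalarMap, bp_mean: float, bp_sd: float, k: float) -> ScarLabeling:
    """Scar where value > bp_mean + k * bp_sd."""
    if bp_sd <= 0:
        raise ValueError("bp_sd must be > 0")
    return _label(shell_map, bp_mean + k * bp_sd, "zscore", k)


def threshold_iir(shell_map: ShellScalarMap, bp_mean: float, r: float) -> ScarLabeling:
    """Scar where value > r * bp_mean (image intensity ratio threshold)."""
    if bp_mean <= 0:
        raise ValueError("bp_mean must be > 0")
    return _label(shell_map, r * bp_mean, "iir", r)


def threshold_absolute(shell_map: ShellScalarMap, cutoff: float) -> ScarLabeling:
    return _label(shell_map, cutoff, "absolute", cutoff)


def paas(labeling: ScarLabeling, shell_map: ShellScalarMap | None = None, weighting: str = "area") -> PaasResult:
    """Scar burden as the area fraction of the usable shell surface.

    Faces with a missing map value (when ``shell_map`` is given) are excluded
    from numerator and denominator alike; ``weighting='count'`` is available
    for sensitivity analysis.
    """
    valid = np.ones(labeling.mesh.n_faces, dtype=bool)
    if shell_map is not None:
        valid = shell_map.valid
    if weighting == "area":
        w = labeling.mesh.face_areas
    elif weighting == "count":
        w = np.ones(labeling.mesh.n_faces)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    total = float(w[valid].sum())
    if total <= 0:
        raise ValueError("zero usable shell area")
    scar_mass = float(w[valid & labeling.scar].sum())
    return PaasResult(
        paas_fraction=scar_mass / total,
        scar_area_mm2=scar_mass,
        total_area_mm2=total,
        excluded_faces=int((~valid).sum()),
    )


def match_threshold(
    shell_map: ShellScalarMap,
    bp_mean: float,
    bp_sd: float,
    mode: str = "zscore",
    target_paas: float = 0.2,
    weighting: str = "area",
) -> MatchedThreshold:
    """Threshold at which this map reproduces a target scar burden.

    %PAAS is a non-increasing step function of the absolute cutoff, with
    steps exactly at the unique face values; the search is therefore exact.
    Returns the largest cutoff whose achieved %PAAS is still >= the target
    (the most stringent threshold not under-shooting the target); errors if
    even the most permissive candidate cutoff falls short.
    """
    if not (0.0 < target_paas < 1.0):
        raise ValueError("target_paas must be in (0, 1)")
    if mode == "zscore" and bp_sd <= 0:
        raise ValueError("bp_sd must be > 0 for zscore mode")
    if mode == "iir" and bp_mean <= 0:
        raise ValueError("bp_mean must be > 0 for iir mode")
    if mode not in ("zscore", "iir"):
        raise ValueError(f"unknown mode {mode!r}")

    valid = shell_map.valid
    values = shell_map.values[valid]
    if weighting == "area":
        w = shell_map.mesh.face_areas[valid]
    elif weighting == "count":
        w = np.ones(valid.sum())
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    total = w.sum()
    if total <= 0:
        raise ValueError("zero usable shell area")

    # achieved(c) for candidate cutoffs c = unique face values, strict '>'
    order = np.argsort(values)
    v_sorted = values[order]
    w_sorted = w[order]
    uniq, first_idx = np.unique(v_sorted, return_index=True)
    # mass strictly above each unique value
    suffix = np.concatenate([np.cumsum(w_sorted[::-1])[::-1], [0.0]])
    counts = np.diff(np.append(first_idx, len(v_sorted)))
    above = suffix[first_idx + counts]  # mass of values > uniq[j]
    achieved = above / total

    feasible = achieved >= target_paas
    if not feasible.any():
        raise ValueError(
            f"target %PAAS {target_paas:.4f} unattainable: even the most "
            f"permissive candidate cutoff achieves only {achieved.max():.4f}"
        )
    j = np.flatnonzero(feasible).max()  # largest cutoff still meeting the target
    cutoff = float(uniq[j])
    ach = float(achieved[j])
    value = (cutoff - bp_mean) / bp_sd if mode == "zscore" else cutoff / bp_mean
    return MatchedThreshold(mode, float(value), cutoff, ach, target_paas)
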