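# Methods

This note documents the models, numerical choices and limitations behind
`atriascar`. It covers the analysis chain (ROI metrics, shell projection,
thresholding, threshold matching, co-location) and the synthetic phantom that
provides its test bed.

## The analysis chain

### Apparent SNR and CNR

With parallel imaging the noise field is spatially heterogeneous, so no true
SNR is measurable from a single acquisition; the *apparent* metrics divide ROI
mean signal by the standard deviation of a lung ROI. Protocol ROI areas are
200 mm² (blood pool), 5 mm² (brightest scar) and 200 mm² (lung), all placed in
one transverse slice. Voxel membership in a circular ROI is decided by
voxel-centre-in-disc with no partial-voxel weighting — deterministic, and what
clinical workstations do. The lung SD uses the n−1 (sample) denominator; with
Gaussian noise this estimator is unbiased for the variance, which is why the
phantom's default noise model is Gaussian rather than Rician (a Rician option
exists behind a flag). No correction is applied for background-intensity
non-uniformity.

ROI placement on real data is manual and config-supplied. `auto_place_rois`
automates placement *on phantoms only* (it reads the truth labels): the blood
disc at the in-slice blood centroid, the scar disc at the highest-mean 5 mm²
disc among scar voxels (emulating "most intense region" placement — note this
maximisation makes the estimate deliberately selection-biased high, as in the
protocol it imitates), the lung disc as deep into the background as the slice
allows. A diagnostic (`scar_roi_percentile`) reports the percentile rank of
the scar-ROI intensity among all shell face values; no pass/fail threshold is
attached.

### Shell maximum-intensity projection

Per face, intensities are sampled along the outward unit normal from 1 mm
inside to 3 mm outside the surface (inclusive) and the maximum is kept.
Sampling uses trilinear interpolation (nearest-neighbour is available for
debugging) at a default step of 0.5 mm — at most half the smallest default
voxel dimension, so the coarse ray cannot skip a voxel-scale maximum; the
acceptance suite checks agreement with a 10×-finer brute-force sampler within
2% on ≥99% of faces. Projection is per-face at the centroid because %PAAS and
DSC are face-area computations. Faces whose entire ray leaves the volume are
marked missing (NaN), counted, and excluded from %PAAS numerator and
denominator and from DSC, consistently across timepoints. Mesh orientation is
validated against the vertex centroid and auto-corrected with a warning.

Blood-pool reference statistics for thresholding come from the voxels at
least 3 mm inside the shell (plane distance to the nearest face): erosion
keeps wall partial-volume out of the estimate while leaving ~10⁴–10⁵ voxels.
The ROI pathway remains the one used for aSNR/aCNR.

### Thresholding and %PAAS

Scar is `value > cutoff` with a strict inequality, so the k→∞ and r→0 limits
behave predictably and a face exactly at the cutoff is not scar. The z-score
mode uses `cutoff = μ_bp + k·σ_bp` (standard k = 3.3), the IIR mode
`cutoff = r·μ_bp` (standard r = 1.32 at 20 min; r = 0.97 is the conventional
native-fibrosis ratio and is expressible through the same operation). %PAAS
is area-weighted ("percentage of total surface area"); face-count weighting
is available for sensitivity analysis. The two modes are consistent by
construction: k and r = (μ + k·σ)/μ give identical labelings.

### Threshold matching

%PAAS is a non-increasing step function of the cutoff with steps exactly at
the unique face values, so the matching problem is solved exactly on that
grid: the returned threshold is the largest candidate cutoff whose achieved
burden still reaches the target (the most stringent threshold that does not
undershoot), with the achieved burden reported alongside. No continuous
interpolation, no tolerance. An exhaustive-sweep oracle in the tests checks
every case. Whether the original analyses searched continuously or manually
is unknowable from the outside; the step-function search is this package's
recorded definition.

### Registration and co-location

Registration is rigid point-to-point ICP on vertex sets: nearest-neighbour
correspondence alternating with an SVD (Kabsch) least-squares update, no
trimming, no scaling (the anatomy scale is shared). It receives geometry
only — never scar values — so the blinding contract holds by construction.
Initialisation is centroid + principal-axes matching; the eigenvector sign
ambiguity leaves four proper-rotation candidates and ICP is multi-started
from all of them, keeping the refinement with the lowest final RMS
correspondence distance. RMS, not the mean, is the selection metric: it is
the quantity the least-squares update minimises, and it punishes the
localised gross mismatches of a wrong basin that a mean dilutes. Exact ties
(perfectly symmetric shapes) break toward the least rotation. Convergence is
declared when the RMS improves by less than `tol_mm` (default 1e-5 mm);
non-convergence returns the best transform with a warning.

After fusion, each imaging face maps to its nearest EAM face by centroid
distance; matches beyond 5 mm are excluded and counted (more than 20%
unmatched raises a misregistration error), and an EAM face is scar if any
scar imaging face maps onto it. Lesion tags mark EAM faces whose centroid
lies within the tag range (default 3 mm, the VisiTag geometric range; the
mapping system's force/time/percentage filters are acquisition-side and out
of computational scope). DSC uses face counts by default, matching the
set-cardinality form of the definition; area weighting is available and
recorded. Both sets empty is defined as DSC = 1 with a warning. The
nearest-centroid label transfer is this package's recorded definition of the
face correspondence; the weighting convention of the original analysis is
likewise unstated, so both are provenance-logged.

### Paired comparisons

Only the Wilcoxon matched-pairs signed-rank comparison is implemented (it is
the test the headline timepoint contrasts need, and it is exactly testable);
ANOVA, Friedman, multiplicity corrections and reliability coefficients are
deliberately out of scope. The implementation delegates to
`scipy.stats.wilcoxon`: exact null distribution for ≤25 non-zero, untied
differences; normal approximation with tie correction otherwise; all-zero
differences return p = 1 by convention.

## The phantom

### Geometry

The shell is an ellipsoid (default semi-axes 24.5 × 22 × 19 mm) modulated by
a direction-dependent radial scale: one broad appendage-like bulge plus four
smaller, irregularly placed pulmonary-vein stubs. The bulges are not
decoration: a pure ellipsoid is exactly symmetric under 180° flips about its
principal axes and its smooth closed surface leaves rotations weakly
determined, which makes geometry-only shell registration ill-posed — roughly
half of registrations land in a flipped basin. Real atrial anatomy breaks
this symmetry, and the phantom must too for the co-location stage to be
well-posed.

The mesh is a subdivided icosahedron (1280 faces by default) mapped onto
that surface. Wall thickness varies smoothly between 2 and 4 mm
(3 ± 1 mm), so thin-walled regions suffer partial-volume blood contamination
of the projection, a recognised feature of real acquisitions. The *analysis*
shell handed to the pipeline is the true mid-wall surface perturbed radially
by a smooth, seeded random field of ±1.5 mm amplitude — a stand-in for manual
endocardial segmentation error of about one voxel. Both the thickness
variation and the segmentation error default on and can be set to zero.

Voxelisation assigns each voxel centre a single label by a first-order
signed distance to the shell surface (gradient-normalised implicit; exact
for a sphere, first-order accurate with the bulges — ample for a ±2 mm wall
band): blood inside, wall within half a local thickness of the surface,
lung/background outside. Scar voxels inherit the face-level lesion footprint
through nearest-face (territory) assignment, which keeps voxel truth and
face truth consistent by construction. The lesion footprint itself is a set
of caps — faces whose centroid lies within a lesion radius (chord distance,
≈ geodesic for small caps) of a centre on the circumferential band — forming
a WACA-like ring (default 24 lesions of 5 mm radius on the 65° polar band)
with two 20° gaps emulating incomplete lines. Lesion tags are the cap
centres on the surface.

### Contrast kinetics

Intensities follow a phenomenological two-compartment washout acting
directly on steady image intensities (no inversion-recovery physics, no
pulse-sequence or k-space modelling — the analysis chain consumes
intensities only):

    blood(t) = 120·exp(−0.03·t)        wall(t) = 40
    scar(t)  = 40 + 60·exp(−0.008·t)   σ_noise = 6      (t in minutes)

No quantitative blood/scar washout constants are available to copy, so these
defaults are calibrated only to reproduce the qualitative timing behaviour
the method is known for, and they do: scar–blood contrast grows from ≈1σ at
10 min to ≈6σ at 30 min; aCNR rises across 10→20→30 min while blood aSNR
falls; the fixed 3.3 SD threshold captures more area at later timepoints;
the burden-matched threshold sits far below 3.3 SD at 10 min and above it at
30 min; and early acquisitions admit blood-pool- and noise-driven scar calls
at sites remote from ablation, depressing Dice co-location at 10 min.
The constraint `blood_decay > scar_decay` is enforced as a kinetics
invariant since it is what makes contrast grow with time.

One direction is *not* reproducible inside this model family: scar aSNR is
non-increasing in time (wall_base + amp·exp(−λt) can only decay), whereas
in patients it creeps upward. The package treats the aCNR direction, which
the model does reproduce, as the operative quantity.

### What the phantom does not emulate

No respiratory/cardiac gating artifacts, no field-strength or dose
modelling, no pulmonary-vein lumens (only outer stubs), no electrical
reconnection physiology, no spatial noise heterogeneity (the "apparent"
metrics exist precisely because real noise is heterogeneous — the phantom's
noise is homogeneous Gaussian by design, matching the estimator's
assumptions rather than the scanner's behaviour). Passing tests therefore
demonstrate correctness of the computational chain and the direction of
timing effects under the stated model, not clinical performance.

## Numerical choices and degenerate inputs

- Exact-recovery regime: at 0.45 mm spacing with a uniform 4 mm wall and no
  segmentation error, every interpolation cell a sample ray touches lies in
  a single compartment, so the noiseless shell map is exactly bimodal and
  any cutoff strictly between wall and scar intensities recovers the true
  scar faces exactly. At the default clinical-like spacing (1.25 mm) the
  same phantom exhibits partial-volume crosstalk — deliberately, as real
  data do.
- Problem sizes: the simulation studies use 40 subjects (acceptance script,
  analysis drivers) or 100 seeds (acceptance tests) on 64³ grids at 1.25 mm
  — large enough that every directional claim is decided at t-statistics
  of ≈5 or more, small enough to run interactively.
- Tie-breaks: threshold matching prefers the more stringent threshold; ICP
  restarts prefer the least rotation on exact ties; ROI placement resolves
  argmax ties by scan order. All deterministic.
- Degenerate inputs raise informative errors rather than returning values:
  zero lung SD, empty eroded interior, unattainable burden targets,
  rank-deficient ICP correspondence, meshes outside the volume, shells that
  do not fit the grid with a 10 mm margin (the outer projection ray plus a
  lung region need that margin).
- Reproducibility: all randomness flows from `numpy.random.default_rng`
  seeds carried in configs; a fixed seed reproduces volumes, meshes, truth
  and downstream tables bit-for-bit.

## Known limitations

- The washout model is phenomenological; absolute metric values (aCNR
  levels, DSC levels, matched-threshold magnitudes) are not calibrated to
  patient data — only their directions and orderings are meaningful.
- Point-to-point ICP on smooth shells leaves a few degrees of rotational
  slack even with the anatomical bulges; per-subject registrations are
  typically within 2–6° of truth, which is visible as DSC variance.
- The segmentation-error field perturbs the analysis shell but the EAM twin
  is derived from the true surface; systematic segmentation bias shared
  between modalities is not modelled.
- `%PAAS` excludes missing-value faces from both numerator and denominator;
  on meshes with many out-of-volume faces the burden refers to the imaged
  portion of the shell only.
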