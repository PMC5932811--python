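# atriascar

Quantification of post-ablation atrial scar (PAAS) on 3D late gadolinium
enhancement (LGE) cardiovascular MR, for researchers studying how acquisition
timing after contrast injection affects scar imaging and for anyone who needs
a tested, scriptable implementation of the standard atrial scar analysis
chain. Because no patient data ship with the package, a first-class synthetic
phantom module generates atrium-like volumes with known ground truth, so every
stage is verifiable end to end.

## What it computes

Given one LGE volume per timepoint (nominally 10, 20 and 30 min post
gadolinium), a triangulated left-atrial shell, and optionally an
electroanatomic-mapping (EAM) shell with ablation lesion tags:

- **Apparent SNR/CNR** from protocol ROIs (200 mm² blood-pool disc, 5 mm²
  scar disc, 200 mm² lung disc, all in one transverse slice):
  `aSNR_scar = SI_scar / SD_lung`, `aSNR_blood = SI_blood / SD_lung`,
  `aCNR = aSNR_scar − aSNR_blood`.
- **Shell maximum-intensity projection (MIP)**: each face of the shell takes
  the maximum trilinearly interpolated intensity along its outward normal,
  3 mm outside to 1 mm inside the surface.
- **Scar thresholding** of the shell map, either as a z-score against the
  blood pool (`value > μ_bp + k·σ_bp`, standard k = 3.3) or as an image
  intensity ratio (`value > r·μ_bp`, standard r = 1.32 at 20 min), and scar
  burden **%PAAS** as the scar fraction of total shell surface area.
- **Threshold matching across timepoints**: the exact threshold at 10 or
  30 min that reproduces the 20-min scar burden, searched on the empirical
  step function of face values (`%PAAS(T)` is piecewise constant, so the
  search is exact).
- **Scar/lesion co-location**: multi-start rigid ICP fusion of the imaging
  shell to the EAM shell (geometry only — blinded to scar), transfer of scar
  labels by nearest face, marking of EAM faces within 3 mm of a VisiTag-style
  lesion point, and the Sørensen–Dice coefficient
  `DSC = 2|Scar ∩ Lesion| / (|Scar| + |Lesion|)` over face sets.

The phantom emulates the study design: an asymmetric atrium-like shell
(ellipsoid plus appendage and pulmonary-vein bulges), a 2–4 mm wall carrying
scar along a wide-area circumferential ablation ring with gaps, two-compartment
gadolinium washout (blood decays faster than scar, so contrast grows with
time), Gaussian noise recoverable from a lung ROI, and a smooth
segmentation-error perturbation of the analysis shell.

## Worked example

```python
from atriascar import (PhantomConfig, generate_phantom, project_mip,
                       blood_pool_stats, threshold_zscore, paas, match_threshold)

volumes, truth = generate_phantom(PhantomConfig(seed=1))
vol20 = volumes[1]                                  # the 20-min acquisition
shell_map = project_mip(vol20, truth.mesh)          # 3 mm out / 1 mm in MIP
bp_mean, bp_sd = blood_pool_stats(vol20, truth.mesh)
label = threshold_zscore(shell_map, bp_mean, bp_sd, k=3.3)
burden = paas(label, shell_map)
print(f"%PAAS at 3.3 SD, 20 min: {100 * burden.paas_fraction:.1f}%")

vol10 = volumes[0]
map10 = project_mip(vol10, truth.mesh)
bp10 = blood_pool_stats(vol10, truth.mesh)
m = match_threshold(map10, *bp10, mode="zscore", target_paas=burden.paas_fraction)
print(f"matched threshold at 10 min: {m.threshold_value:.2f} SD "
      f"(achieved %PAAS {100 * m.achieved_paas:.1f}%)")
```

prints

```
%PAAS at 3.3 SD, 20 min: 16.6%
matched threshold at 10 min: 0.47 SD (achieved %PAAS 16.7%)
```

i.e. 16.6% of the shell surface is called scar at the standard 3.3 SD
threshold at 20 min, and reproducing that burden on the 10-min acquisition
requires descending to 0.47 SD above the blood-pool mean — early after
injection the scar intensity distribution still sits close to the bright
blood pool, so an equal-burden threshold is far less stringent (and scar
calls are correspondingly less specific).

The numbered drivers under `analysis/` run the full study shape: `01`
generates a reference phantom and the washout table, `02` runs the 40-subject
multi-timepoint study into `results/summary_long.csv`, `03` reports the
burden-matched thresholds and paired signed-rank comparisons, `04` the Dice
co-location per timepoint.

There is also a CLI: `atriascar phantom|run|metrics|coloc --help`.

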