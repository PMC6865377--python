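# mp2vbm

Voxel-based morphometry (VBM) with MP2RAGE multispectral MRI for focal-lesion
detection, as a tested, reusable Python pipeline — from image combination and
tissue segmentation through single-case statistics to lobar concordance
scoring and ROC-based operating-point selection — exercised end-to-end on a
seeded synthetic brain phantom with planted gray-matter lesions.

## Who this is for

Neuroimaging methods researchers who want a fully reproducible, simulation-
backed implementation of the single-case VBM workflow used to screen focal
epilepsy (and similar) cohorts for subtle structural lesions:

1. **MP2 reconstruction.** The MP2RAGE sequence acquires two inversion images
   INV1 and INV2; the uniform ("MP2") image is the voxelwise combination

       MP2 = INV1 · INV2 / (INV1² + INV2²)  ∈  [−0.5, 0.5],

   invariant to any shared multiplicative field — the receive-field bias
   cancels exactly ("self-bias-corrected").

2. **Multispectral segmentation.** GM/WM/CSF posterior maps from 1–3
   co-registered channels via a full-covariance Gaussian-mixture EM with
   optional per-voxel spatial priors (a fully specified stand-in for unified
   segmentation).

3. **Single-case statistics.** Each subject's smoothed GM map is compared to
   a control group with the two-group GLM t for group sizes 1 and *n*
   (the Crawford–Howell statistic):

       t = (x_subj − x̄_ctrl) / (s_ctrl · √(1 + 1/n)),   df = n − 1.

4. **Lobar scoring.** Supra-threshold clusters (26-connectivity) are kept if
   ≥ 1/3 of their voxels lie in the brain; a patient is *concordant*
   (*discordant*) if some cluster has ≥ 1/3 of its voxels in the union of
   hypothesis (non-hypothesis) lobes. Cohort summaries: concordant rate C_R,
   discordant rate D_R, specificity S_P (controls with no finding), and the
   Euclidean distance ED = √((100−C_R)² + (100−S_P)²) to the ideal (100, 100).

5. **Operating-point tuning.** C_R and 100−S_P over statistical cutoffs
   t = 2.5…6.0 (step 0.1) trace a ROC per smoothing level (4–16 mm FWHM,
   step 2 mm); the smoothing with the highest AUC is selected, and the
   working threshold is the discrete C_R/S_P intersection.

Because no clinical images ship with the package, a first-class synthetic
cohort generator (`mp2vbm.phantom`) produces controls and patients with known
lesion ground truth, an eight-lobe atlas, a dura/vessel confounder shell, a
shared INV1/INV2 bias field, and realistic noise — see `docs/methods.md`.

## Worked example

```python
from mp2vbm import PhantomConfig, RunConfig, run_pipeline

result = run_pipeline(RunConfig(phantom=PhantomConfig(seed=1)))
op = result.operating_point
print(f"fwhm={op.fwhm} mm  t-threshold={op.threshold}")
print(f"C_R={op.c_r}%  D_R={op.d_r}%  S_P={op.s_p}%  ED={op.euclidean_distance}")
```

prints, for the reference phantom (12 controls, 8 patients with 14 mm lesions
of amplitude 0.3, seed 1):

```
fwhm=10.0 mm  t-threshold=6.0
C_R=75.0%  D_R=25.0%  S_P=66.7%  ED=41.6
```

i.e. the tuner selects 10 mm smoothing at the top of the cutoff grid, where
6 of 8 planted lesions are recovered in their hypothesis lobe, 2 patients
show a finding elsewhere, and 8 of 12 lesion-free controls are clean. The
same run is available from the shell:

```bash
mp2vbm run --seed 1 --out out/   # writes performance.csv, roc_points.csv,
                                 # auc_summary.csv, operating_point.csv,
                                 # findings.csv, volumes.csv, manifest.txt
```

Other subcommands (`phantom`, `recon`, `segment`, `vbm`, `evaluate`, `tune`)
expose the individual stages on NIfTI/CSV files; the seven channel-set models
(T1, MP2, T1+FLAIR, MP2+INV1, MP2+INV2, MP2+FLAIR, INV1+INV2) are named
presets.

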