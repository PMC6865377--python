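# Methods

This note documents the models, the synthetic-data design, the numerical
choices, and the limitations of `mp2vbm`. Everything quantitative stated here
is computed by the test suite or by `scripts/acceptance.py`.

## Pipeline overview

A cohort of co-registered multispectral volumes (controls plus patients) is
processed as: MP2 reconstruction → tissue segmentation → Gaussian smoothing →
voxelwise single-case t-maps → cluster/lobe scoring → operating-point
selection. All stages operate on one common voxel grid; registration and
resampling are out of scope (the phantom generates data already in a common
space).

## MP2 reconstruction

`MP2 = INV1·INV2 / (INV1² + INV2²)`, computed voxelwise on real-valued
(signed) inputs, output in [−0.5, 0.5]. Where the denominator is at or below
`background_epsilon` (default 1e-12, air voxels) the output is 0. Because a
shared multiplicative field b enters numerator and denominator as b², it
cancels identically — the property `verify_bias_cancellation` measures (the
phantom's shared INV1/INV2 bias cancels to < 1e-9 under noise-free
conditions). No regularized ("robust") variant is implemented; the formula is
the plain product-over-sum-of-squares combination. Complex-valued k-space
combination and T1 mapping are out of scope.

## Segmentation

A full-covariance Gaussian mixture over voxel intensity vectors (1–3
channels), fit by EM:

* stopping rule: relative log-likelihood change < `tol` (1e-5) or `max_iter`
  (200); the log-likelihood trace is exposed and nondecreasing;
* covariance floors: `reg_covar` (1e-6) diagonal loading, escalated with a
  warning if a covariance turns singular;
* initialization: seeded k-means on a ≤ 50 000-voxel subsample without
  priors; with priors, prior-weighted moments (which keeps mixture component
  k aligned with prior column k throughout);
* spatial priors: optional per-voxel class priors multiply the likelihood in
  the E-step (posterior ∝ prior × weight × likelihood);
* class-to-tissue labeling: by assignment to prior columns when priors are
  given, else by ascending mean on the first channel (valid for T1-like,
  MP2, INV1, INV2 first channels; put such a channel first or pass priors
  when the first channel is FLAIR-like).

There is no bias-field estimation inside segmentation (the MP2 channel is
self-bias-corrected; residual bias on other channels is absorbed into class
covariances), no prior warping, and no MRF cleanup — deliberate fidelity gaps
relative to unified segmentation, chosen to keep the component fully
specified and testable.

The end-to-end pipeline uses a *normative* variant: one mixture is fit on a
subsample of control voxels (with the template priors below) and its fixed
parameters are applied to every subject. Two reasons: spatial priors are how
segmentation in a common space anchors class identity across subjects, and a
focal lesion occupying ~1 % of this small phantom brain measurably biases a
per-subject fit's class means, leaking lesion signal into remote boundary
posteriors. Judging pathology against a control-derived intensity model
avoids both. The per-subject EM (`fit_segmentation`) remains the public
segmentation operation.

Template priors (`population_priors`): the unjittered template anatomy's
CSF/GM/WM maps, smoothed at 6 mm, floored at 0.05 and renormalized;
dura-shell voxels receive an uninformative CSF/GM-leaning prior so that the
channel likelihood, not the prior, decides how the confounder is classified.

## Smoothing, volumes, statistics

* Gaussian smoothing: separable convolution, σ = FWHM/(2√(2 ln 2)) in voxel
  units, kernel truncated at 4σ and normalized to sum 1, replicate padding.
  Default FWHM grid 4–16 mm, step 2 mm.
* Absolute volumes: Σp × voxel volume / 1000 (mL); TIV = GM + WM + CSF,
  exact.
* Analysis mask: voxels where the mean smoothed control GM exceeds a
  threshold and the between-control variance is positive. The function
  default is 0.1; the pipeline uses 0.2, the conventional absolute GM
  threshold for VBM, which also keeps smoothing "shadow" voxels beyond the
  dura shell (non-informative, near-degenerate variance) out of the
  statistics.
* Single-case t: `(x − x̄)/(s·√(1 + 1/n))`, df = n − 1 — algebraically the
  two-group GLM t with group sizes 1 and n (verified against a brute-force
  least-squares fit to 1e-10). Patients are compared to all controls; each
  control to the remaining controls (leave-one-out). Zero-variance voxels
  are removed from the mask. Direction "decrease" negates the map; the
  pipeline default analyzes both directions and unions the clusters, since
  focal cortical dysplasia can present as either a GM increase or decrease.
* Paired group comparison: voxelwise paired t on differences, df = n − 1,
  with a Bonferroni family-wise threshold `t.isf(α/(2m), df)` over the m
  in-mask voxels (α = 0.05). Random-field-theory FWE is a documented
  fidelity gap; Bonferroni is conservative.

## Lobar scoring

Clusters are 26-connected components (configurable: 6/18/26) of
{t ≥ threshold} within the analysis mask, with no minimum extent. All
one-third rules are inclusive and evaluated on integer voxel counts:

* brain rule: keep clusters with ≥ 1/3 of voxels inside the brain mask;
* concordant: some surviving cluster has ≥ 1/3 of its voxels in the union of
  the patient's hypothesis lobes; discordant: same against the union of the
  remaining lobes; one cluster may set both flags; out-of-atlas voxels count
  toward neither;
* controls carry an empty hypothesis — every lobe is discordant for them —
  and S_P is the percentage of controls with no surviving finding.

Rates are reported at one decimal, ratios at two, rounding half away from
zero. Note a consequence of the brain rule: S_P is *not* guaranteed monotone
in the threshold — raising the cutoff shrinks a cluster and can move its
in-brain fraction upward across 1/3, creating a finding where none counted
before. This occurs rarely (single 0.1-steps at one smoothing in the
reference phantom) but it is a real property of the rules, not a bug.

## Operating-point selection

Per smoothing level, the (100−S_P, C_R) points across cutoffs are sorted by
false-positive rate (ties keep the highest C_R), anchored at (0, 0) — the
infinite-threshold limit, no findings at all — and integrated by the
trapezoid rule over the 100×100 square. No (100, 100) anchor is appended, so
a model that never reaches high concordance keeps an honestly small AUC. The
smoothing with the highest AUC wins (ties toward more smoothing, which is
the more conservative single-case choice); at that smoothing the working
threshold minimizes |C_R − S_P| (ties: higher C_R, then the lower cutoff).
Lesional sensitivity applies an inclusive peak-t ≥ threshold rule per case,
with the peak taken within hypothesis-concordant clusters (a global-peak
alternative is available).

## The phantom: what it emulates, and what it does not

Geometry: an ellipsoidal brain (semi-axes 0.44 × grid extent) on a
48×56×48 grid at 2 mm isotropic by default; one mid-sagittal and two
centroid planes partition it into eight "lobes" (left/right ×
frontal/parietal/temporal/occipital). The evaluation logic needs a labeled
partition, not anatomy. Radial layering: CSF ventricle (inner 42 % of the
radius, sub-voxel-sharp rim), WM mantle, and an outer GM shell (logistic
transition at 80 % of the radius), with ~0.1 of surface GM ceded to CSF as
subarachnoid partial volume. A one-voxel dura shell sits immediately outside
the brain mask.

Between-subject variability is designed so that the smoothed GM maps behave
like the approximately Gaussian random fields the voxelwise GLM assumes:

* per-voxel channel noise (sd 4 intensity units against tissue contrasts of
  25–50) is the dominant variance source — each posterior boundary is a
  fine-grained Bernoulli mosaic whose smoothed average is Gaussian by the
  central limit theorem;
* smooth, near-Gaussian low-frequency fields (sums of six random cosine
  components, unit RMS) add coherent "biological" variability at every soft
  interface: GM↔WM and CSF↔WM density exchanges (RMS 0.015), subarachnoid
  rim partial volume, per-subject dura signal variation (sd 1), and a
  sub-voxel boundary jitter (RMS 0.004 of the radius — residual common-space
  misalignment);
* the multiplicative bias field (range ±0.2, three cosine components scaled
  by peak) multiplies each channel, with a single shared realization for
  INV1 and INV2 — the premise the MP2 combination exploits.

Channel means place dura close to GM on T1/INV1/INV2 (and near the CSF/GM
likelihood boundary, so its classification is noise-driven rather than
deterministic) and far from GM on FLAIR — which is what makes T1-only
segmentation misclassify the shell as GM and a FLAIR channel resolve it, the
qualitative multispectral effect the segmentation tests assert.

Lesions are spherical, cosine-tapered GM-concentration changes (default
radius 14 mm, amplitude 0.3) planted at a GM/WM interface voxel with at
least one radius of clearance from other lobes; an increase draws
probability proportionally from WM and CSF, a decrease cedes it, so maps
stay valid. The 14 mm default models a lobar-scale malformation: sized so
its smoothed effect survives the 10–16 mm kernels at which the null field of
a 12-control cohort is quiet (with df = 11 and cutoffs capped at t = 6,
smaller foci are statistically undetectable at matched specificity on this
grid). The reference cohort is 12 controls + 8 patients (lesion signs
alternate increase/decrease, lobes cycle 1–8).

What passing tests on this phantom do **not** show about real data: no
cortical folding or anatomical shape variance, no registration error beyond
sub-voxel jitter, linear partial-volume mixing only, Gaussian (not Rician)
noise, a single confounder class, and a normative segmentation with exact
template priors — real cohorts violate all of these, and the clinical
specificity/concordance levels are accordingly far worse than the phantom's.

## Numerical details and edge cases

* Determinism: every stochastic step takes a seed; per-subject seeds derive
  from the cohort seed via a seed sequence (31-bit). Identical configs
  regenerate bit-identical volumes and reports.
* EM degeneracies: singular covariances are diagonally loaded (warning);
  voxels equidistant to all classes get posteriors equal to the mixing
  weights.
* t-map degeneracies: zero-variance voxels are masked, not infinite;
  subjects bit-identical to a control are rejected (leave-one-out
  contract).
* Rounding: half away from zero at table granularity (one decimal for
  rates/ED, two for ratios), applied at the reporting boundary only.
* NIfTI I/O: isotropic voxels enforced within 1 %; float data stored as
  float32, giving bit-identical round trips; cohort grid equality enforced
  with the offending file named.

## Known limitations

* Bonferroni FWE is conservative relative to random-field theory.
* DARTEL-style modulation is out of scope, so "volume" and "concentration"
  analyses coincide on the phantom's native-space maps.
* The segmentation stand-in has no within-segmentation bias correction;
  heavy bias on non-MP2 channels degrades it (absorbed into covariances).
* Multi-lobar hypotheses are supported throughout but the generator defaults
  to singleton hypotheses.
* S_P monotonicity in the threshold can be violated by the brain rule (see
  above); the effect is a rare single-step artifact of the published scoring
  rules.
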