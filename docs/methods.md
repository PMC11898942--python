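# Methods

This note records the models, conventions and numerical choices behind
`mmdiscover`, in the order the pipeline runs them.

## Problem setting

The pipeline discriminates clinically significant prostate cancer
(Gleason ≥ 3+4; secondary contrast 3+3 vs ≥ 4+3, which drops 3+4 samples)
from indolent disease (3+3) using three sample-matched views: radiomic
features from bi-parametric MR lesion ROIs (T2W, ADC), plasma exosomal
miRNA expression, and clinical covariates.  Cohorts are small (tens of
samples), so the design favors low-dimensional models (≤ 3 features),
heavy resampling, and rank-based statistics.

## Synthetic cohorts

Real cohorts of this kind are not publicly deposited, so all testing and
calibration runs on a generator with known ground truth.

* **miRNA.** Features are simulated directly on the log2-expression scale
  (log-normal counts): per-feature baseline mean ~ N(5, 2²), unit noise
  SD.  Informative features receive a class-mean shift equal to
  `mirna_effect_size` (default 3.0, a standardized effect since the noise
  SD is 1).  Duplicate blocks are exact affine copies `a·base + b` with
  distinct |a| and alternating signs, so within-block pairwise R² = 1 and
  the maximum-variance representative is unique.  The default cohort is
  48 samples (21 indolent / 27 significant), 322 features, 11 duplicate
  triples — so redundancy reduction removes 22/322 = 6.8% of features.
* **Lesion volumes.** A constant base level (100) plus correlated noise:
  white noise Gaussian-smoothed with correlation length σ = 0.6 voxels
  for the indolent class and σ·(1 + texture_contrast) for the significant
  class, renormalized to a fixed amplitude (20) so the two classes share
  an intensity histogram and differ only in spatial correlation — the
  axis co-occurrence features measure.  The mask is an ellipsoidal blob
  (≥ 27 voxels, connected); the significant class is mildly larger
  (+5% radius per unit contrast).  `texture_contrast` = 0 makes classes
  indistinguishable; 1.5 is the default "strong" contrast.
* **Clinical.** age ~ N(72.7, 7.1); PSA log-normal (median 6 ng/mL,
  log-SD 0.6); PIRADS ordinal on 2–5 with class-dependent probabilities
  ([0.30, 0.40, 0.20, 0.10] indolent, [0.05, 0.20, 0.35, 0.40]
  significant).  Shapes loosely match published cohort summaries; they
  are not fitted.
* **Seeding.** One master seed; every generator draws from a
  `SeedSequence((seed, key…))` substream, so outputs are byte-identical
  under a fixed seed and independent across samples/stages.

What the generator does **not** emulate: MR physics and scanner
protocols, spatial anatomy, sequencing read-level noise, batch effects,
inter-feature correlation beyond the planted duplicate blocks, and
label noise.  Passing recovery/calibration tests therefore demonstrates
correctness of the machinery under the stated generative model, not
clinical performance on real cohorts.

## Radiomics

All features are computed on the lesion mask's bounding-box crop ("mask
frame"), which makes every feature except the weighted centre of mass
exactly translation invariant; the CoM is reported in the full-grid
frame as 0-based voxel index × spacing (mm).

* **Discretization.** Fixed bin number (default 32 levels): in-mask min
  maps to level 1, max to level n; a constant ROI maps to level 1
  (convention, not an error).  Fixed-bin-number makes discretized texture
  features invariant to affine intensity rescaling.
* **GLCM.** Distance-1 co-occurrences over the 13 unique 3D directions,
  symmetrized and normalized per direction; joint maximum,
  autocorrelation (Σ i·j·p(i,j)) and difference entropy (base-2 log) are
  averaged across directions (the `Avg_`/`avg` prefix in the registry).
  Directions with no in-mask pairs are dropped; a single-voxel mask is an
  error.
* **GLSZM.** Zones are 26-connected equal-level components; small-zone
  high-grey-level emphasis Σ s(i,j)·i²/j² / N_s and high-grey-level zone
  emphasis Σ s(i,j)·i² / N_s.
* **GLRLM.** Low grey-level run emphasis Σ r(i,j)/i² / Σ r(i,j) per
  direction, averaged over the 13 directions; out-of-mask voxels break
  runs.
* **Laws energies.** Separable 3D filters from the 5-tap kernels
  L5 = [1,4,6,4,1], E5 = [−1,−2,0,2,1], S5 = [−1,0,2,0,−1],
  W5 = [−1,2,0,−2,1], R5 = [1,−4,6,−4,1], applied along axes (0,1,2) of
  the crop with edge replication; energy = mean |response| over in-mask
  voxels.  All 125 kernel triplets are emitted.
* **Wavelets.** 2-level separable orthonormal Haar decomposition
  (periodization mode) of the crop; per sub-band, energy = mean squared
  coefficient over the mask-projected support (a coefficient is in the
  support if any voxel of its 2^level cube is in the mask).  Sub-bands
  are named `3D_Wavelet_P1_L{level}_C{k}` with `k` enumerating level-1
  detail octants first (C1–C7, octants ordered aad…ddd), then the
  deepest approximation (C8) and level-2 details (C9–C15).  The external
  spelling this mirrors is not publicly defined; the `P1` prefix is fixed
  and the (level, index) coordinate is this package's convention.
* **First-order.** COV = sample SD / mean of in-mask intensities (zero
  mean is an error); maximum-histogram-gradient grey level = discretized
  level maximizing the central-difference gradient of the level
  histogram; volume at intensity fraction 10 = fraction of ROI voxels
  with intensity ≥ min + 0.10·(max − min) (the intensity-fraction
  convention, not the 10th percentile).
* **Morphology.** Minimum-volume enclosing ellipsoid by Khachiyan's
  iteration (tolerance 1e-6 on the weight update) over the convex hull of
  the mask voxels' corner points in mm — corner points make even
  single-voxel or coplanar masks full-rank, so no separate degenerate
  branch is needed.  Density = voxel volume of the mask / MVEE volume;
  voxelization biases it below 1 (mask undercounts, corners inflate), and
  it approaches 1 from below as resolution grows.

Every texture/filter feature is checked in the test suite against an
independent brute-force oracle (explicit pair/zone/run enumeration,
direct triple-loop convolution, manual tensor-product filter bank) on
volumes ≤ 8³.

## Expression preprocessing

Raw miRNA counts are normalized per sample to log2(1 + CPM); the
transform is monotone within a sample and invariant to per-sample library
size.  Features nonzero in fewer than `min_nonzero_fraction` (default
0.2) of samples can be dropped; filtering is idempotent.  The synthetic
generator emits log2-scale values directly, so normalization applies when
real count tables enter the pipeline.

## Selection

* **R².** Squared Pearson correlation; a constant vector yields R² = 0
  with a warning (a constant feature carries no dependence and must not
  be flagged against others).
* **Grouping.** "Iteratively flag pairs with R² ≥ 0.99" is formalized as
  connected components of the R²-threshold graph, which removes any
  dependence on the order pairs are visited and makes the reduction
  idempotent.  One representative per component is kept: the member with
  the largest sample variance on the modeling scale (log2 for miRNA, raw
  for radiomics); ties break to the earliest column.  A feature with no
  flagged partner is always kept.
* **Screening.** Two-sided Wilcoxon rank-sum per feature: exact
  enumeration p-values for combined n ≤ 20 without ties, otherwise the
  normal approximation with tie and continuity correction
  (`scipy.stats.mannwhitneyu`).  Raw p ≤ α (default 0.05) defines
  significance, matching how such panels are usually reported; a
  Benjamini–Hochberg option exists but is off by default.

## Model search

* **Logistic fit.** Newton/IRLS on the penalized log-likelihood with an
  L2 penalty (default 1e-4) on standardized, non-intercept coefficients,
  so perfectly separable small-n training folds converge to a finite
  optimum.  The solver matches scikit-learn's `LogisticRegression`
  (C = 1/penalty) to ~1e-5 and is cross-checked against it in the tests;
  a vectorized variant fits all hold-out repeats of a subset in one
  batched Newton solve and is verified against the scalar path.
* **Splits.** Stratified 80/20: per class, round(0.2·n) test samples but
  at least 1 and at most n−1, so every training fold contains both
  classes and every test fold has at least one sample of each —
  degenerate folds cannot occur by construction.  Samples are ordered by
  id before splitting, making ensembles invariant to row order.
* **Threshold.** Chosen on each training fold to maximize Youden's J over
  midpoints of adjacent distinct scores (plus outer sentinels); the
  lowest maximizer is taken for determinism.  A fixed-0.5 rule is
  available via configuration.
* **Metrics.** Se/Sp/PPV/NPV from the test-fold confusion matrix at the
  chosen threshold (PPV/NPV are undefined on folds without
  positive/negative predictions and are averaged over folds where they
  exist); AUC in the Mann–Whitney form P(s⁺ > s⁻) + ½P(tie).  Ensembles
  report means over repeats, the AUC SD, and the 2.5–97.5 percentile
  interval of per-repeat AUCs — the bracketed interval convention for
  reporting repeat spread.
* **Ranking.** Youden J descending, then mean AUC, then lexicographic
  feature ids (fully deterministic).
* **Search scale.** Exhaustive enumeration is the reference; for large
  panels a two-stage mode scores each subset by one fixed stratified
  split and runs the full ensemble only for the top M (pipeline default
  M = 25).  The subset counts themselves are exact binomials.
* **Fusion.** Cross product of the top-k single-modality candidates on
  the matched cohort; feature ids are tagged `modality:feature`;
  mismatched sample-id sets across modalities are an error.
* **Clinical baseline.** The same ensemble machinery over all 1–3-subsets
  of {age, PSA, PIRADS}.

## Pipeline and reporting

A run directory contains every stage artifact (feature tables, reduced
tables, redundancy report, screen results, per-modality / clinical /
fused leaderboards), a manifest with the config hash and package version,
and a markdown + JSON report.  No timestamps are written, so identical
configs reproduce identical bytes.  Report percentages are rounded
half-even to one decimal.  Leaderboards carry both numeric columns and
the formatted `Sensitivity/Specificity`, `PPV/NPV`, `AUC [CI], SD`
presentation columns.

## Problem sizes used in tests and the acceptance script

Simulation-based checks run at sizes chosen for a single CPU: screen
calibration on 1000 null features at n = 48; null-ensemble calibration
over 100 cohorts × 200 repeats of a single feature; univariate recovery
over 100 cohorts of 30 features (4 informative, shift 3); fusion
calibration over 100 matched cohorts (7/6) with one planted marker per
modality; the volumetric texture-recovery check on one 18-sample cohort
of 16³ volumes.  Cohort shapes, effect sizes and the 200-repeat ensemble
are the package defaults throughout.

## Known limitations

* Radiomics covers the named feature families, not a full institutional
  306-feature panel; wavelet sub-band naming beyond (level, octant) is a
  package convention.
* The hold-out ensemble reuses the same split sequence across subsets
  (paired comparisons, lower ranking variance) rather than independent
  sequences per subset.
* Exhaustive 3-subset × 200-repeat searches over hundreds of features are
  computationally heavy by design; the two-stage mode trades completeness
  for time and can miss subsets that only shine under ensembling.
* Small matched cohorts (n ≈ 13) give very wide AUC intervals; ensemble
  means on such cohorts are optimistic relative to external validation,
  which is a property of the study design being modeled, not of the
  implementation.
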