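# Methods

This note documents the models, the numerical choices and the synthetic data
conditions behind `lesionparc`, and what the test battery does and does not
establish about real data.

## Imaging model

All analyses operate on `Volume` objects — one 3-D scalar field with a 4×4
voxel-to-mm affine — restricted to a binary brain mask. Abnormality maps are
continuous voxel-wise likelihoods in [0, 1]; the simplified
control-referenced construction scores each voxel as `2·Φ(|x−μ_c|/σ_c) − 1`
against the control mean and SD (SD floored at 1e-6 of the control intensity
range so homogeneous voxels cannot divide by zero). This stands in for richer
outlier-detection pipelines; it reproduces their two outputs (a 0–1
abnormality map and a binary lesion map) without their segmentation machinery.

Binary lesions are defined by the U-threshold rule: abnormality > 0.5, then
connected components (26-connectivity by default; 6 and 18 available) strictly
larger than 100 voxels. Smoothing takes an FWHM in mm and converts per axis to
voxel sigmas through the affine, with reflective boundaries so total mass is
preserved; whether to smooth before lesion definition is left to the caller —
smoothing is an explicit, ordered pipeline step, not an implicit default.
Cluster tables report sizes, peak and unweighted centre of mass in mm.

## Lesion PCA

The patients × in-mask-voxels matrix is column-centred (centring only; no
voxel scaling — a configuration switch exists) and decomposed by SVD via the
patients-direction Gram matrix, which is exact and keeps memory linear in the
voxel count. Retained voxel loadings are varimax-rotated with Kaiser row
normalisation, patient scores are the centred data projected on the rotated
loadings, components are reordered by post-rotation explained variance and
signed so each component's largest-|loading| voxel is positive. Rotating the
spatial loadings (rather than the patient-side factors) is a deliberate
choice: the spatial maps are the scientific object, and patient "component
scores" follow from them.

The rotation itself is Kaiser's classical pairwise algorithm: sweeps over all
column pairs, each rotated in-plane by the closed-form optimal angle
`φ = atan2(num, den)/4`, iterated until the largest angle in a sweep falls
below 1e-12 rad. Each sweep is O(voxels · k²), which keeps 14k-voxel × 20
rotations in seconds where general gradient-projection routines take tens of
minutes. The test suite cross-checks the achieved criterion against an
independent gradient-projection implementation on small matrices and against
an exhaustive 0.01°-step planar-angle search for k = 2.

### Model order

Order selection scores the sphericity of the trailing eigenvalues of the
patients-direction covariance spectrum with N = number of voxels as the
observation count: `L(k) = N(p−k)·log(arith/geom mean of trailing
eigenvalues)`, penalised as `MDL(k) = L(k) + ½·k(2p−k)·log N` and
`KIC(k) = 2L(k) + 3(k(2p−k)+1)`. Ties break toward the smaller order; a flat
spectrum returns k = 0 with a warning. On planted-rank Gaussian data these
criteria recover the true order essentially always at high SNR and select
k = 0 under a pure-noise null. On near-noiseless synthetic vascular cohorts
with watershed jitter the criteria saturate near the patient count — each
patient's idiosyncratic boundary displacement is genuine, non-spherical
structure — so the estimated order on such cohorts tracks the sample size, as
the subsampling stability analysis makes visible. Components are therefore
usually fitted at an explicit `k` on synthetic data.

Stability analysis re-estimates the order on `reps` patient subsamples (drawn
without replacement, re-centred per subsample) at each requested sample size
and reports the long table plus medians.

## Behaviour PCA

Component-based factor analysis: PCA of the tests × tests correlation matrix,
retention by eigenvalue > 1 (threshold configurable), varimax rotation with
Kaiser normalisation, and regression-method factor scores `Z R⁻¹ L` (ridge
1e-8 with a warning if R is singular). Missing scores are a hard error —
the procedure assumes complete batteries. Percentage conversion divides by a
declared maximum or, under the `group-max` sentinel, by the observed column
maximum (all-zero columns are rejected as degenerate). The loading summary
marks |loading| ≥ 0.5 in bold, the conventional presentation.

## Mapping procedures

**VBCM.** All behavioural factors enter one per-voxel multiple regression
(valid because rotated factor scores are near-orthogonal; the code warns above
|r| = 0.3). Per-factor t statistics become partial correlations via
`r = t/√(t²+df)`; voxels at two-sided p < 0.001 form clusters, and a cluster
survives if its size is extreme under the permutation null of maximum cluster
size (factor rows permuted jointly, 1000 permutations by default, cluster
p ≤ 0.01 using the (1+#{null ≥ obs})/(B+1) estimator). This permutation
correction targets the same cluster-level family-wise error as Monte-Carlo
(smoothness-based) cluster-extent correction but needs no smoothness
estimate; its false-positive rate is verified at the nominal level on
label-permuted data. Note one algebraic consequence of reporting *partial* r:
with exactly orthogonal factors the joint-model map equals
`r₀/√(1−r_other²)`, which differs from the zero-order map in the third
decimal at typical effect sizes.

**Component–factor correlations.** Pearson r for every component × factor
pair with Bonferroni control at 0.05 over the full family (e.g. per-test
α = 0.000625 for 20 × 4).

**Stepwise regression.** Classical forward-entry (p ≤ 0.05) / backward-removal
(p ≥ 0.10) on partial-F p-values, iterated to a fixed point with cycle
detection; entry stops when fewer than two residual degrees of freedom would
remain. The final model refits the selected set and reports standardized
betas, overall F with its df, and adjusted R². An empty model is a valid
outcome. Selected components are rendered into brain space as the
beta-weighted sum of their rotated loading maps, z-scored over the mask,
|z| > 3.29, clusters > 200 voxels (both configurable).

## Synthetic data: what it emulates

The generator reproduces the two statistical properties the analyses depend
on, not anatomy:

1. **Hierarchical territory covariance.** A random binary tree is grown by
   splitting random leaves; leaves own territories produced by farthest-point
   seeding and nearest-seed (Voronoi) assignment inside an ellipsoidal mask,
   with seeds ordered along the first spatial axis so siblings tend to be
   neighbours. Per patient an occlusion node is drawn with weights 1.0
   (leaves), 0.5 (internal), 0.25 (root): most simulated strokes hit one
   territory, a minority take out a subtree, occasionally everything — the
   source of between-territory damage correlation.
2. **Watershed variability.** Before assigning territories, each patient's
   voxel coordinates are displaced by a smooth random field (Gaussian-filtered
   white noise, correlation length 2 voxels) scaled to an RMS of
   `boundary_jitter_mm` (default 2 mm), so territory borders move between
   patients.

Damage intensity inside occluded territories is Beta(8, 2) per voxel (mean
0.8 — heavy but variable abnormality); background noise is additive N(0,
0.02) clipped into [0, 1]; optional smoothing is off by default because the
abnormality maps are already continuous. The default grid is 32×38×32 at
4-mm voxels (~14k in-mask voxels) and the default cohort has 70 patients —
sizes chosen so every experiment, including the displacement study, runs at
desk scale in minutes.

Behaviour generation ties each of four latent abilities to critical
territories (`ability = 1 − mean abnormality` over them) and mixes abilities
through a 21 × 4 loading matrix whose strong entries (≥ 0.5) follow the
published factor pattern of a chronic-aphasia battery, with uniform 0.2
cross-loadings, unique noise of SD 0.1, and scores clipped to 0–100. A second
generator (`simulate_battery`) draws the abilities i.i.d. Uniform(0, 1)
instead — needed when the study requires independent generating factors,
which lesion-driven abilities on a shared arterial tree are not. Deficit
labels for a region truth follow the two-parameter rule: damaged iff the
lesion covers ≥ 20 % of the region, then deficit with probability 0.9
(damaged) or 0 (intact). Voxel-level truths use the deterministic rule
deficit ⇔ damaged.

What passing on these cohorts does **not** show: robustness to registration
error, to graded/partial infarcts within a territory, to non-vascular
aetiologies, to missing behavioural data, or to realistic atrophy — none of
which the generator emulates.

## Spatial-error experiments

For every eligible ground truth (strictly more than 3 damaged patients),
deficit labels are simulated, Fisher's exact test (two-sided, unique 2×2
tables cached) is run over all in-mask voxels, Benjamini–Hochberg FDR is
applied at q = 0.01, and the displacement is the Euclidean distance from the
significant set's centre of mass to the reference point (the truth voxel, or
the region's centre of mass). Two readings of "centre of mass of the
significant cluster" are implemented; the experiment defaults to the largest
cluster, because with hierarchically co-occluded territories the pooled
variant is dominated by distant co-damaged clusters (the generic cluster
utilities keep the pooled default). Truths with no significant voxels are
reported as non-localized and excluded from means; region truths are redrawn
`n_repeats` times so region-level arms reach comparable truth counts. Welch
t-tests compare displacement distributions across lesion models.

Component ground-truth regions are a component's |z| > 3.29 suprathreshold
set after a volume-equivalent extent rule: the 500-voxel (4 cm³) criterion is
applied as `round(4000 mm³ / voxel volume)` voxels so it means the same thing
on any grid. On the default grid, components whose loadings spread over two
or more territories standardise to a maximum |z| below 3.29 and drop out of
the region list — a geometric consequence of z-scoring a plateau covering a
sizable mask fraction `f`, whose height is `√((1−f)/f)`.

Sparse CCA is a rank-1 penalized cross-covariance decomposition: with a
one-dimensional behaviour vector the voxel weights alternate between the
normalised thresholded cross-covariance and a sign update, hard-thresholding
to retain exactly `⌈sparseness · voxels⌉` entries (sparseness = nonzero
fraction; default 0.045, the convention of the neuroimaging sparse-CCA
literature). Cross-validated mode picks sparseness on a log-spaced grid in
[0.005, 0.9] by mean held-out correlation over 5 folds. The method-comparison
experiment scores five procedures (mass-univariate, sparse CCA fixed and CV,
PCA + stepwise regression, PCA + Bonferroni correlations rendered as the
union of significant components' thresholded maps) by Dice against the truth
region, including composite truths built as unions of two regions.

## Determinism and degenerate inputs

Every stochastic stage takes an explicit seed; the CLI derives per-stage
seeds from the global seed via a CRC-keyed `SeedSequence`, and re-running any
command with the same seed is byte-identical (verified down to the NIfTI
bytes). Degenerate cases are contracts, not crashes: empty regions,
single-class labels, constant test columns, all-equal eigenvalue spectra,
zero-SD loading columns and empty stepwise models each either raise a named
error or return an explicitly flagged result, as documented on the
functions.

## Known limitations

- The abnormality construction is a deliberate simplification (normal-CDF
  deviation from controls); it ignores spatial covariance among controls.
- MDL/KIC saturate on near-noiseless, jitter-rich synthetic cohorts (see
  above); they are trustworthy on data with a genuine noise floor.
- The permutation cluster correction assumes exchangeable patients under the
  null (no covariate structure); covariate adjustment is out of scope.
- Sparse CCA approximates the published tool's sparseness semantics with hard
  thresholding and no sign constraint; canonical correlations on binary
  labels are point-biserial.
- Out-of-sample projection of new patients onto a fitted component solution
  is not provided.
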