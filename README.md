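# lesionparc

Data-driven vascular parcellation of stroke lesions, and the lesion–symptom
mapping procedures that use it.

## The problem

Stroke damage is not spatially random: an occlusion in the arterial tree takes
out every territory supplied by the branches below it, so the damage status of
neighbouring voxels — and of whole distant regions sharing a feeding branch —
is strongly correlated. Mass-univariate lesion–symptom mapping, which treats
voxels as independent units, can therefore mislocalize brain–behaviour
relationships. `lesionparc` implements an alternative: decompose a cohort's
lesion maps with varimax-rotated principal component analysis (PCA), so the
resulting components form a parcellation of lesion covariance that tracks the
vascular territories, and relate behaviour to those components instead of to
individual voxels. A simulation framework quantifies how much spatial error
each lesion model (single voxel, anatomical atlas, PCA territories) induces.

The package is aimed at researchers in lesion–symptom mapping and clinical
neuroimaging methods who want to work with territory-level lesion models or to
benchmark mapping procedures against simulated ground truths.

## What it computes

Given per-patient abnormality maps `x_p` restricted to a brain mask (columns
centred to give `X`, patients × voxels):

- **Lesion PCA** — the top-`k` principal directions `V` of `X`, with `k`
  chosen by minimum-description-length (MDL) or Kullback information (KIC)
  eigenvalue-sphericity criteria; a varimax rotation `T` (Kaiser-normalised,
  maximising Σ_j var(v_j²)) applied to the voxel loadings; patient component
  scores `S = X V T`; and per-component z-maps (loadings standardised over the
  mask, thresholded at |z| > 3.29 with a cluster-extent rule).
- **Behaviour PCA** — components of the tests × tests correlation matrix with
  eigenvalue > 1, varimax-rotated, with regression-method factor scores
  `F = Z R⁻¹ L`.
- **Three mapping routes** — voxel-based correlational mapping (per-voxel
  regression of abnormality on all factors, partial-r maps, permutation
  max-cluster-size correction); Bonferroni-corrected component × factor
  Pearson correlations; and forward/backward stepwise regression of factors on
  component scores, back-projected as beta-weighted loading maps.
- **Spatial-error simulations** — ground truths planted at voxel, atlas-region
  or component level; deficit labels by a 20 % damage-fraction / 90 %
  deficit-probability rule; Fisher-exact mass-univariate mapping with
  Benjamini–Hochberg FDR; centre-of-mass displacement compared across lesion
  models by Welch t-tests; and Dice comparison of five inference methods
  (mass-univariate, sparse CCA at fixed and cross-validated sparseness,
  PCA + stepwise regression, PCA + correlations).

Because clinical lesion data cannot be redistributed, the package ships a
first-class synthetic generator: a random arterial tree whose leaves own
Voronoi territories inside a brain mask, patient cohorts produced by sampling
occlusion sites on that tree (with per-patient watershed jitter and background
noise), and a 21-test behavioural battery with a four-factor loading
structure. Everything downstream is testable end to end on these cohorts.

## Worked example

```python
import numpy as np
import lesionparc as lp
from lesionparc.synth import simulate_battery

seeds = [int(s) for s in np.random.SeedSequence(0).generate_state(6) % (2**31)]

# 1. synthetic cohort: 14-territory vascular atlas, 70 patients, 4-mm grid
mask = lp.default_brain_mask()
vol = mask.volume
tree, atlas = lp.make_vascular_atlas(vol.grid_shape, vol.affine, mask, 14, seed=seeds[0])
lesions = lp.simulate_patient_lesions(tree, atlas, lp.CohortSpec(n_patients=70, seed=seeds[1]))

# 2. varimax-rotated lesion PCA
matrix = lp.assemble_lesion_matrix(lesions, mask)
results = lp.LesionPCA(matrix).fit(14)

# 3. behavioural battery with independent latent abilities
W = lp.reference_battery_loadings()
scores, _ = simulate_battery(200, lp.BehaviourGenSpec(W, uniqueness_sd=0.1, seed=seeds[4]))
fact = lp.BehaviourFactorModel(lp.BehaviourMatrix(scores)).fit()

# 4. stepwise regression of a lesion-driven factor on component scores
crit = {f: [l] for f, l in zip(W.columns, (1, 5, 9, 13))}
beh = lp.simulate_behaviour(lesions, atlas, crit, lp.BehaviourGenSpec(W, seed=seeds[5]))
bfact = lp.BehaviourFactorModel(lp.BehaviourMatrix(beh)).fit()
m1 = lp.stepwise_regression(bfact.factor_scores, results.scores_frame(),
                            lp.MappingConfig(n_permutations=500, seed=seeds[4]))["factor_1"]

# 5. displacement error: every-voxel model vs PCA territories
binary = [v.with_data((np.asarray(v.data) > 0.5).astype(np.uint8), "binary") for v in lesions]
binm = lp.assemble_lesion_matrix(binary, mask, center=False)
comp_regs = lp.component_regions(results, 3.29, round(4000 / vol.voxel_volume_mm3))
rec_v, s_vox = lp.displacement_experiment(binm, "voxel", n_truths=120, seed=seeds[2])
rec_c, s_cmp = lp.displacement_experiment(binm, comp_regs, n_repeats=10, seed=seeds[3])
t, df, p = lp.welch_ttest(rec_v.loc[rec_v.localized, "displacement_mm"],
                          rec_c.loc[rec_c.localized, "displacement_mm"])
```

With the summary lines printed along the way, the run reports:

```
Lesion PCA: 14 varimax-rotated components, 70 patients x 13944 voxels
variance explained by the first three components: ['14.6%', '13.0%', '8.9%']
behaviour factors retained (eigenvalue > 1): 4
factor_1 ~ comp_08 + comp_04 + comp_02 + comp_09; F(4,65) = 405.79, adj R^2 = 0.959
voxel model:      23.11 mm (SD 10.22, n=120)
components model: 8.20 mm (SD 12.95, n=110)
Welch t = 9.63, p = 2.3e-18
```

Reading the numbers: the 14 rotated components each absorb a territory-sized
share of lesion variance; the battery decomposition retains exactly the four
generating ability dimensions; the stepwise model finds the components whose
territories drive the first factor; and planting ground truths at the
component level more than halves the mean centre-of-mass displacement relative
to single-voxel ground truths on the identical cohort — the territory model
localizes better because it respects how damage actually covaries. (When the
behavioural factors are driven by territories that co-occlude on the arterial
tree, fewer than four factors can survive the eigenvalue rule: collinear
abilities merge. That is a property of the vasculature, not a bug.)

A command-line interface covers the same pipeline
(`lesionparc simulate-cohort | decompose-lesions | decompose-behaviour |
map-symptoms | eval-displacement | eval-methods | report`); every command
logs its seed and re-runs bit-identically.

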