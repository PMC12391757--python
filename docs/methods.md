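# Methods

## Scope and model

`netlesion` implements a lesion-topography analysis pipeline for stroke
cohorts: given binary lesion masks in a shared template space, an outcome
(the modified Rankin Scale, mRS, at 3 months), and normative resources
(a parcellation in three frameworks — vascular territories, functional
networks, white-matter tract systems — a voxel×time normative functional
dataset, and a set of tract visitation maps), it

1. summarises each lesion per parcel by dual overlap percentages,
2. estimates indirect functional and structural disconnection,
3. compares Lasso predictions of outcome across atlas frameworks, and
4. locates voxel-wise correlates of outcome with TFCE permutation
   inference.

Because the clinical cohorts such analyses are run on are not publicly
deposited, the package ships a first-class synthetic-data module that
generates every input with planted, configurable effect structure, so
every downstream stage can be validated against a known ground truth.

## Overlap features and exclusion

For lesion L and parcel P: `lesion_pct = 100·|L∩P|/|L|` (the spatial
distribution of the lesion over parcels) and `parcel_pct = 100·|L∩P|/|P|`
(the volumetric load on the parcel). A parcel enters the design matrix
for a subject only if `lesion_pct ≥ 5` **or** `parcel_pct ≥ 5`
(boundary inclusive); sub-threshold cells are zeroed per subject —
exclusion never drops a column for the whole cohort, so one subject's
low overlap cannot silence another's signal. The design-matrix value is
`lesion_pct`; `parcel_pct` serves only in the exclusion rule (a config
switch exposes the alternative).

## Indirect disconnection

**Functional.** The within-lesion voxel×voxel Pearson correlation matrix
is computed from the normative time series; its first principal
component, oriented so its loadings sum ≥ 0 and rectified at zero, is
normalized into per-voxel seed weights ("reshaping" the lesion toward
its dominant functional compartment; degenerate cases — ≤ 2 voxels or a
rank-deficient matrix — fall back to uniform weights). The seed series
is the weighted mean of the lesion voxels' series and the map value at
every brain voxel is its correlation with that seed. Maps are stored as
r values; the analysis threshold keeps r ≥ 0.2 (negative correlations
are retained in the unthresholded map and removed by the threshold).

**Structural.** A tract is *hit* when the lesion covers a voxel whose
visitation probability is ≥ 0.5. The structural map assigns each voxel
the **maximum** visitation over hit tracts — max, not sum, because the
values are probabilities and the downstream threshold ("higher than
0.5", strict) assumes the [0, 1] scale. This max-over-hit-tracts
contract is this package's defined construction for the per-voxel
likelihood that a lesioned bundle passes through a voxel; normative
tractogram databases implement proprietary variants of the same idea.

## Outcome prediction

Each representation (vascular / functional / white-matter design matrix,
the clinical benchmark age + sex + admission NIHSS, and each atlas +
covariates combination) is fit with Lasso regression. The L1 penalty is
selected by leave-one-out cross-validation over 100 log-spaced values in
[1e-5, 1e5], maximizing negative mean squared error; ties break toward
the larger (sparser) penalty. Features are standardized **inside each
training fold only**; constant columns are dropped (zeroed) per fold.
The headline score is the out-of-sample R² of the held-out predictions
(1 − SS_res/SS_tot); the in-sample R² of the final full-data fit is also
emitted. `loo_sd` is the standard deviation over folds of the per-fold
squared error. `delta_vs_benchmark` of a combined model is its R² minus
the atlas-only R² — the accuracy gained by adding clinical covariates.
mRS is treated as a numeric 0–6 target; ordinal models are out of scope.
An out-of-sample R² can be negative (worse than predicting the mean);
that is the expected behaviour of an uninformative model and is asserted
by the permutation-null tests.

## Voxel-wise inference

Per voxel, the Pearson correlation r of the subject-level feature value
(binary lesion, thresholded functional or structural disconnection) with
mRS is converted to `t = r·sqrt((n−2)/(1−r²))`, capped at ±1e6 for
r = ±1. Voxels outside the brain mask, with zero variance, or with fewer
than 5 subjects carrying nonzero values are excluded from the analysis
mask (correlations over near-constant columns are noise).

TFCE: `TFCE(v) = Σ_h e_h(v)^E · h^H · dh` over the ladder
h = dh, 2dh, … ≤ max(t), with E = 0.5, H = 2, 26-connectivity and 100
integration steps by default (the field-standard parameterization);
e_h(v) is the voxel count of the connected component containing v in
{t ≥ h}. Negative contrasts are computed from sign-flipped statistics,
so a map and its negation swap contrast results exactly.

FWE correction uses the max-statistic permutation scheme: the outcome
vector is fully permuted across subjects (exchangeability under the null
of no association); each permutation's maximum TFCE over the analysis
mask forms the null distribution and
`fwe_p(v) = (1 + #{max ≥ TFCE_obs(v)}) / (n_perm + 1)` — the add-one
estimator, whose smallest attainable p is 1/(n_perm+1). Defaults:
n_perm = 500 per run (1000 is the conventional reporting scale; 500
keeps a full desk-scale run under a minute of permutation time while
leaving the 0.01 significance level attainable), alpha = 0.01.

The per-network report summarises each subject's thresholded
disconnection map by its mean over a network's voxels and correlates
that score with mRS (two-sided p from the t distribution, n−2 df);
constant score vectors are reported as r = 0 with a degeneracy flag.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *structure* of an anterior-circulation
mechanical-thrombectomy cohort at desk scale (default grid 24×28×24 at a
nominal 2 mm; template-scale 1–2 mm grids are numerically identical but
pointlessly slow for validation):

- **Brain mask**: an ellipsoid filling ~90% of the grid.
- **Vascular-like atlas**: 10 contiguous Voronoi territories grown from
  well-separated random seeds (convex cells inside a convex mask are
  connected).
- **Network atlas**: the mask is cut into 2n equal-volume slabs along
  the anterior–posterior axis; network k owns slabs s and s+n (phase
  randomized by seed). Every network is therefore a distributed system
  of exactly two disjoint contiguous patches separated by other
  networks' territory. An earlier Voronoi-patch-pair design was
  abandoned: with few parcels on a convex mask, two antipodal cells of
  the same network become adjacent through the interior, collapsing the
  distributed structure.
- **Tracts**: 8 Gaussian-profile corridors (σ = 1.2 voxels, support
  radius 2.5, rasterized core path at probability 1) joining the two
  patches of each network at laterally offset routes; the wm atlas
  labels corridor voxels by their maximum-visitation tract.
- **Connectome**: each in-mask voxel's series is
  `sqrt(c)·latent_network + sqrt(1−c)·noise` over 200 timepoints
  (c = 0.6), giving expected correlation c within a network — including
  across its disjoint patches — and 0 between networks.
- **Cohort** (n = 70): lesions are 6-connected random-growth blobs,
  confined to one hemisphere (left with probability 40/70), seeded in
  the anterior part of the mask, with volumes log-uniform in 40–250
  voxels. The latent outcome is
  `damage + 0.04·(age−73) + 0.3·sex + 0.12·(NIHSS−13.8) + N(0, 1)` with
  `damage = Σ_p w_p · frac(parcel p lesioned)` and default weights
  {network 1: 60, network 2: 44}; admission NIHSS is generated as
  `10 + 5·damage + N(0, 5)` (clipped to 0–42), because admission
  severity clinically reflects the same damage that drives outcome —
  without this coupling a covariate benchmark could not reach the
  predictive strength such models show on real cohorts. mRS is the
  latent discretized at fixed cut-points 0.5, 1.5, …, 5.5 into 0–6.

The default weights were calibrated once so that the planted effect
reproduces realistic effect sizes — network-atlas LOO R² ≈ 0.36,
vascular ≈ 0.05, covariate benchmark ≈ 0.6 — and then frozen; they are
study conditions, not tuning knobs.

Not emulated: haemodynamics, anatomically shaped vascular territories,
CT-vs-MRI delineation differences, spatial autocorrelation of fMRI
noise, distance-dependent connectivity, and lesion-induced signal
dropout in the normative data. Passing tests therefore demonstrate that
the *pipeline machinery* is correct and that planted effects of
realistic size are recovered — not that real cohorts will show the same
R² values.

## Numerical choices and degenerate inputs

- Voxel indexing is 0-based; grids are defined by their affine; world
  space is RAS mm. Nearest-neighbour resampling breaks ties toward the
  lower index. Binarization threshold for loading masks is > 0.5.
- Eigenvector sign ambiguity in the lesion reshape is resolved by
  requiring a non-negative loading sum; an all-zero rectified loading
  falls back to uniform weights.
- A constant outcome makes R² undefined; it is reported as 0 with a
  degeneracy flag rather than raising.
- Model ranking ties break stably by model id.
- The pipeline fans one global seed into per-stage sub-seeds by fixed
  offsets, so stages can be re-run in isolation reproducibly.

## Problem sizes used in validation

The test suite runs the oracle comparisons at 8³–12³ grids, the FWER
calibration on 200 null cohorts of 30 subjects at 16³ with 500
permutations and a 32-step TFCE ladder (a permutation test is exact at
any enhancement parameterization, so the coarser ladder does not affect
calibration), the prediction-ordering experiment on 20 full-size default
cohorts, and the end-to-end check on the default configuration. These
sizes were chosen as the smallest that still exercise every code path
with meaningful statistics.

## Known limitations

- The Lasso retains one of several correlated predictors arbitrarily;
  coefficient identities (as opposed to predictive R²) should not be
  over-interpreted.
- The permutation scheme does not adjust for nuisance covariates
  (no Freedman–Lane); a design-matrix hook is the natural extension.
- The wm-atlas design matrix in the synthetic world is a weak proxy for
  the planted network damage (corridors traverse many slabs), so its
  predictive R² is near zero there; this is a property of the toy
  geometry, not of the estimator.
- Structural disconnection thresholds are conventions; sensitivity to
  the 0.5 level is not explored automatically.
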