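# Methods

This note documents the models, conventions and numerical choices behind
`gliomics`, and what the synthetic cohort does and does not emulate.

## Preprocessing

**Gray-level normalization.** Scanners differ in intensity scale, so every
channel is mapped onto integer levels 0–255.  T2 uses its full range;
T1, FLAIR and gadolinium-enhanced T1 are first *winsorized* at the 99.9th
percentile — the top 0.1% of voxels are predominantly high-signal noise.
Winsorizing (capping) rather than deleting those voxels keeps the grid
intact for the downstream spatial operations.  The mapping is
`floor(255·(x − lo)/(hi − lo))` with the maximum sent to 255 and a constant
volume sent to all zeros; it is monotone and invariant to positive affine
rescaling of the input (up to one gray level at floating-point bin
boundaries).

**T2Edge.** 3D Prewitt filter: the gradient magnitude is the Euclidean norm
of the three axis responses (derivative kernel `[-1,0,1]` smoothed by
`[1,1,1]` in the two orthogonal axes), computed with `scipy.ndimage` and
re-normalized to 0–255 with the full-range rule.  The filter is applied in
3D, matching the 3D lesion tracing.

**Gdzscore.** The enhancement map is the voxel-wise difference d = Gd − T1
standardized against its distribution over *normal-appearing brain* (brain
mask minus lesion): z = (d − mean_ref)/sd_ref, with z ≡ 0 when sd_ref = 0.
The reference population is a declared convention of this package; the area
of enhancement feature (`Gdzscore_ara.of.Gd.`) is the *fraction* of VOI
voxels with z > 2 (threshold configurable), chosen over an absolute volume
so the feature is size-independent.

## Registration

A deliberately lightweight affine registration with the standard contract:
histogram mutual information (joint histogram, 32 bins at full resolution,
fewer on coarse grids to keep the histogram populated), a Gaussian-smoothed
subsampling pyramid (factors 4, 2, 1; levels below 12 voxels per axis are
skipped), and a derivative-free Powell search.  Parameters are translation
(voxels), rotation (degrees, composed Rx·Ry·Rz about the grid center), then
log-scales and shears for 9/12 DOF.  The start point is the identity plus a
tiny seeded jitter, making results deterministic per seed.  On smooth blob
phantoms, planted rigid transforms (≤5 voxels, ≤10°) are recovered to well
under 0.5 voxel / 1° (20/20 seeded trials in the test suite).  The
implementation is *not* a numerical replica of any external registration
tool; it exists so the pipeline's spatial contract is testable end to end.
Synthetic cohorts are generated directly in atlas space by default
(`misalign=True` plants a small rigid offset per case to exercise
registration).

Resampling uses trilinear interpolation for intensity volumes and nearest
neighbor for masks (binarity preserved).  The laterality flip mirrors
atlas-space masks about the voxel x-midline.

## The 109-feature inventory

Three blocks:

| block | features |
|---|---|
| first-order texture | 8 statistics × 5 channels (T1, T2, FLAIR, Gd, T2Edge): mean, population SD, skewness, excess kurtosis, median, p10, p90, Shannon entropy of the 256-level histogram (bits) |
| Gdzscore block | the same statistics *minus entropy* (the z-map is continuous, not 8-bit, so 256-level entropy is not meaningful) plus the enhancing-area fraction `Gdzscore_ara.of.Gd.` |
| shape | volume (voxel count × voxel volume) and sphericity π^{1/3}(6V)^{2/3}/A, with A the marching-cubes isosurface area |
| location | occupancy ratio over the 10-label structural parcellation (`MNI_str_loc.01..10`) and the 49-label cortical parcellation (`HrvdOxf_loc.01..49`); `loc.k` ↔ atlas value k−1, so `loc.01` is the label-0 white-matter compartment |

Total 40 + 8 + 2 + 59 = 109.  The composition of the Gdzscore block (7
first-order statistics + enhancement area) is this package's inventory
choice; the inventory list is explicit (`build_default_inventory`) and
configurable.

Zero-variance conventions, each with a warning: skewness/kurtosis = 0 for a
constant region; ANOVA p = 1 for a constant feature; correlation 0
(including the diagonal) for a constant column.

## Voxel-wise lesion statistics

At each voxel with at least one lesion occurrence, the 3×2 table
(subtype × lesion-positive/negative) is tested with the exact conditional
test, two-tailed by the probability-ordering rule: the p-value sums the
probabilities of all fixed-margin tables no more probable than the observed
one (exhaustive enumeration; agrees exactly with R's `fisher.test` and with
rational-arithmetic enumeration on all tables with total ≤ 12).  Voxels no
lesion touches receive no test.

Cluster correction: voxels with p < α (default 0.05) are grouped into
connected components (26-connectivity by default; the choice is exposed
because conventions differ), subtype labels are shuffled across cases
(group sizes preserved — the exchangeability unit is the case, not the
voxel), and the maximum suprathreshold cluster size is recorded per
permutation (default 500).  A cluster's corrected p is the add-one
Monte-Carlo estimate (1 + #{null ≥ size})/(n_perm + 1), and it is called
significant when corrected p ≤ α.  The add-one rule is used instead of a
plain 95th-percentile cutoff because the latter is slightly anticonservative
when the observed statistic is excluded from the null; measured null FWER is
≈0.065 (add-one) vs ≈0.080 (plain cutoff) at 100 permutations.  The null
statistic is max cluster *size* (not mass).  Permutations reuse the per-case
voxel-occurrence matrix and a memoized p-table over count triples, making
500 permutations on a 48³ grid a matter of seconds.

An `ignore_laterality` flag unions each mask with its left-right mirror
before analysis, for the variant of the mapping that disregards hemisphere.

## Predictive modeling

**Split.** Institution-balanced random split: each institution contributes
`round(nᵢ·fraction)` training cases via largest-remainder rounding,
constrained so the total equals `round(N·fraction)` exactly (169 cases at
the default fraction 111/169 always give 111/58).

**LASSO.** L1-penalized logistic (binomial) or multinomial-logit regression
along a glmnet-style λ path (30 knots, log-spaced from λ_max down to
0.01·λ_max, where λ_max is the smallest penalty that zeroes every
coefficient).  λ_min minimizes the 10-fold cross-validated deviance;
features with nonzero coefficients at λ_min are "selected".  The per-knot
fits use scikit-learn (liblinear for binomial, saga with warm starts for
multinomial; CV-path fits run at a relaxed tolerance of 1e-3, the final fit
at 1e-4).  Standardization (zero mean, unit variance) is always computed on
the training portion only — including inside each CV fold — to avoid
leakage.

**Refit and metrics.** An unpenalized fit on the selected features gives the
final model; classes are predicted by maximum posterior (0.5 threshold in
the binary case).  If LASSO selects nothing, the model falls back to
predicting the training-majority class.  Binary metrics: accuracy,
sensitivity, specificity, PPV, NPV (positive class = IDH-mutant); 3-class:
accuracy plus the confusion matrix.

**Atlas choice per task.** The IDH binary task uses the 10-label structural
occupancies (the only block that covers the deep white matter, where
IDH-wildtype tumors concentrate); the 3-class task uses the 49-label
cortical occupancies (finer cortical detail separates the two IDH-mutant
subtypes).  The two blocks are never used together — they are largely
redundant encodings of the same location.

**Repetition and comparison.** The chain is repeated over fresh splits
(default 5).  Location-on vs location-off arms are compared per metric
(mean ± SD) and with an exact McNemar test on the pooled validation
predictions — the comparison test is this package's choice, made because
paired per-case predictions are exactly what McNemar conditions on.

**Chance-level subtlety.** On a no-signal cohort the chain's mean validation
accuracy is slightly *below* 1/3 (≈0.29): the majority-class fallback
predicts the training-plurality class, which in a fixed re-split cohort is
systematically under-represented in the validation complement (sampling
without replacement anti-correlates train and validation class
frequencies).  This is a property of the design, not a bug; the acceptance
script reports the measured value.

## The synthetic cohort generator

The generator's defaults define the emulated study conditions: 169 cases
(the complete-imaging subset size), 11 institutions, subtype mix
(0.32, 0.33, 0.35) ≈ (IDH-mutant astro, IDH+TERT oligo, IDH-wildtype), a
48³ grid at 4 mm spacing, ellipsoidal lesions of radius 10–25 mm with axis
ratio ≤ 2, and contrast-enhancement probability (0.1, 0.1, 0.6) — the
enhancing core marks IDH-wildtype.  Channel offsets differ by subtype by
roughly one between-case SD (`case_effect_sd` = 12), so texture is
informative but imperfect: texture-only IDH accuracy lands near 0.75 and
location lifts it into the high 0.8s, the regime the real modeling problem
occupies.  Location preferences are qualitative choices (frontotemporal /
frontal-dominant / white-matter + parietal), not fitted frequencies, since
no quantitative per-lobe table is available.

Two deliberate departures from iid sampling, both in the service of testable
planted structure: subtype counts *and* per-subtype lesion-seed labels are
quota-allocated by largest remainder (then shuffled), so the planted
composition and location distribution are matched exactly up to rounding —
with iid multinomial draws, sampling noise alone (expected L1 ≈ 0.14 at
n = 200) would swamp the planted-location signal the tests verify.  Lesion
centers prefer voxels at least one lesion radius inside the seeded region
(distance-transform criterion), so a lesion's occupancy vector is dominated
by its seeded label.

The toy atlases are deterministic geometric parcellations of an ellipsoidal
brain: a 10-label scheme (white-matter core = label 0, nine angular sectors
with label 3 anterior/"frontal") and a 49-label scheme (8 axial bands × 6
sectors of the shell).  They reproduce the *coding conventions* of the real
parcellations (label 0 = white matter; label 3 = frontal; 49 entries
including 0) but none of their anatomy; real label maps can be supplied to
the pipeline via `atlas_paths`.

What the generator does **not** emulate: MR physics (bias fields, partial
volume, scanner-specific nonstationarity), infiltrative lesion geometry,
correlated multi-focal disease, institution-level intensity batch effects,
or any relation between lesion size and subtype.  Passing tests therefore
demonstrate that the *pipeline* recovers planted statistical structure at
realistic sizes and noise levels — not that the specific accuracy numbers
transfer to patient data.

## Problem sizes and determinism

Test and acceptance workloads are sized for a desk run: 32³ grids for
statistical simulations (200 null replications × 100 permutations for the
FWER check), 20 seeded trials for registration and selection recovery, and
50 re-splits for the chance-level computation on the default 48³ cohort.
One master seed hash-derives a sub-seed per pipeline stage, every random
draw flows from a `numpy` `default_rng` seeded that way, volumes are written
uncompressed, and report JSON is key-sorted — identical configurations
reproduce byte-identical outputs.

## Known limitations

* The MI registration is tested on smooth phantoms; it is not expected to
  match production tools voxel-for-voxel on real brains, and large initial
  misalignments (beyond ~10°/5 voxels at 32³) can escape its capture range.
* The exact test's p-table memoization assumes three groups; the mapping
  machinery is 3-subtype-specific by design.
* Sphericity on very small digital lesions (a few voxels) is biased by
  surface discretization; values can exceed 1.
* The 109-feature inventory is one concrete realization of the documented
  blocks; alternative inventories can be passed to `assemble_feature_table`
  but must keep names unique.
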