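# gliomics

Lesion-location-aware MRI radiomics for molecular subtyping of WHO grade
II/III (lower-grade) gliomas.

## The problem

Treatment of lower-grade gliomas hinges on three truncal genetic
alterations — *IDH1/2* mutation, *TERT* promoter mutation and 1p/19q
codeletion — which today require surgical tissue sampling.  Conventional MRI
carries two kinds of signal about these subtypes: lesion *texture*
(intensity distributions across T1, T2, FLAIR and gadolinium-enhanced T1)
and lesion *location* (oligodendrogliomas favor the frontal lobe, IDH-mutant
astrocytomas the frontotemporal cortex, IDH-wildtype tumors the deep white
matter and parietal lobe).  This package implements a complete, tested
pipeline that turns both kinds of signal into a predictive model:

1. **Normalization + derived channels** — each channel is mapped onto 256
   gray levels (T2 full-range; T1/FLAIR/Gd winsorized at the 99.9th
   percentile), then a 3D Prewitt edge map (`T2Edge`) and a voxel-wise
   z-scored enhancement map (`Gdzscore`, from the Gd−T1 difference
   standardized over normal-appearing brain) are added.
2. **Atlas mapping** — affine registration to atlas space by maximizing
   32-bin histogram mutual information (12 DOF, coarse-to-fine, Powell), and
   propagation of the T2-drawn lesion mask (VOI).
3. **109 radiomic features per case** — 8 first-order histogram statistics
   for five channels, 7 + enhancing-area-fraction for `Gdzscore`, lesion
   volume and sphericity, and the *occupancy ratio* of the VOI over every
   label of two brain parcellations (10-label structural, 49-label
   cortical): `loc.k` is the fraction of lesion voxels in atlas label k−1.
4. **Voxel-wise lesion mapping** — at every voxel touched by ≥1 lesion, a
   two-tailed exact test of the 3×2 table (subtype × lesion±), with
   family-wise error over voxels controlled by cluster-based permutation
   (subtype labels shuffled across cases; observed cluster sizes compared
   with the permutation null of the maximum cluster size).
5. **Prediction** — institution-balanced 111/58 split, L1-penalized
   logistic/multinomial fit along a λ path with λ_min chosen by 10-fold CV
   deviance, unpenalized refit on the selected features, and accuracy /
   sensitivity / specificity / PPV / NPV (plus the confusion matrix for the
   3-class task), repeated over fresh splits, with and without the location
   block.

Because no patient images are distributable, the package ships a seeded
synthetic cohort generator (`gliomics.simulate`) that reproduces the
*statistical structure* the analysis assumes — subtype-biased lesion
locations, subtype-dependent intensities, contrast enhancement concentrated
in IDH-wildtype tumors, 11 institutions — so every stage is testable end to
end.

## Worked example

```python
from gliomics import CohortSpec, simulate_cohort, repeat_and_compare
from gliomics.pipeline import cohort_feature_table

cases, _ = simulate_cohort(CohortSpec(seed=70))   # 169 cases, 11 institutions
table = cohort_feature_table(cases)               # 169 x 109 features
res = repeat_and_compare(table, task="idh_binary", n_rep=5, seed=71)
```

prints, via `examples/predict_subtypes.py`:

```
IDH validation accuracy location_off: 0.74 +/- 0.02
IDH validation accuracy location_on : 0.86 +/- 0.03
location-on wins 5/5 repetitions; McNemar p = 0.000
3-class validation accuracy (49-label occupancies): 0.64 +/- 0.06 (chance 0.33)
```

Dropping the ten structural-atlas occupancy features costs about a tenth of
a point of validation accuracy on the IDH task: the location of a
lower-grade glioma is itself diagnostic, beyond its texture.  The ANOVA
screen (`examples/extract_features.py`) tells the same story from the
feature side — the strongest subtype discriminators are white-matter
occupancy (`MNI_str_loc.01`, highest in IDH-wildtype), frontal occupancy
(`MNI_str_loc.04`) and the contrast-enhancement statistics.

Other entry points, one script per capability, live in `examples/`:
cohort simulation, channel preprocessing, phantom registration,
feature extraction/screening and permutation lesion mapping.  A thin CLI
(`gliomics simulate|preprocess|extract|map|fit|run-all`) drives the same
pipeline from YAML configs.

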