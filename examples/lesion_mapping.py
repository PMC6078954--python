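"""Voxel-wise lesion mapping with cluster-based permutation correction.

Tests, at every atlas voxel touched by a lesion, whether the three molecular
subtypes differ in lesion frequency (two-tailed exact 3x2 test), then
controls the family-wise error over voxels by shuffling subtype labels and
comparing observed cluster sizes with the permutation null.
"""

from gliomics import CohortSpec, cluster_permutation_correct, simulate_cohort

cases, _ = simulate_cohort(CohortSpec(n_cases=90, n_institutions=3,
                                      grid_shape=(32, 32, 32), seed=4))
result = cluster_permutation_correct(
    [c.voi for c in cases], [c.subtype for c in cases],
    n_permutations=200, alpha=0.05, connectivity=26, seed=0,
)

print(f"suprathreshold voxels (p < 0.05): {int(result.sig_mask.sum())}")
print(f"null 95th-percentile max cluster size: {result.size_threshold:.0f} voxels")
sig = result.clusters[result.clusters["significant"]]
print(f"clusters: {len(result.clusters)} observed, {len(sig)} survive correction")
for _, row in sig.iterrows():
    print(f"  cluster {int(row.cluster_id)}: {int(row['size'])} voxels, "
          f"corrected p = {row.corrected_p:.3f}")
# Surviving clusters are brain regions where lesion placement genuinely
# differs between subtypes (here: the planted frontal/temporal/white-matter
# preferences), not chance clustering of marginally significant voxels.
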