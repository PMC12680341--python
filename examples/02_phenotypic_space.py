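"""Compare the realized (wild accessions) and potential (F2) phenotypic
spaces with one-class-SVM hypervolumes.

The pipeline corrects spatial block effects estimated on the replicated
accessions, applies the measurement-scale transforms, averages accession
replicates, imputes the few missing values, and builds hypervolumes on
the leading PCA axes for each generation, resampled to equal size.
"""

import phenospace as ps

ds = ps.simulate_dataset(ps.default_config(seed=1))
correction = ps.estimate_block_effects(ds.phenotypes)
print("block deviations (flowering time, raw units):",
      [round(float(d), 3) for d in correction.deviations["flowering_time"]],
      "- planted (0, +0.6, -0.4)")

mat = ps.transform_and_aggregate(ps.apply_block_correction(ds.phenotypes, correction))
mat = ps.impute_missing_iterative_pca(mat)
space = ps.phenotypic_space(mat, reps=10, samples_per_point=200, seed=1)

print(f"PCA axes used: {space.dim} (sequential permutation test flags "
      f"{space.pca.n_significant}; traits are near-independent by design)")
print(f"accession hypervolume: {space.acc_volumes.mean:8.1f} +/- {space.acc_volumes.se:.1f} SD^{space.dim}")
print(f"F2 hypervolume:        {space.f2_volumes.mean:8.1f} +/- {space.f2_volumes.se:.1f} SD^{space.dim}")
print(f"volume ratio (F2 / accessions): {space.volume_ratio:.2f}")
print("-> recombination releases variance hidden by stabilizing selection,")
print("   so the potential space is larger than the realized one.")

hv_acc = ps.estimate_hypervolume(space.acc_scores, samples_per_point=200, seed=2)
hv_f2 = ps.estimate_hypervolume(space.f2_scores, samples_per_point=200, seed=3)
ov = ps.overlap_stats(hv_acc, hv_f2)
print(f"Jaccard overlap of the two spaces: {ov.jaccard:.2f} "
      f"(intersection {ov.intersection:.1f} / union {ov.union:.1f})")
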