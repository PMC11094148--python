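"""Simulate bulk methylation mixtures with known cell composition.

Builds the three matrices of the linear mixing model: S (cell-type
proportions per sample, Dirichlet on the simplex with the summed immune
fraction capped), P (pure cell-type methylomes, averages of reference
replicates) and M = P @ S (the synthetic bulk betas a deconvolution method
sees).
"""
import methdeconv as md

# a fully synthetic labeled reference: 10 cell types (epithelium,
# fibroblasts, 7 immune subtypes, tumor), 12 replicates each
reference = md.generate_synthetic_reference(seed=1)
print(f"reference: {reference.betas.shape[0]} probes x "
      f"{reference.betas.shape[1]} samples, "
      f"{len(reference.cell_types)} cell types")

# S: 20 compositions, immune cells capped at 25% of each sample
compositions = md.sample_compositions(
    20, list(md.DEFAULT_CELL_TYPES),
    immune_types=md.IMMUNE_SUBTYPES, immune_cap=0.25, seed=2,
)
immune_sum = compositions.values.loc[list(md.IMMUNE_SUBTYPES)].sum(axis=0)
print(f"S: {compositions.values.shape[0]} types x "
      f"{compositions.values.shape[1]} samples; "
      f"immune fraction range {immune_sum.min():.3f}-{immune_sum.max():.3f} "
      "(all below the 0.25 cap)")

# P: average 4 reference replicates per cell type
profiles = md.build_profile_matrix(
    reference, {t: 4 for t in md.DEFAULT_CELL_TYPES}, seed=3
)
print(f"P: {profiles.values.shape[0]} probes x "
      f"{profiles.values.shape[1]} cell types "
      f"(e.g. Epi averaged from {profiles.manifest['Epi']})")

# M = P @ S: exact convex combinations, so every beta stays in [0, 1]
mixtures = md.mix(profiles, compositions)
arr = mixtures.mixtures.values.to_numpy()
print(f"M: {arr.shape[0]} probes x {arr.shape[1]} bulk samples, "
      f"beta range [{arr.min():.3f}, {arr.max():.3f}]")
print("ground-truth composition is carried alongside M for benchmarking")
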