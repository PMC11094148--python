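"""Select marker CpGs and build deconvolution signature matrices.

Shows the two selection strategies: one-vs-all (each cell type against the
pooled rest, per-type effect-size thresholds — the tumor-aware four-type
panel) and pairwise (every type pair, capped per comparison — the
pre-selection style of one-step deconvolution tools).
"""
import methdeconv as md

reference = md.generate_synthetic_reference(seed=1)
# panel-member samples only (source sets A and C)
panel = reference.subset_samples(
    list(reference.labels.index[reference.source_set.isin(["A", "C"])])
)

# selection runs on min-max normalized betas: the per-type thresholds
# (IC 0.85, Fib 0.65, Epi 0.55, TC 0.8) are calibrated on that scale
normalized = md.LabeledReference(
    md.min_max_normalize(panel.betas), panel.labels, panel.source_set
)

# hierarchical pair: main signature (Epi/Fib/TC/IC) + immune subtypes
main_sig, immune_sig, main_sel, immune_sel = md.build_hierarchical_panel(panel)
for label, df in main_sel.per_comparison.items():
    print(f"one-vs-all {label:<14s}: {len(df):4d} CpGs")
print(f"main signature: {main_sig.values.shape[0]} CpGs x "
      f"{list(main_sig.cell_types)}")
print(f"immune signature: {immune_sig.values.shape[0]} CpGs x "
      f"{len(immune_sig.cell_types)} immune subtypes")

# pairwise selection, max 100 CpGs per direction per pair
pairwise = md.select_features_pairwise(
    normalized, max_per_pair=100, delta_median_min=0.2, fdr_max=0.01
)
sig = md.build_signature(panel, pairwise)
print(f"pairwise union: {len(pairwise.union)} CpGs over "
      f"{len(pairwise.per_comparison)} type pairs; "
      f"flat signature {sig.values.shape[0]} x {sig.values.shape[1]}")

md.write_signature(sig, "pairwise_signature.txt")
print("signature written to pairwise_signature.txt "
      "(tab-delimited, probe IDs in the first column)")
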