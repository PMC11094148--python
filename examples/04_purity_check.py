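"""Recognition of pure reference samples (the purity sanity check).

A trustworthy protocol should call a pure sample ~100% of its own cell
type — both for samples the panel was built from ("recognizing-self",
source sets A/C) and for independent samples ("recognizing-other", B/D).
"""
import methdeconv as md

# independent sets carry extra between-lab noise
reference = md.generate_synthetic_reference(
    seed=1, independent_extra_noise_sd=0.03
)
panel = reference.subset_samples(
    list(reference.labels.index[reference.source_set.isin(["A", "C"])])
)
main_sig, immune_sig, *_ = md.build_hierarchical_panel(panel)

report = md.purity_check(reference, main_sig, immune_sig, method="rpc")
print("mean estimated proportion of the true cell type:")
print(f"  recognizing-self  (sets A/C): "
      f"{100 * report.set_means['recognizing_self']:.1f}%")
print(f"  recognizing-other (sets B/D): "
      f"{100 * report.set_means['recognizing_other']:.1f}%")
worst = report.per_sample.nsmallest(3, "score")
print("three least-recognized pure samples:")
for _, row in worst.iterrows():
    print(f"  {row.sample_id} ({row.true_type}, set {row.source_set}): "
          f"{100 * row.score:.1f}%")
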