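"""Accuracy as a function of cell-type balance: the immune-cap sweep.

For each cap on the summed immune fraction, compositions are drawn,
mixed with three independently drawn profile matrices (20 x 3 = 60 bulk
samples per scenario) and deconvolved hierarchically.  Rare cell types
are hard to estimate: relative error (MedAPE) shrinks and rank
correlations for immune subtypes rise as the cap loosens, while the
abundant epithelial/fibroblast estimates stay near-perfect throughout.
"""
import methdeconv as md

reference = md.generate_synthetic_reference(
    cell_types=("Epi", "Fib") + md.IMMUNE_SUBTYPES, seed=5
)
summary, reports = md.run_scenario_sweep(
    reference,
    caps=(0.25, 0.50, 0.80),
    n_pool=300,     # compositions drawn per scenario (study scale: 10,000)
    n_select=20,    # compositions actually mixed, x3 profile matrices
    n_repeats=3,
    seed=42,
)
print(summary.round(3).to_string())
print()
medape = summary.loc["MedAPE"]
print(f"MedAPE falls from {medape.iloc[0]:.2f} (immune <= 25%) to "
      f"{medape.iloc[-1]:.2f} (immune <= 80%): balanced compositions are "
      "easier to deconvolve")
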