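# Methods

## Model

Bulk DNA-methylation deconvolution rests on a linear mixing assumption:
the beta value (methylated fraction, in [0, 1]) of a bulk sample at a CpG
is the proportion-weighted average of the beta values of the underlying
cell types. In matrix form `M = P · S`, with `P` (probes × cell types) the
pure methylomes and `S` (cell types × samples) the compositions, each
column of `S` on the probability simplex. The assumption is good for
methylation because a beta value is an event fraction over DNA copies, so
it tracks cell numbers linearly — unlike expression, no per-cell scaling
term intervenes. Reference-based deconvolution inverts this relation per
sample given a signature matrix of discriminating CpGs.

Cell types modelled: epithelium (Epi), fibroblasts (Fib), the tumor
component (TC) and seven immune subtypes (B, NK, CD4T, CD8T, Mono, Neutro,
Eosino), collectively the immune compartment (IC).

## Synthetic data generator

`generate_synthetic_reference` emulates a labeled reference panel of pure
cell-type methylomes:

* per cell type, a block of `n_informative_per_type` (default 50) marker
  CpGs with target beta 0.9 in that type and `0.9 − informative_delta`
  (default 0.8, i.e. 0.1) in every other type;
* a shared pan-immune block, hypermethylated in all immune subtypes, added
  automatically when ≥2 subtypes are present — real leukocytes share
  pan-immune marks, and the hierarchical main step needs IC-vs-rest
  markers;
* background probes drawn from a bimodal beta-like distribution confined
  to [0.12, 0.88], mimicking the two-mode shape of real methylomes while
  leaving each sample's extremes at planted markers (this matters for
  min–max normalization, below);
* i.i.d. Gaussian replicate jitter (default sd 0.02), clipped to [0, 1];
  replicates split into panel-member source sets (A; C for TC) and
  independent sets (B; D), the latter optionally carrying extra jitter to
  emulate between-laboratory variation.

Defaults — 10 cell types, 12 replicates/type, 50 markers/type, contrast
0.8, replicate noise 0.02 — define the study conditions used throughout
the tests and the acceptance script. What the generator does **not**
emulate: probe-chemistry artifacts (type I/II design), batch effects,
spatially correlated noise, copy-number distortion of tumor betas, and
marker overlap between cell types beyond the planted structure. Passing
tests therefore demonstrate correctness of the pipeline and its behaviour
under the linear model with replicate-level variation, not performance on
any particular real cohort.

Compositions are Dirichlet (default concentration α = 1, uniform on the
simplex; the per-type α is configurable). A cap on the summed immune
fraction is enforced by rejection sampling — whole vectors are redrawn
until the immune block sum is ≤ cap (budget `max_attempts` = 10,000 draws
per accepted vector) — because rejection preserves a well-defined
conditional-Dirichlet law, which rescaling would not. Mixtures are exact
convex combinations by default (`noise_sd = 0`); truncated Gaussian noise
is an extension toggle.

## Preprocessing and panel construction

Probe-level filters remove cross-reactive probes, SNP-affected probes and
(for reference panels) sex-chromosome probes; probes missing from the
annotation are retained with a warning under sex-chromosome filtering
(their location cannot be proven; a destructive default is avoided) and
are removed by blacklist filters only when explicitly listed. Platform
intersection keeps the CpGs shared between two matrices in lexicographic
order, making runs byte-reproducible. Min–max normalization is per sample
(column), mapping each sample's range onto [0, 1]; the per-sample choice
preserves the between-probe contrasts that signatures rely on.

Marker selection uses a moderated two-sample t-test: per-probe pooled
variances are shrunk toward a scaled inverse-chi-square prior fitted by
the standard moment method on log-variances (the limma squeezeVar /
fitFDist construction, including its small-variance offset and the cap of
the posterior degrees of freedom at the pooled residual df). q-values are
Benjamini–Hochberg within each comparison's full probe set. Two
strategies:

* **one-vs-all** (hierarchical panels): per type, keep probes with
  q < 0.01 and |difference of group **mean** betas| ≥ a per-type
  threshold — IC 0.85, Fib 0.65, Epi 0.55, TC 0.8. Selection runs on
  min–max-normalized betas: the thresholds are calibrated on that
  full-range scale (on raw synthetic betas the planted 0.8 contrast would
  sit below the 0.85 IC threshold; normalization stretches it to ≈0.89).
  Signature values themselves are aggregated from the un-normalized
  reference, the scale on which mixtures are deconvolved.
* **pairwise** (one-step panels): per unordered type pair, probes with
  q < 0.01 and |difference of group **median** betas| ≥ 0.2, ranked by
  (q ascending, |Δ| descending, probe ID) and truncated to `max_per_pair`
  separately in the hyper- and hypomethylated directions (default 100;
  1000 for the large pre-selection feeding the weighted-SVR protocol).

Mean-based deltas for one-vs-all and median-based deltas for pairwise
mirror the conventions of the respective tool families. The tie-break
order makes selection fully deterministic. Thresholding uses |Δ| by
default, with a signed mode available. Signatures aggregate each type's
reference replicates by median (robust to outlier replicates) or mean.
The immune-step signature can also be built from an externally supplied
fixed probe list rather than a fresh selection.

## Deconvolution algorithms

All methods regress a sample's betas on signature columns over shared
probes (≥80% of signature probes must be present, else a coverage error;
rank-deficiency raises a conditioning error), then clip negative
coefficients to zero and renormalize to sum 1. A fit whose coefficients
are all ≤0 returns uniform proportions with a per-sample `degenerate`
flag rather than NaN, keeping downstream metrics total.

* **RPC** (robust partial correlations): iteratively reweighted least
  squares with Huber weights, c = 1.345, max 100 iterations, no intercept
  by default. Scale is the normalized median absolute residual; when the
  fit is (near-)exact the iteration short-circuits to the least-squares
  solution, so noiseless mixtures are recovered to machine precision.
  An optional intercept (`fit_intercept=True`) absorbs constant offsets
  between mixture and signature scales; without it, a level shift in a
  sample perturbs estimates by a bounded, documented amount (tested).
* **ν-SVR**: linear-kernel NuSVR per sample on standardized data. Both
  the signature and the sample are standardized with *global* (scalar)
  location/scale, which commutes with convex combinations, so simplex
  weights survive the transform. Each ν in the grid (default
  {0.25, 0.5, 0.75}) is fitted and the reconstruction-RMSE minimizer kept.
  Solver settings C = 10, tol = 1e-3, max 20,000 iterations: C = 10
  removes the shrinkage bias visible at the sklearn default (noiseless
  recovery ≈2e-4 max error at these settings), and the iteration cap
  bounds run time on noisy fits where the optimizer converges slowly,
  at no measurable accuracy cost.
* **Weighted ν-SVR** (rare-cell-type protocol): (i) greedy pruning of
  signature probes — repeatedly drop the probe whose removal most reduces
  the signature's condition number, until the target is met, no removal
  improves it, or a floor of 50 probes remains (the pruned condition
  number is never worse than the original's); (ii) an initial ν-SVR fit;
  (iii) `refit_rounds` (default 2) weighted refits in which each probe's
  weight grows with its mean discriminative margin for the currently
  rarest third of estimated types. With zero refit rounds and an infinite
  condition target the method reduces exactly to plain ν-SVR (tested).
  These internals reconstruct a two-sentence published description of the
  collinearity-aware rare-cell-type approach; they are an approximation of
  that tool's intent, parameterized so each heuristic can be switched off,
  not a reimplementation claim.
* **Hierarchical (two-step)**: step 1 estimates the main compartments
  (TC/Epi/Fib plus aggregate IC); step 2 estimates immune-subtype
  fractions against an immune-only signature; each subtype's final
  proportion is its step-2 fraction × the sample's step-1 IC estimate, so
  subtypes sum exactly to IC and the full vector stays on the simplex.
  The step-2 regression sees the whole bulk profile, in which non-immune
  content forms a near-constant baseline across immune markers. Without
  an intercept this baseline biases relative subtype estimates toward
  uniform (bounded by the baseline-to-contrast ratio); with
  `immune_fit_intercept=True` the RPC immune step absorbs it — exact in
  the noiseless limit — but on signatures whose marker blocks partition
  the probes the immune columns sum to a constant, the intercept makes
  the design rank-deficient, and the minimum-norm solution shrinks small
  subtypes to zero under noise. The intercept is therefore off by
  default and recommended only for well-separated, low-noise panels.

## Evaluation

With `p_m` predicted and `p_a` actual proportions:
`RMSE = sqrt(mean((p_m − p_a)^2))` over all cells (overall accuracy,
dominated by abundant types); `MedAPE = median(|p_m − p_a| / p_a)`
(relative accuracy, sensitive to rare types; the median keeps single bad
cells from inflating the score, as the per-cell errors are not normally
distributed — Shapiro–Wilk p-values are recorded per cell type as
diagnostics, and rank-based Spearman correlation is used throughout for
the same reason). Cells with `p_a = 0` exactly are excluded from MedAPE
(the ratio is undefined; Dirichlet truth makes such cells measure-zero,
but purity inputs need the rule) and the exclusion count is reported.
Spearman for a constant vector is reported as missing, never coerced to 0,
and missing scores are excluded from comparison tallies.

The purity check deconvolves pure reference samples and scores the
estimated proportion of each sample's true type, averaged within
panel-member (A/C, "recognizing-self") and independent (B/D,
"recognizing-other") source sets.

The scenario sweep builds the panel once from the A/C samples, then per
immune-cap scenario and repeat: draws a pool of compositions conditioned
on the cap, selects `n_select` of them uniformly at random (how selected
compositions relate to the generated pool is a design choice; uniform
subsampling is used), builds three profile matrices from the held-out B/D
samples (4 replicates averaged per type, disjoint from the panel), mixes
each selected composition with all three (n_select × 3 bulk samples), and
scores hierarchical deconvolution against truth. Reported values are
means over repeats. The method-comparison table scores arbitrary
`(name, fitter)` configurations on one mixture set and tallies how often
each lands in the top three of a category, ties sharing membership.

## Problem sizes and seeds

Tests and the acceptance script run at desk scale: 1,000–3,000 probes,
composition pools of a few hundred, 60 mixtures per scenario, 3 repeats —
sizes chosen so the whole validation runs in minutes on one CPU while
leaving every qualitative contrast (exact recovery, marker recovery, the
cap trend, purity ordering) comfortably resolved. One master seed drives
every source of randomness; child seeds are split off a SeedSequence so
composition sampling, profile selection and noise are independently
reproducible, and identical seeds give byte-identical reports.

## Known limitations

* The linear-mixing model ignores copy-number alterations, which distort
  tumor beta values in real cancers.
* The weighted ν-SVR internals are a documented approximation (above).
* MedAPE is undefined on cells with zero true proportion; the exclusion
  rule makes purity-style inputs scoreable but means MedAPE compares only
  supported cells.
* The per-sample axis for min–max normalization is a documented choice;
  the alternative (per-probe) is not implemented.
* Synthetic validation bounds what can be claimed about real cohorts; see
  the generator section.
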