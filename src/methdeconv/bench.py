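"""Accuracy metrics, scenario sweeps and method comparison.

Metrics, with ``p_m`` the model-predicted and ``p_a`` the actual proportion:

* ``RMSE  = sqrt(mean((p_m - p_a)^2))`` over all (cell type, sample) cells —
  overall accuracy, dominated by abundant cell types.
* ``MedAPE = median(|p_m - p_a| / p_a)`` — relative error, sensitive to how
  well *rare* cell types are recovered; the median (rather than the mean)
  keeps a single badly-estimated cell from inflating the score, since the
  per-cell errors are not normally distributed.
* per-cell-type **Spearman** rank correlation across samples between
  predicted and actual proportions (rank-based because the errors fail
  Shapiro-Wilk normality checks, which are recorded as diagnostics).

The purity ("recognizing-self" / "recognizing-other") check deconvolves
pure reference samples and scores the estimated proportion of each sample's
true cell type, averaged within panel-member (A/C) and independent (B/D)
source sets.
"""
from __future__ import annotations

import logging
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import deconv as _deconv
from . import io as _io
from . import panel as _panel
from . import simulate as _simulate
from .containers import (
    AlignmentError,
    CompositionMatrix,
    EvaluationReport,
    IMMUNE_SUBTYPES,
    LabeledReference,
    MixtureSet,
    PurityReport,
    SignatureMatrix,
    UndefinedMetricError,
)

logger = logging.getLogger(__name__)

#: the immune-cap grid of the proportion-range scenario sweep: 25% to 80%
#: of total content in 5-point increments (12 scenarios)
DEFAULT_CAPS = tuple(np.round(np.arange(0.25, 0.801, 0.05), 2))


def _aligned(predicted: CompositionMatrix, actual: CompositionMatrix):
    if list(predicted.cell_types) != list(actual.cell_types) or list(
        predicted.sample_ids
    ) != list(actual.sample_ids):
        raise AlignmentError("predicted and actual matrices are not aligned")
    return predicted.values.to_numpy(float), actual.values.to_numpy(float)


def rmse(predicted: CompositionMatrix, actual: CompositionMatrix) -> float:
    """Root-mean-square error over all (cell type, sample) cells."""
    p, a = _aligned(predicted, actual)
    return float(np.sqrt(np.mean((p - a) ** 2)))


def medape(
    predicted: CompositionMatrix,
    actual: CompositionMatrix,
    return_excluded: bool = False,
):
    """Median absolute percentage error, ``median(|p_m - p_a| / p_a)``.

    Cells whose actual proportion is exactly 0 are excluded (the ratio is
    undefined there); the exclusion count is available via
    ``return_excluded=True``.
    """
    p, a = _aligned(predicted, actual)
    support = a > 0
    n_excluded = int((~support).sum())
    if not support.any():
        raise UndefinedMetricError("all actual proportions are zero")
    value = float(np.median(np.abs(p[support] - a[support]) / a[support]))
    return (value, n_excluded) if return_excluded else value


def spearman_by_celltype(
    predicted: CompositionMatrix, actual: CompositionMatrix
) -> dict[str, float]:
    """Per-cell-type Spearman rho across samples (NaN where undefined)."""
    p, a = _aligned(predicted, actual)
    if p.shape[1] < 3:
        raise ValueError("need >= 3 samples for rank correlation")
    out = {}
    for i, t in enumerate(predicted.cell_types):
        if np.ptp(p[i]) == 0 or np.ptp(a[i]) == 0:
            out[t] = float("nan")  # constant vector: rho undefined, not 0
            continue
        rho = stats.spearmanr(p[i], a[i]).statistic
        out[t] = float(rho)
    return out


def shapiro_by_celltype(
    predicted: CompositionMatrix, actual: CompositionMatrix
) -> dict[str, float]:
    """Shapiro-Wilk normality p-value of per-type errors (diagnostic only)."""
    p, a = _aligned(predicted, actual)
    out = {}
    for i, t in enumerate(predicted.cell_types):
        err = p[i] - a[i]
        if len(err) < 3 or np.ptp(err) == 0:
            out[t] = float("nan")
            continue
        out[t] = float(stats.shapiro(err[:5000]).pvalue)
    return out


def evaluate(
    predicted: CompositionMatrix,
    actual: CompositionMatrix,
    scenario: dict | None = None,
) -> EvaluationReport:
    """Full scoring of one deconvolution run against ground truth."""
    value, n_excluded = medape(predicted, actual, return_excluded=True)
    return EvaluationReport(
        spearman=spearman_by_celltype(predicted, actual),
        rmse=rmse(predicted, actual),
        medape=value,
        medape_excluded=n_excluded,
        normality_p=shapiro_by_celltype(predicted, actual),
        scenario=scenario or {},
    )


def _align_result(result, truth: CompositionMatrix) -> CompositionMatrix:
    """Reorder a deconvolution result onto the truth's cell-type order."""
    missing = truth.cell_types.difference(result.proportions.index)
    if len(missing):
        raise AlignmentError(f"result lacks cell types: {list(missing)}")
    return CompositionMatrix(
        result.proportions.loc[list(truth.cell_types), list(truth.sample_ids)]
    )


def purity_check(
    pure_samples: LabeledReference,
    signature_main: SignatureMatrix,
    signature_immune: SignatureMatrix | None = None,
    method: str = "rpc",
) -> PurityReport:
    """Deconvolve pure reference samples; score recognition of the true type.

    Samples from panel-member source sets (A, C) contribute to the
    "recognizing-self" mean, independent sets (B, D) to "recognizing-other".
    """
    if signature_immune is not None:
        result = _deconv.deconvolve_hierarchical(
            pure_samples.betas, signature_main, signature_immune, method=method
        )
    else:
        result = _deconv.deconvolve(pure_samples.betas, signature_main,
                                    method=method)
    rows = []
    for sid in pure_samples.betas.sample_ids:
        true_type = pure_samples.labels[sid]
        score = (
            float(result.proportions.loc[true_type, sid])
            if true_type in result.proportions.index
            else float("nan")
        )
        rows.append(
            {
                "sample_id": sid,
                "true_type": true_type,
                "source_set": pure_samples.source_set[sid],
                "score": score,
            }
        )
    per_sample = pd.DataFrame(rows)
    groups = {
        "recognizing_self": per_sample["source_set"].isin(["A", "C"]),
        "recognizing_other": per_sample["source_set"].isin(["B", "D"]),
        "user": per_sample["source_set"] == "user",
    }
    set_means = {
        name: float(per_sample.loc[mask, "score"].mean())
        for name, mask in groups.items()
        if mask.any()
    }
    return PurityReport(per_sample=per_sample, set_means=set_means)


def build_hierarchical_panel(
    reference: LabeledReference,
    immune_types: Sequence[str] = IMMUNE_SUBTYPES,
    fdr_max: float = 0.01,
    delta_min_by_type=None,
    immune_delta_min: float = 0.5,
    aggregator: str = "median",
    normalize_for_selection: bool = True,
):
    """Build the main (IC-aggregated) and immune-subtype signature pair.

    Marker *selection* runs on a min-max normalized copy of the reference —
    the delta thresholds are calibrated on that full-range scale — while
    the signature values themselves are aggregated from the reference betas
    as given, the scale on which mixtures are deconvolved.  Immune subtypes
    are collapsed to "IC" for the main-step one-vs-all selection; a second
    one-vs-all selection among immune subtypes (immune samples only) yields
    the second-step signature.
    """
    if normalize_for_selection:
        selection_ref = LabeledReference(
            _io.min_max_normalize(reference.betas),
            reference.labels,
            reference.source_set,
        )
    else:
        selection_ref = reference
    immune_present = [t for t in reference.cell_types if t in set(immune_types)]
    ic_map = {t: "IC" for t in immune_present}
    main_sel = _panel.select_features_one_vs_all(
        selection_ref.relabel(ic_map), fdr_max=fdr_max,
        delta_min_by_type=delta_min_by_type,
    )
    main_sig = _panel.build_signature(reference.relabel(ic_map), main_sel,
                                      aggregator=aggregator, step="main")
    immune_samples = [
        s for s in reference.labels.index
        if reference.labels[s] in immune_present
    ]
    immune_sel = _panel.select_features_one_vs_all(
        selection_ref.subset_samples(immune_samples),
        fdr_max=fdr_max,
        delta_min_by_type={t: immune_delta_min for t in immune_present},
    )
    immune_sig = _panel.build_signature(
        reference.subset_samples(immune_samples), immune_sel,
        aggregator=aggregator, step="immune",
    )
    return main_sig, immune_sig, main_sel, immune_sel


def run_scenario_sweep(
    reference: LabeledReference,
    caps: Sequence[float] = DEFAULT_CAPS,
    n_pool: int = 10_000,
    n_select: int = 20,
    n_repeats: int = 3,
    seed: int = 0,
    method: str = "rpc",
    immune_types: Sequence[str] = IMMUNE_SUBTYPES,
    profile_samples_per_type: int = 4,
    alpha: float = 1.0,
    fdr_max: float = 0.01,
    delta_min_by_type=None,
) -> tuple[pd.DataFrame, list[EvaluationReport]]:
    """Immune-cap scenario sweep: accuracy as a function of cell balance.

    For each cap: a pool of ``n_pool`` Dirichlet compositions conditioned on
    the summed immune fraction <= cap is generated, ``n_select`` are drawn,
    three profile matrices are built from held-out reference samples, and
    every selected composition is mixed with each profile matrix
    (``n_select`` x 3 bulk samples), deconvolved hierarchically and scored.
    Values reported are means over ``n_repeats`` independent repeats.

    The signature panel is built once, from the panel-member source sets
    (A/C); profile matrices are drawn from the independent sets (B/D), so
    the methylomes behind the mixtures are disjoint from the panel.
    """
    panel_mask = reference.source_set.isin(["A", "C"])
    profile_mask = reference.source_set.isin(["B", "D"])
    if not panel_mask.any() or not profile_mask.any():
        # untagged reference: deterministic per-type half split
        panel_ids, profile_ids = [], []
        for t in reference.cell_types:
            samples = reference.samples_of(t)
            half = len(samples) // 2
            panel_ids += samples[:half]
            profile_ids += samples[half:]
    else:
        panel_ids = list(reference.labels.index[panel_mask])
        profile_ids = list(reference.labels.index[profile_mask])

    panel_ref = reference.subset_samples(panel_ids)
    profile_ref = reference.subset_samples(profile_ids)
    main_sig, immune_sig, *_ = build_hierarchical_panel(
        panel_ref,
        immune_types=immune_types,
        fdr_max=fdr_max,
        delta_min_by_type=delta_min_by_type,
    )
    immune_present = [t for t in reference.cell_types if t in set(immune_types)]
    mains = [t for t in reference.cell_types if t not in set(immune_present)]
    type_order = mains + immune_present

    reports: list[EvaluationReport] = []
    seeds = np.random.SeedSequence(seed).spawn(len(caps) * n_repeats)
    for ci, cap in enumerate(caps):
        for rep in range(n_repeats):
            rng = np.random.default_rng(seeds[ci * n_repeats + rep])
            comps = _simulate.sample_compositions(
                n_pool, type_order, immune_types=immune_present,
                immune_cap=cap, alpha=alpha, seed=rng,
            )
            chosen = sorted(
                rng.choice(n_pool, size=n_select, replace=False).tolist()
            )
            selected = CompositionMatrix(comps.values.iloc[:, chosen])
            mixture_blocks = []
            truth_blocks = []
            for pm in range(3):
                counts = {
                    t: min(profile_samples_per_type,
                           len(profile_ref.samples_of(t)))
                    for t in type_order
                }
                profiles = _simulate.build_profile_matrix(
                    profile_ref, counts, seed=rng
                )
                ms = _simulate.mix(profiles, selected)
                block = ms.mixtures.values.add_suffix(f"_p{pm + 1}")
                mixture_blocks.append(block)
                truth_blocks.append(ms.truth.values.add_suffix(f"_p{pm + 1}"))
            from .containers import BetaMatrix  # local to avoid cycle at import

            mixtures = BetaMatrix(pd.concat(mixture_blocks, axis=1))
            truth = CompositionMatrix(pd.concat(truth_blocks, axis=1))
            result = _deconv.deconvolve_hierarchical(
                mixtures, main_sig, immune_sig, method=method
            )
            predicted = _align_result(result, truth)
            report = evaluate(
                predicted, truth,
                scenario={"immune_cap": float(cap), "repeat": rep},
            )
            reports.append(report)
            logger.info("cap %.2f repeat %d: RMSE=%.4f MedAPE=%.3f",
                        cap, rep, report.rmse, report.medape)

    rows = [f"Spearman_{t}" for t in type_order] + ["RMSE", "MedAPE"]
    summary = pd.DataFrame(index=rows, columns=[f"{c:.2f}" for c in caps],
                           dtype=float)
    for ci, cap in enumerate(caps):
        cap_reports = reports[ci * n_repeats:(ci + 1) * n_repeats]
        for t in type_order:
            summary.loc[f"Spearman_{t}", f"{cap:.2f}"] = float(
                np.nanmean([r.spearman[t] for r in cap_reports])
            )
        summary.loc["RMSE", f"{cap:.2f}"] = float(
            np.mean([r.rmse for r in cap_reports])
        )
        summary.loc["MedAPE", f"{cap:.2f}"] = float(
            np.mean([r.medape for r in cap_reports])
        )
    return summary, reports


def compare_methods(
    mixtures: MixtureSet,
    configurations: Sequence[tuple[str, Callable]],
) -> pd.DataFrame:
    """Score several deconvolution configurations on one mixture set.

    ``configurations`` is a list of ``(name, fitter)`` where ``fitter`` maps
    a BetaMatrix of mixtures to a DeconvolutionResult.  The output table has
    one column per configuration plus a ``ground_truth`` column for the
    mean-content rows, and a final ``top3_count`` row tallying how often
    each configuration scored among the best three in a category (ties all
    count; undefined scores are excluded from the category).
    """
    truth = mixtures.truth
    types = list(truth.cell_types)
    spearman_rows = {f"spearman_{t}": {} for t in types}
    content_rows = {f"content_{t}": {} for t in types}
    other_rows = {"rmse": {}, "medape": {}}
    truth_content = truth.values.mean(axis=1)

    for name, fitter in configurations:
        result = fitter(mixtures.mixtures)
        predicted = _align_result(result, truth)
        report = evaluate(predicted, truth)
        for t in types:
            spearman_rows[f"spearman_{t}"][name] = report.spearman[t]
            content_rows[f"content_{t}"][name] = float(
                predicted.values.loc[t].mean()
            )
        other_rows["rmse"][name] = report.rmse
        other_rows["medape"][name] = report.medape

    names = [name for name, _ in configurations]
    table = pd.DataFrame(
        {**spearman_rows, **other_rows, **content_rows}
    ).T[names].astype(float)

    tally = dict.fromkeys(names, 0)
    for row in table.index:
        scores = table.loc[row]
        if row.startswith("spearman_"):
            goodness = scores
        elif row in ("rmse", "medape"):
            goodness = -scores
        else:  # content rows: closeness to the true mean content
            t = row.removeprefix("content_")
            goodness = -(scores - float(truth_content[t])).abs()
        valid = goodness.dropna()
        if valid.empty:
            continue
        cutoff = valid.sort_values(ascending=False).iloc[: 3].min()
        for name in valid.index[valid >= cutoff]:
            tally[name] += 1
    table.loc["top3_count"] = pd.Series(tally, dtype=float)
    table["ground_truth"] = np.nan
    for t in types:
        table.loc[f"content_{t}", "ground_truth"] = float(truth_content[t])
    return table
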