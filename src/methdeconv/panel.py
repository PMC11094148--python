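"""Marker-CpG selection and signature-matrix construction.

Two selection strategies are provided, matching the two families of
reference-based deconvolution tools:

* **one-vs-all** — each cell type is contrasted against the pooled
  remainder; a probe is kept when its FDR-adjusted moderated-t q-value is
  below ``fdr_max`` and the absolute difference of group *mean* betas
  reaches a per-type threshold.  The tumor-aware four-type panel uses the
  thresholds 0.85 (IC), 0.65 (Fib), 0.55 (Epi) and 0.8 (TC).
* **pairwise** — every unordered pair of cell types is contrasted; probes
  passing the FDR cut and an absolute group-*median* difference threshold
  are ranked and truncated to ``max_per_pair`` per direction of change
  (hyper-/hypomethylated), the convention of pairwise selection tools
  (default 100 per pair; ~1000 when pre-selecting for collinearity-aware
  deconvolution).

The differential test is a moderated t with empirical-Bayes variance
shrinkage: per-probe pooled variances are shrunk toward a common prior
fitted by the standard scaled-F moment method, which stabilizes inference
with the few replicates per cell type that reference panels typically have.
"""
from __future__ import annotations

import itertools
import logging
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .containers import (
    FeatureSelection,
    LabeledReference,
    SignatureMatrix,
)

logger = logging.getLogger(__name__)

#: per-type minimum |mean-beta difference| of the tumor-aware one-vs-all panel
ONE_VS_ALL_DELTA_MIN = {"IC": 0.85, "Fib": 0.65, "Epi": 0.55, "TC": 0.8}
DEFAULT_DELTA_MIN = 0.5


def _trigamma_inverse(x: np.ndarray) -> np.ndarray:
    """Solve trigamma(y) = x by Newton iteration (monotone, convex)."""
    x = np.asarray(x, dtype=float)
    y = 0.5 + 1.0 / x
    for _ in range(75):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if np.max(np.abs(dif) / np.maximum(y, 1e-12)) < 1e-10:
            break
    return y


def squeeze_variances(s2: np.ndarray, df: float) -> tuple[np.ndarray, float, float]:
    """Empirical-Bayes shrinkage of per-probe variances.

    Fits a scaled inverse-chi-square prior (``df_prior``, ``s2_prior``) to
    the observed sample variances by matching moments of log s2, then
    returns the posterior variances
    ``(df_prior * s2_prior + df * s2) / (df_prior + df)``.

    Returns (posterior variances, df_prior, s2_prior); ``df_prior`` is
    ``inf`` when the variances are consistent with a single common value.
    """
    s2 = np.clip(np.asarray(s2, dtype=float), 0.0, None)
    if len(s2) < 2:
        s2_prior = float(s2[0]) if len(s2) else 0.0
        return np.full_like(s2, s2_prior), np.inf, s2_prior
    m = float(np.median(s2))
    if m == 0.0:
        if not (s2 > 0).any():  # every probe constant: nothing to shrink
            return np.zeros_like(s2), np.inf, 0.0
        m = 1.0
    s2_off = np.maximum(s2, 1e-5 * m)  # offset exact zeros away from log(0)
    z = np.log(s2_off)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2.0))
    if e_var > 0:
        df_prior = float(2.0 * _trigamma_inverse(np.array(e_var)))
        s2_prior = float(np.exp(
            e_mean + special.digamma(df_prior / 2.0) - np.log(df_prior / 2.0)
        ))
    else:
        df_prior = np.inf
        s2_prior = float(s2_off.mean())
    if np.isfinite(df_prior):
        post = (df_prior * s2_prior + df * s2) / (df_prior + df)
    else:
        post = np.full_like(s2, s2_prior)
    return post, df_prior, s2_prior


def moderated_differential_test(
    reference: LabeledReference,
    group: Sequence[str],
    rest: Sequence[str],
    comparison_label: str,
) -> pd.DataFrame:
    """Moderated two-group differential methylation test, per probe.

    Returns a DataFrame with columns ``probe_id``, ``comparison``,
    ``delta`` (difference of group means), ``delta_median`` (difference of
    group medians), ``t_stat`` (moderated t), ``p_value`` and ``q_value``
    (Benjamini-Hochberg over all probes in this comparison).  Probes with a
    missing value in either group are dropped (complete-case).
    """
    group = list(group)
    rest = list(rest)
    if set(group) & set(rest):
        raise ValueError("group and rest sample sets overlap")
    if len(group) < 2 or len(rest) < 2:
        raise ValueError(
            f"need >= 2 samples per side for variance estimation "
            f"(got {len(group)} vs {len(rest)})"
        )
    vals = reference.betas.values
    missing = [s for s in group + rest if s not in vals.columns]
    if missing:
        raise KeyError(f"samples absent from reference: {missing[:5]}")
    g = vals[group].dropna(axis=0)
    r = vals[rest].dropna(axis=0)
    shared = g.index.intersection(r.index)
    g = g.loc[shared].to_numpy()
    r = r.loc[shared].to_numpy()

    n1, n2 = len(group), len(rest)
    mean1, mean2 = g.mean(axis=1), r.mean(axis=1)
    delta = mean1 - mean2
    delta_median = np.median(g, axis=1) - np.median(r, axis=1)
    df_resid = n1 + n2 - 2
    ss = g.var(axis=1, ddof=1) * (n1 - 1) + r.var(axis=1, ddof=1) * (n2 - 1)
    s2 = ss / df_resid
    s2_post, df_prior, _ = squeeze_variances(s2, df_resid)
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, delta / np.where(se > 0, se, 1.0), 0.0)
        t = np.where((se == 0) & (delta != 0), np.sign(delta) * np.inf, t)
    # total df capped at the pooled residual df, as in the reference method
    df_total = min(df_resid + df_prior, len(s2) * df_resid)
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.clip(p, 0.0, 1.0)
    q = stats.false_discovery_control(p, method="bh")
    out = pd.DataFrame(
        {
            "probe_id": shared.to_numpy(),
            "comparison": comparison_label,
            "delta": delta,
            "delta_median": delta_median,
            "t_stat": t,
            "p_value": p,
            "q_value": q,
        }
    )
    logger.info("%s: %d probes tested (df=%d, df_prior=%.2f)",
                comparison_label, len(out), df_resid,
                df_prior if np.isfinite(df_prior) else float("inf"))
    return out


def welch_differential_test(
    reference: LabeledReference,
    group: Sequence[str],
    rest: Sequence[str],
    comparison_label: str,
) -> pd.DataFrame:
    """Plain Welch t-test variant, kept as an independent cross-check."""
    vals = reference.betas.values
    g = vals[list(group)].dropna(axis=0)
    r = vals[list(rest)].dropna(axis=0)
    shared = g.index.intersection(r.index)
    g, r = g.loc[shared].to_numpy(), r.loc[shared].to_numpy()
    t, p = stats.ttest_ind(g, r, axis=1, equal_var=False)
    q = stats.false_discovery_control(np.clip(np.nan_to_num(p, nan=1.0), 0, 1),
                                      method="bh")
    return pd.DataFrame(
        {
            "probe_id": shared.to_numpy(),
            "comparison": comparison_label,
            "delta": g.mean(axis=1) - r.mean(axis=1),
            "delta_median": np.median(g, axis=1) - np.median(r, axis=1),
            "t_stat": t,
            "p_value": p,
            "q_value": q,
        }
    )


def _rank_probes(df: pd.DataFrame, delta_col: str) -> pd.DataFrame:
    """Deterministic ranking: q ascending, |delta| descending, probe lexicographic."""
    key = df.assign(_absd=-df[delta_col].abs())
    order = key.sort_values(
        ["q_value", "_absd", "probe_id"], kind="mergesort"
    ).index
    return df.loc[order]


def select_features_one_vs_all(
    reference: LabeledReference,
    fdr_max: float = 0.01,
    delta_min_by_type: Mapping[str, float] | None = None,
    signed: bool = False,
) -> FeatureSelection:
    """One-vs-all marker selection: each type against the pooled remainder.

    A probe is selected for a type when ``q_value < fdr_max`` and the
    absolute (or signed, with ``signed=True``) difference of group mean
    betas is at least that type's threshold.  Types without a threshold in
    ``delta_min_by_type`` fall back to the tumor-aware defaults
    (IC 0.85, Fib 0.65, Epi 0.55, TC 0.8) or 0.5.
    """
    types = reference.cell_types
    thresholds = {}
    for t in types:
        if delta_min_by_type and t in delta_min_by_type:
            thresholds[t] = delta_min_by_type[t]
        else:
            thresholds[t] = ONE_VS_ALL_DELTA_MIN.get(t, DEFAULT_DELTA_MIN)
    if delta_min_by_type:
        unknown = set(delta_min_by_type) - set(types)
        if unknown:
            raise KeyError(f"delta_min_by_type names unknown types: {sorted(unknown)}")

    per_comparison: dict[str, pd.DataFrame] = {}
    warn_list: list[str] = []
    union: dict[str, None] = {}
    for t in types:
        group = reference.samples_of(t)
        rest = [s for s in reference.labels.index if reference.labels[s] != t]
        label = f"{t}_vs_rest"
        stats_df = moderated_differential_test(reference, group, rest, label)
        effect = stats_df["delta"] if signed else stats_df["delta"].abs()
        keep = (stats_df["q_value"] < fdr_max) & (effect >= thresholds[t])
        sel = _rank_probes(stats_df.loc[keep], "delta").reset_index(drop=True)
        if sel.empty:
            msg = f"no probes selected for {t} (delta_min={thresholds[t]})"
            warn_list.append(msg)
            warnings.warn(msg, stacklevel=2)
        per_comparison[label] = sel
        for p in sel["probe_id"]:
            union.setdefault(p, None)
        logger.info("one-vs-all %s: %d probes", t, len(sel))
    return FeatureSelection(
        strategy="one_vs_all",
        per_comparison=per_comparison,
        union=list(union),
        parameters={"fdr_max": fdr_max, "delta_min_by_type": thresholds,
                    "signed": signed},
        warnings=warn_list,
    )


def select_features_pairwise(
    reference: LabeledReference,
    max_per_pair: int = 100,
    delta_median_min: float = 0.2,
    fdr_max: float = 0.01,
) -> FeatureSelection:
    """Pairwise marker selection over all unordered cell-type pairs.

    Probes passing ``q_value < fdr_max`` and ``|median-beta difference| >=
    delta_median_min`` are ranked (q ascending, |delta| descending, probe ID)
    and truncated to ``max_per_pair`` separately within the hyper- and the
    hypomethylated direction of each pair.
    """
    types = reference.cell_types
    if len(types) < 2:
        raise ValueError("pairwise selection needs >= 2 cell types")
    per_comparison: dict[str, pd.DataFrame] = {}
    union: dict[str, None] = {}
    for a, b in itertools.combinations(types, 2):
        label = f"{a}_vs_{b}"
        stats_df = moderated_differential_test(
            reference, reference.samples_of(a), reference.samples_of(b), label
        )
        keep = (stats_df["q_value"] < fdr_max) & (
            stats_df["delta_median"].abs() >= delta_median_min
        )
        passed = stats_df.loc[keep]
        parts = []
        for direction in (passed["delta_median"] > 0, passed["delta_median"] < 0):
            ranked = _rank_probes(passed.loc[direction], "delta_median")
            parts.append(ranked.head(max_per_pair))
        sel = pd.concat(parts).reset_index(drop=True) if parts else passed
        per_comparison[label] = sel
        for p in sel["probe_id"]:
            union.setdefault(p, None)
        logger.info("pairwise %s: %d probes", label, len(sel))
    return FeatureSelection(
        strategy="pairwise",
        per_comparison=per_comparison,
        union=list(union),
        parameters={"max_per_pair": max_per_pair,
                    "delta_median_min": delta_median_min, "fdr_max": fdr_max},
    )


def build_signature(
    reference: LabeledReference,
    selection: FeatureSelection | Sequence[str],
    aggregator: str = "median",
    step: str = "main",
) -> SignatureMatrix:
    """Aggregate reference betas at selected probes into a signature matrix.

    ``selection`` may be a :class:`FeatureSelection` or a plain probe list —
    the latter supports externally fixed marker sets such as the unaltered
    immune-subtype list used for the second deconvolution step.
    """
    probes = (
        list(selection.union)
        if isinstance(selection, FeatureSelection)
        else list(selection)
    )
    missing = [p for p in probes if p not in reference.betas.probe_ids]
    if missing:
        raise KeyError(
            f"{len(missing)} selected probes missing from reference, e.g. "
            f"{missing[:5]}"
        )
    sub = reference.betas.values.loc[probes]
    cols = {}
    for t in reference.cell_types:
        block = sub[reference.samples_of(t)]
        cols[t] = block.median(axis=1) if aggregator == "median" else block.mean(axis=1)
    values = pd.DataFrame(cols)
    return SignatureMatrix(values, aggregator=aggregator, step=step)


def selection_report(selection: FeatureSelection) -> pd.DataFrame:
    """Flatten a FeatureSelection into one (comparison, probe, stats) table."""
    frames = [df for df in selection.per_comparison.values() if not df.empty]
    if not frames:
        return pd.DataFrame(
            columns=["probe_id", "comparison", "delta", "delta_median",
                     "t_stat", "p_value", "q_value"]
        )
    return pd.concat(frames, ignore_index=True)
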