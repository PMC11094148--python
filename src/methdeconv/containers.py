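"""Core data containers.

Every matrix in this package is a thin, validated wrapper around a pandas
DataFrame with a fixed orientation: CpG probes in rows, samples (or cell
types) in columns.  Beta values are methylation fractions in [0, 1];
compositions live on the probability simplex (columns sum to 1).
"""
from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

SIMPLEX_TOL = 1e-9

# canonical immune subtypes used throughout (leukocyte compartment, "IC")
IMMUNE_SUBTYPES = ("B", "NK", "CD4T", "CD8T", "Mono", "Neutro", "Eosino")


class FormatError(ValueError):
    """Malformed input: duplicate identifiers, bad headers, shape mismatch."""


class BetaRangeError(ValueError):
    """A parsed or computed beta value falls outside [0, 1]."""


class AlignmentError(ValueError):
    """Two matrices that must share an axis ordering do not."""


class CoverageError(ValueError):
    """Too few signature probes are present in the mixture matrix."""


class ConditioningError(ValueError):
    """Signature matrix is rank-deficient on the shared probe set."""


class EmptyResultError(ValueError):
    """An operation removed every probe/sample."""


class ConfigurationError(ValueError):
    """Inconsistent parameters (e.g. missing IC column in a main signature)."""


class UndefinedMetricError(ValueError):
    """Metric undefined for the given input (e.g. MedAPE with all-zero truth)."""


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dups = index[index.duplicated()].unique().tolist()[:5]
        raise FormatError(f"duplicate {what}: {dups}")


def _check_beta_range(values: pd.DataFrame) -> None:
    arr = values.to_numpy(dtype=float)
    bad = (arr < 0) | (arr > 1)
    bad &= ~np.isnan(arr)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise BetaRangeError(
            f"beta value {arr[i, j]!r} outside [0, 1] at probe "
            f"{values.index[i]!r}, sample {values.columns[j]!r}"
        )


@dataclasses.dataclass
class BetaMatrix:
    """CpG probes x samples matrix of methylation beta values.

    Missing measurements are stored as NaN.  ``platform`` tags the array
    generation ("450K", "EPIC") or "synthetic" for simulated data.
    """

    values: pd.DataFrame
    platform: str = "synthetic"

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "probe IDs")
        _check_unique(self.values.columns, "sample IDs")
        _check_beta_range(self.values)

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def drop_incomplete_probes(self) -> "BetaMatrix":
        """Remove probes with any missing value (complete-case analysis)."""
        kept = self.values.dropna(axis=0)
        return BetaMatrix(kept, platform=self.platform)

    def subset_probes(self, probes: Sequence[str]) -> "BetaMatrix":
        missing = pd.Index(probes).difference(self.values.index)
        if len(missing):
            raise KeyError(f"probes absent from matrix: {list(missing[:5])}")
        return BetaMatrix(self.values.loc[list(probes)], platform=self.platform)


@dataclasses.dataclass
class LabeledReference:
    """Reference methylomes: a BetaMatrix plus per-sample cell-type labels.

    ``source_set`` tags each sample with its provenance panel (A/B/C/D for
    the panel-member vs independent split, "user" otherwise).
    """

    betas: BetaMatrix
    labels: pd.Series  # sample_id -> cell type
    source_set: pd.Series | None = None  # sample_id -> {A,B,C,D,user}

    def __post_init__(self) -> None:
        missing = self.betas.sample_ids.difference(self.labels.index)
        if len(missing):
            raise FormatError(f"samples without a label: {list(missing[:5])}")
        self.labels = self.labels.reindex(self.betas.sample_ids)
        if self.source_set is None:
            self.source_set = pd.Series(
                "user", index=self.betas.sample_ids, name="source_set"
            )
        else:
            self.source_set = self.source_set.reindex(
                self.betas.sample_ids
            ).fillna("user")

    @property
    def cell_types(self) -> list[str]:
        seen: dict[str, None] = {}
        for t in self.labels:
            seen.setdefault(t, None)
        return list(seen)

    def samples_of(self, cell_type: str) -> list[str]:
        return list(self.labels.index[self.labels == cell_type])

    def subset_samples(self, sample_ids: Sequence[str]) -> "LabeledReference":
        sub = self.betas.values[list(sample_ids)]
        return LabeledReference(
            BetaMatrix(sub, platform=self.betas.platform),
            self.labels.loc[list(sample_ids)],
            self.source_set.loc[list(sample_ids)],
        )

    def relabel(self, mapping: Mapping[str, str]) -> "LabeledReference":
        """Collapse cell-type labels, e.g. immune subtypes -> "IC"."""
        new = self.labels.map(lambda t: mapping.get(t, t))
        return LabeledReference(self.betas, new, self.source_set)


@dataclasses.dataclass
class CompositionMatrix:
    """Cell types x samples matrix of proportions; columns on the simplex."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "cell types")
        _check_unique(self.values.columns, "sample IDs")
        arr = self.values.to_numpy(dtype=float)
        if (arr < -SIMPLEX_TOL).any():
            raise FormatError("negative proportion in composition matrix")
        sums = arr.sum(axis=0)
        off = np.abs(sums - 1.0)
        if (off > 1e-6).any():
            j = int(np.argmax(off))
            raise FormatError(
                f"composition column {self.values.columns[j]!r} sums to "
                f"{sums[j]:.9f}, not 1"
            )

    @property
    def cell_types(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns


@dataclasses.dataclass
class ProfileMatrix:
    """Pure cell-type methylation profiles (probes x cell types): matrix P.

    ``manifest`` records which reference samples were averaged per type so
    callers can verify disjointness from signature-building samples.
    """

    values: pd.DataFrame
    manifest: dict[str, list[str]] | None = None

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "probe IDs")
        _check_unique(self.values.columns, "cell types")
        _check_beta_range(self.values)

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def cell_types(self) -> pd.Index:
        return self.values.columns


@dataclasses.dataclass
class MixtureSet:
    """Synthetic bulk mixtures M with their ground-truth composition S."""

    mixtures: BetaMatrix
    truth: CompositionMatrix
    provenance: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if list(self.mixtures.sample_ids) != list(self.truth.sample_ids):
            raise AlignmentError("mixture and truth sample IDs differ")


@dataclasses.dataclass
class SignatureMatrix:
    """Selected CpGs x cell types: the deconvolution design matrix."""

    values: pd.DataFrame
    aggregator: str = "median"  # {mean, median}
    step: str = "main"  # {main, immune}

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "probe IDs")
        _check_unique(self.values.columns, "cell types")
        _check_beta_range(self.values)
        if self.aggregator not in ("mean", "median"):
            raise ConfigurationError(f"unknown aggregator {self.aggregator!r}")
        if self.step not in ("main", "immune"):
            raise ConfigurationError(f"unknown step {self.step!r}")

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def cell_types(self) -> pd.Index:
        return self.values.columns


@dataclasses.dataclass
class FeatureSelection:
    """Outcome of a marker-selection run.

    ``per_comparison`` maps a comparison label (e.g. "IC_vs_rest") to the
    DataFrame of selected probes with their statistics; ``union`` is the
    deduplicated concatenation in a deterministic order.
    """

    strategy: str  # {one_vs_all, pairwise}
    per_comparison: dict[str, pd.DataFrame]
    union: list[str]
    parameters: dict
    warnings: list[str] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        expected: dict[str, None] = {}
        for df in self.per_comparison.values():
            for p in df["probe_id"]:
                expected.setdefault(p, None)
        if list(expected) != list(self.union):
            raise FormatError("union is not the deduplicated concatenation "
                              "of per-comparison lists")


@dataclasses.dataclass
class DeconvolutionResult:
    """Estimated cell-type proportions (cell types x samples, simplex columns).

    ``diagnostics`` is one row per sample: reconstruction RMSE, number of
    negative coefficients clipped, probe coverage, chosen nu (SVR) and a
    degenerate-fit flag.
    """

    proportions: pd.DataFrame
    method: str
    diagnostics: pd.DataFrame

    def __post_init__(self) -> None:
        arr = self.proportions.to_numpy(dtype=float)
        if (arr < -SIMPLEX_TOL).any():
            raise FormatError("negative estimated proportion")
        if np.abs(arr.sum(axis=0) - 1.0).max() > 1e-6:
            raise FormatError("estimated proportions do not sum to 1")

    @property
    def cell_types(self) -> pd.Index:
        return self.proportions.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.proportions.columns

    def as_composition(self) -> CompositionMatrix:
        return CompositionMatrix(self.proportions.copy())


@dataclasses.dataclass
class EvaluationReport:
    """Accuracy of one deconvolution run against ground truth."""

    spearman: dict[str, float]  # cell type -> rho (NaN if undefined)
    rmse: float
    medape: float
    medape_excluded: int  # cells with true proportion 0, left out of MedAPE
    normality_p: dict[str, float]  # Shapiro-Wilk p of per-type errors
    scenario: dict = dataclasses.field(default_factory=dict)


@dataclasses.dataclass
class PurityReport:
    """Recognition of pure reference samples by a deconvolution protocol."""

    per_sample: pd.DataFrame  # sample_id, true_type, source_set, score
    set_means: dict[str, float]  # recognizing_self / recognizing_other / user
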