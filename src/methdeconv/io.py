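"""Reading, writing and probe-level preprocessing of beta matrices.

File dialects
-------------
* Beta matrix: TSV/CSV, first column header ``probe_id``, remaining headers
  sample IDs.  An optional leading comment line ``# platform=450K`` carries
  the array platform; otherwise the platform defaults to "synthetic".
* Labels: TSV with columns ``sample_id``, ``cell_type`` and optionally
  ``source_set``.
* Probe annotation: TSV with columns ``probe_id``, ``chromosome``,
  ``cross_reactive`` (0/1), ``snp_affected`` (0/1).
* Blacklists may alternatively be given as one-probe-per-line text files.
"""
from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    AlignmentError,
    BetaMatrix,
    BetaRangeError,
    CompositionMatrix,
    EmptyResultError,
    FormatError,
    LabeledReference,
    MixtureSet,
    SignatureMatrix,
)

logger = logging.getLogger(__name__)

SEX_CHROMOSOMES = ("chrX", "chrY")


def _read_header_and_meta(path: Path, delimiter: str) -> tuple[dict, int, list[str]]:
    meta: dict[str, str] = {}
    skip = 0
    with open(path) as fh:
        line = fh.readline()
        while line.startswith("#"):
            for token in line.lstrip("#").strip().split():
                if "=" in token:
                    k, v = token.split("=", 1)
                    meta[k] = v
            skip += 1
            line = fh.readline()
    header = line.rstrip("\n").split(delimiter)
    return meta, skip, header


def read_beta_matrix(path, delimiter: str = "\t") -> BetaMatrix:
    """Read a probes x samples beta matrix.

    Raises :class:`FormatError` on duplicate probe or sample IDs and
    :class:`BetaRangeError` (naming probe and sample) on values outside
    [0, 1].  Empty cells are kept as missing (NaN).
    """
    path = Path(path)
    meta, skip, header = _read_header_and_meta(path, delimiter)
    sample_ids = header[1:]
    if len(set(sample_ids)) != len(sample_ids):
        dups = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
        raise FormatError(f"duplicate sample IDs in header: {dups[:5]}")
    df = pd.read_csv(
        path, sep=delimiter, skiprows=skip, index_col=0, dtype=str
    )
    df.columns = sample_ids
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate probe IDs: {dups[:5]}")
    values = df.apply(pd.to_numeric, errors="coerce").astype(float)
    # distinguish genuinely empty cells from unparsable tokens
    unparsable = values.isna() & df.notna()
    if unparsable.to_numpy().any():
        i, j = np.argwhere(unparsable.to_numpy())[0]
        raise FormatError(
            f"non-numeric value {df.iat[i, j]!r} at probe {df.index[i]!r}, "
            f"sample {df.columns[j]!r}"
        )
    platform = meta.get("platform", "synthetic")
    logger.info("read %s: %d probes x %d samples (platform=%s)",
                path.name, *values.shape, platform)
    return BetaMatrix(values, platform=platform)


def write_beta_matrix(betas: BetaMatrix, path, delimiter: str = "\t") -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# platform={betas.platform}\n")
        betas.values.to_csv(fh, sep=delimiter, index_label="probe_id")


def read_labels(path, delimiter: str = "\t") -> tuple[pd.Series, pd.Series | None]:
    """Read a sample label table; returns (labels, source_set or None)."""
    df = pd.read_csv(path, sep=delimiter, dtype=str)
    if "sample_id" not in df.columns:  # headerless two/three-column file
        df = pd.read_csv(path, sep=delimiter, dtype=str, header=None)
        names = ["sample_id", "cell_type", "source_set"][: df.shape[1]]
        df.columns = names
    if df["sample_id"].duplicated().any():
        raise FormatError("duplicate sample IDs in label table")
    labels = df.set_index("sample_id")["cell_type"]
    source = (
        df.set_index("sample_id")["source_set"]
        if "source_set" in df.columns
        else None
    )
    return labels, source


def read_probe_annotation(path, delimiter: str = "\t") -> pd.DataFrame:
    """Read probe annotation (probe_id, chromosome, cross_reactive, snp_affected)."""
    df = pd.read_csv(path, sep=delimiter, dtype={"probe_id": str})
    if df["probe_id"].duplicated().any():
        raise FormatError("duplicate probe IDs in annotation")
    df = df.set_index("probe_id")
    for col in ("cross_reactive", "snp_affected"):
        if col in df.columns:
            df[col] = df[col].astype(int).astype(bool)
    return df


def read_probe_list(path) -> list[str]:
    """Read a one-probe-per-line blacklist / marker list."""
    with open(path) as fh:
        return [ln.strip() for ln in fh if ln.strip()]


def filter_probes(
    betas: BetaMatrix,
    annot: pd.DataFrame,
    drop_cross_reactive: bool = True,
    drop_snp: bool = True,
    drop_sex_chromosomes: bool = True,
) -> BetaMatrix:
    """Apply probe-level quality filters.

    Cross-reactive probes and probes affected by SNPs are removed when the
    corresponding flag is on; probes on chrX/chrY are removed for
    reference-panel use.  Probes absent from the annotation are removed only
    by filters that explicitly list them: under sex-chromosome filtering an
    unannotated probe is *retained* with a warning (its chromosome cannot be
    proven), never silently destroyed.  Input probe order is preserved.
    """
    probes = betas.probe_ids
    annotated = probes.isin(annot.index)
    drop = np.zeros(len(probes), dtype=bool)
    counts = {}
    if drop_cross_reactive and "cross_reactive" in annot.columns:
        flagged = annot.index[annot["cross_reactive"]]
        mask = probes.isin(flagged)
        counts["cross_reactive"] = int(mask.sum())
        drop |= mask
    if drop_snp and "snp_affected" in annot.columns:
        flagged = annot.index[annot["snp_affected"]]
        mask = probes.isin(flagged)
        counts["snp_affected"] = int(mask.sum())
        drop |= mask
    if drop_sex_chromosomes:
        chrom = annot["chromosome"].reindex(probes)
        mask = chrom.isin(SEX_CHROMOSOMES).to_numpy()
        counts["sex_chromosome"] = int(mask.sum())
        drop |= mask
        n_unannot = int((~annotated).sum())
        if n_unannot:
            warnings.warn(
                f"{n_unannot} probes lack annotation; retained despite "
                "sex-chromosome filtering",
                stacklevel=2,
            )
    kept = betas.values.loc[~drop]
    logger.info("filter_probes: removed %s, kept %d/%d",
                counts, kept.shape[0], len(probes))
    if kept.shape[0] == 0:
        raise EmptyResultError("all probes removed by filters")
    return BetaMatrix(kept, platform=betas.platform)


def intersect_platforms(a: BetaMatrix, b: BetaMatrix) -> tuple[BetaMatrix, BetaMatrix]:
    """Restrict both matrices to their shared probes, in lexicographic order.

    Mirrors keeping only CpGs shared between the 450K and EPIC designs; the
    sorted order makes downstream runs byte-reproducible.
    """
    if a.shape[0] == 0 or b.shape[0] == 0:
        raise EmptyResultError("cannot intersect an empty matrix")
    shared = sorted(a.probe_ids.intersection(b.probe_ids))
    if not shared:
        raise EmptyResultError("no probes shared between the two matrices")
    logger.info("intersect_platforms: %d shared probes", len(shared))
    return (
        BetaMatrix(a.values.loc[shared], platform=a.platform),
        BetaMatrix(b.values.loc[shared], platform=b.platform),
    )


def min_max_normalize(betas: BetaMatrix) -> BetaMatrix:
    """Per-sample min-max normalization: x -> (x - min) / (max - min).

    The fallback normalization used when raw intensities are unavailable.
    Applied per sample (column) so between-probe contrasts within a sample
    are preserved.  Missing values are ignored when taking extremes.
    """
    vals = betas.values
    mins = vals.min(axis=0)
    maxs = vals.max(axis=0)
    span = maxs - mins
    flat = span <= 0
    if flat.any():
        bad = list(vals.columns[flat])[:5]
        raise BetaRangeError(f"constant beta column(s), cannot normalize: {bad}")
    out = (vals - mins) / span
    return BetaMatrix(out, platform=betas.platform)


def read_composition_matrix(path, delimiter: str = "\t") -> CompositionMatrix:
    df = pd.read_csv(path, sep=delimiter, index_col=0).astype(float)
    return CompositionMatrix(df)


def write_composition_matrix(comp: CompositionMatrix, path, delimiter: str = "\t") -> None:
    comp.values.to_csv(path, sep=delimiter, index_label="cell_type")


def write_signature(sig: SignatureMatrix, path, delimiter: str = "\t") -> None:
    """Write a signature in the tab-delimited upload dialect (probe ID first)."""
    sig.values.to_csv(path, sep=delimiter, index_label="probe_id")


def read_signature(path, delimiter: str = "\t", aggregator: str = "median",
                   step: str = "main") -> SignatureMatrix:
    df = pd.read_csv(path, sep=delimiter, index_col=0).astype(float)
    return SignatureMatrix(df, aggregator=aggregator, step=step)


def write_mixture_set(ms: MixtureSet, directory, prefix: str = "mixture") -> None:
    """Serialize a MixtureSet: betas TSV + truth TSV + JSON provenance."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_beta_matrix(ms.mixtures, directory / f"{prefix}_betas.tsv")
    write_composition_matrix(ms.truth, directory / f"{prefix}_truth.tsv")
    with open(directory / f"{prefix}_provenance.json", "w") as fh:
        json.dump(ms.provenance, fh, indent=2, sort_keys=True, default=str)


def read_mixture_set(directory, prefix: str = "mixture") -> MixtureSet:
    directory = Path(directory)
    betas = read_beta_matrix(directory / f"{prefix}_betas.tsv")
    truth = read_composition_matrix(directory / f"{prefix}_truth.tsv")
    with open(directory / f"{prefix}_provenance.json") as fh:
        prov = json.load(fh)
    return MixtureSet(betas, truth, prov)
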