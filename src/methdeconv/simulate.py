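"""Synthetic bulk-mixture generation with known ground truth.

The generative model is deliberately simple and matches how in-silico
deconvolution benchmarks are built: a composition matrix ``S`` (cell types x
samples, columns Dirichlet-distributed on the simplex, optionally conditioned
on a cap for the summed immune fraction), a profile matrix ``P`` of pure
cell-type methylomes (averages of randomly selected reference samples), and
the bulk mixture matrix ``M = P @ S`` — an exact linear (convex) combination
of profiles, with optional truncated Gaussian noise as an extension.

A fully synthetic labeled reference generator is included so the entire
pipeline (marker selection, signature construction, deconvolution, scoring)
can be exercised without any external downloads.
"""
from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import (
    AlignmentError,
    BetaMatrix,
    CompositionMatrix,
    ConfigurationError,
    IMMUNE_SUBTYPES,
    LabeledReference,
    MixtureSet,
    ProfileMatrix,
)

logger = logging.getLogger(__name__)

#: the ten cell types of the tumor-aware benchmark: epithelium, fibroblasts,
#: seven immune subtypes and the tumor component
DEFAULT_CELL_TYPES = (
    "Epi", "Fib", "B", "NK", "CD4T", "CD8T", "Mono", "Neutro", "Eosino", "TC",
)


def sample_compositions(
    n: int,
    cell_types: Sequence[str],
    immune_types: Sequence[str] = (),
    immune_cap: float = 1.0,
    alpha: float | Sequence[float] = 1.0,
    seed: int | np.random.Generator | None = None,
    max_attempts: int = 10_000,
) -> CompositionMatrix:
    """Draw ``n`` Dirichlet composition vectors, capping the immune sum.

    The cap is enforced by rejection sampling (whole vectors are redrawn
    until the summed immune entries are <= ``immune_cap``), which preserves
    the conditional-Dirichlet law.  ``max_attempts`` bounds the expected
    number of draws per accepted vector.
    """
    cell_types = list(cell_types)
    if len(cell_types) < 2:
        raise ConfigurationError("need at least 2 cell types")
    if immune_cap <= 0:
        raise ConfigurationError("immune_cap must be positive")
    immune_types = list(immune_types)
    unknown = set(immune_types) - set(cell_types)
    if unknown:
        raise ConfigurationError(f"immune types not in cell_types: {sorted(unknown)}")
    alpha_vec = np.broadcast_to(np.asarray(alpha, dtype=float), (len(cell_types),))
    if (alpha_vec <= 0).any():
        raise ConfigurationError("alpha entries must be positive")

    rng = np.random.default_rng(seed)
    immune_idx = [cell_types.index(t) for t in immune_types]
    accepted: list[np.ndarray] = []
    n_left = n
    total_draws = 0
    budget = max_attempts * n
    batch = max(1024, 2 * n)
    while n_left > 0:
        if total_draws >= budget:
            raise RuntimeError(
                f"rejection sampling failed after {total_draws} draws; "
                f"immune_cap={immune_cap} may be too tight for this alpha — "
                "consider a larger cap"
            )
        batch = int(min(max(batch, 1024), 2_000_000, budget - total_draws))
        draws = rng.dirichlet(alpha_vec, size=batch)
        total_draws += batch
        if immune_idx and immune_cap < 1.0:
            ok = draws[:, immune_idx].sum(axis=1) <= immune_cap
            draws = draws[ok]
            rate = max(len(draws) / batch, 1.0 / batch)
            batch = int(min(2_000_000, 1.5 * n_left / rate + 1024))
        take = draws[:n_left]
        if len(take):
            accepted.append(take)
            n_left -= len(take)
    mat = np.concatenate(accepted, axis=0)[:n].T  # types x samples
    width = max(3, len(str(n)))
    sample_ids = [f"mix{i + 1:0{width}d}" for i in range(n)]
    logger.info("sample_compositions: %d vectors from %d draws (cap=%.2f)",
                n, total_draws, immune_cap)
    return CompositionMatrix(pd.DataFrame(mat, index=cell_types, columns=sample_ids))


def build_profile_matrix(
    reference: LabeledReference,
    per_type_sample_counts: Mapping[str, int],
    seed: int | np.random.Generator | None = None,
    exclude: Sequence[str] = (),
) -> ProfileMatrix:
    """Average randomly selected reference samples into pure profiles.

    One column per cell type, equal to the arithmetic mean of the selected
    samples' betas; the selection manifest is attached so callers can verify
    that profile samples are disjoint from signature-panel samples (pass the
    panel samples via ``exclude``).
    """
    rng = np.random.default_rng(seed)
    exclude = set(exclude)
    cols = {}
    manifest: dict[str, list[str]] = {}
    for cell_type, count in per_type_sample_counts.items():
        pool = [s for s in reference.samples_of(cell_type) if s not in exclude]
        if len(pool) < count:
            raise ValueError(
                f"cell type {cell_type!r}: requested {count} samples but only "
                f"{len(pool)} available"
            )
        chosen = sorted(rng.choice(pool, size=count, replace=False).tolist())
        manifest[cell_type] = chosen
        cols[cell_type] = reference.betas.values[chosen].mean(axis=1)
    values = pd.DataFrame(cols)
    return ProfileMatrix(values, manifest=manifest)


def mix(
    profiles: ProfileMatrix,
    compositions: CompositionMatrix,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator | None = None,
) -> MixtureSet:
    """Form bulk mixtures ``M = P @ S`` (plus optional truncated noise).

    With ``noise_sd`` = 0 (the default) every mixture column is an exact
    convex combination of profile columns, so all values stay in [0, 1].
    Noise, when enabled, is Gaussian truncated to the valid beta range.
    """
    if list(profiles.cell_types) != list(compositions.cell_types):
        raise AlignmentError(
            "profile and composition cell types differ or are mis-ordered: "
            f"{list(profiles.cell_types)} vs {list(compositions.cell_types)}"
        )
    m = profiles.values.to_numpy() @ compositions.values.to_numpy()
    if noise_sd < 0:
        raise ConfigurationError("noise_sd must be non-negative")
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        m = np.clip(m + rng.normal(0.0, noise_sd, size=m.shape), 0.0, 1.0)
    values = pd.DataFrame(
        m, index=profiles.probe_ids, columns=compositions.sample_ids
    )
    provenance = {
        "noise_sd": noise_sd,
        "n_profiles": int(profiles.values.shape[1]),
        "profile_manifest": profiles.manifest,
    }
    return MixtureSet(BetaMatrix(values, platform="synthetic"),
                      compositions, provenance)


def generate_synthetic_reference(
    cell_types: Sequence[str] = DEFAULT_CELL_TYPES,
    replicates_per_type: int = 12,
    n_probes: int = 5000,
    n_informative_per_type: int = 50,
    informative_delta: float = 0.8,
    replicate_noise_sd: float = 0.02,
    seed: int | np.random.Generator | None = None,
    shared_blocks: Mapping[str, Sequence[str]] | str | None = "auto",
    independent_extra_noise_sd: float = 0.0,
) -> LabeledReference:
    """Generate a labeled reference with planted cell-type marker CpGs.

    Design, per cell type: a disjoint block of ``n_informative_per_type``
    probes with target beta 0.9 in that type and ``0.9 - informative_delta``
    in every other type.  When ``shared_blocks`` is "auto" and at least two
    canonical immune subtypes are present, an additional pan-immune ("IC")
    block is planted, hypermethylated in all immune subtypes — leukocytes
    share pan-immune marks, and hierarchical deconvolution needs IC-vs-rest
    markers.  Background probes follow a bimodal (methylome-like) beta
    distribution confined to [0.12, 0.88], so each sample's extreme values
    sit at planted markers.  Per-replicate Gaussian jitter of
    ``replicate_noise_sd`` is added and values are clipped to [0, 1].

    Replicates are split into a panel half (source sets A, or C for the
    tumor component "TC") and an independent half (B / D); the independent
    half can carry extra jitter (``independent_extra_noise_sd``) to emulate
    between-laboratory variation.  Deterministic under ``seed``.
    """
    cell_types = list(cell_types)
    if shared_blocks == "auto":
        immune_present = [t for t in cell_types if t in IMMUNE_SUBTYPES]
        shared_blocks = {"IC": immune_present} if len(immune_present) >= 2 else {}
    shared_blocks = dict(shared_blocks or {})
    for name, members in shared_blocks.items():
        missing = set(members) - set(cell_types)
        if missing:
            raise ConfigurationError(
                f"shared block {name!r} names unknown cell types: {sorted(missing)}"
            )
    n_blocks = len(cell_types) + len(shared_blocks)
    if n_informative_per_type * n_blocks > n_probes:
        raise ConfigurationError(
            f"{n_informative_per_type} informative probes x {n_blocks} blocks "
            f"exceed n_probes={n_probes}"
        )
    if not 0 < informative_delta <= 0.9:
        raise ConfigurationError("informative_delta must be in (0, 0.9]")

    rng = np.random.default_rng(seed)
    high = 0.9
    low = high - informative_delta

    # target profile per (probe, type)
    base = np.empty((n_probes, len(cell_types)))
    n_inf = n_informative_per_type
    probe_ids = np.array([f"cg{i:07d}" for i in range(n_probes)])
    block_owner: dict[str, tuple[int, int]] = {}
    offset = 0
    for j, t in enumerate(cell_types):
        block = slice(offset, offset + n_inf)
        base[block, :] = low
        base[block, j] = high
        block_owner[t] = (offset, offset + n_inf)
        offset += n_inf
    for name, members in shared_blocks.items():
        block = slice(offset, offset + n_inf)
        base[block, :] = low
        for m in members:
            base[block, cell_types.index(m)] = high
        block_owner[name] = (offset, offset + n_inf)
        offset += n_inf
    # bimodal background, shared across types (non-informative)
    n_bg = n_probes - offset
    mode = rng.random(n_bg) < 0.5
    bg = np.where(mode, rng.beta(2, 8, size=n_bg), rng.beta(8, 2, size=n_bg))
    bg = 0.12 + 0.76 * bg
    base[offset:, :] = bg[:, None]

    # replicates with jitter; first half -> panel sets (A/C), rest -> B/D
    n_rep = replicates_per_type
    half = n_rep // 2
    columns = {}
    labels = {}
    source = {}
    for j, t in enumerate(cell_types):
        panel_set, indep_set = ("C", "D") if t == "TC" else ("A", "B")
        for r in range(n_rep):
            tag = panel_set if r < half else indep_set
            sd = replicate_noise_sd
            if r >= half:
                sd = float(np.hypot(sd, independent_extra_noise_sd))
            sid = f"{t}_{tag}{r + 1:02d}"
            col = base[:, j] + rng.normal(0.0, sd, size=n_probes)
            columns[sid] = np.clip(col, 0.0, 1.0)
            labels[sid] = t
            source[sid] = tag
    values = pd.DataFrame(columns, index=probe_ids)
    ref = LabeledReference(
        BetaMatrix(values, platform="synthetic"),
        pd.Series(labels, name="cell_type"),
        pd.Series(source, name="source_set"),
    )
    # stash planted-marker bookkeeping for tests and selection validation
    ref.planted_markers = {  # type: ignore[attr-defined]
        name: list(probe_ids[a:b]) for name, (a, b) in block_owner.items()
    }
    ref.target_profile = pd.DataFrame(  # type: ignore[attr-defined]
        base, index=probe_ids, columns=cell_types
    )
    return ref
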