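"""Computational downsampling of sequencing depth.

Sequencing depth differs between libraries, so comparisons are made after
in-silico removal of counts down to a common target depth.  Reads are
removed one at a time with probability proportional to each gene's count
representation; the default ``hypergeometric`` variant draws the removed
reads uniformly at random without replacement (one multivariate
hypergeometric draw per sample, distributionally identical to the
iterative removal with probabilities recomputed each step), while the
``fixed_probability`` variant freezes the removal probabilities at the
initial proportions, skipping genes that reach zero.

For 3'-DGE samples, every read removal from a gene also removes one of the
gene's UMIs with probability u/c (current UMI over current read count), so
downsampled read and UMI matrices stay coupled and ``umi <= reads`` always
holds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .containers import CountMatrix

log = logging.getLogger("dgecompare")

Variant = Literal["hypergeometric", "fixed_probability"]

__all__ = [
    "DownsampleResult",
    "downsample_sample",
    "downsample_paired",
    "downsample_matrix",
    "downsample_to_common_depth",
    "downsample_replicates",
]


@dataclass
class DownsampleResult:
    counts_at_depth: CountMatrix
    removed_low_expression_genes: list[str]
    target_depth: int
    seed: int
    variant: Variant


def _check_target(total: int, target_depth: int) -> None:
    if target_depth < 0:
        raise ValueError(f"target depth must be >= 0, got {target_depth}")
    if target_depth > total:
        raise ValueError(
            f"target depth {target_depth} exceeds available counts {total}"
        )


def downsample_sample(
    counts: np.ndarray,
    target_depth: int,
    variant: Variant = "hypergeometric",
    seed: int | np.random.Generator = 0,
    min_count: int = 0,
) -> np.ndarray:
    """Downsample one sample's count vector to ``target_depth`` total counts.

    Parameters
    ----------
    counts
        Non-negative integer vector (one entry per gene).
    target_depth
        Desired total count after removal; must not exceed the available
        total (after the optional low-count pre-filter).
    variant
        ``hypergeometric``: exact uniform removal of individual reads.
        ``fixed_probability``: removal probabilities frozen at the initial
        proportions, exhausted genes skipped.
    min_count
        Genes with fewer than this many counts are zeroed before removal
        (the "<4 counts" low-expression pre-filter when set to 4).

    Returns
    -------
    Integer vector with the same shape, summing to ``target_depth``, each
    entry bounded by its input value.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = np.asarray(counts)
    if counts.ndim != 1:
        raise ValueError("counts must be a 1-D vector")
    if counts.size and counts.min() < 0:
        raise ValueError("counts must be non-negative")
    counts = counts.astype(np.int64, copy=True)
    if min_count > 0:
        counts[counts < min_count] = 0
    total = int(counts.sum())
    _check_target(total, target_depth)
    if target_depth == total:
        return counts
    if target_depth == 0:
        return np.zeros_like(counts)

    if variant == "hypergeometric":
        # Keeping `target_depth` reads uniformly at random == removing the rest.
        return rng.multivariate_hypergeometric(counts, target_depth).astype(np.int64)
    if variant != "fixed_probability":
        raise ValueError(f"unknown downsampling variant {variant!r}")

    # Fixed-probability removal: probabilities frozen at initial proportions;
    # a draw landing on an exhausted gene is repeated among non-exhausted
    # genes (implemented as multinomial rounds clipped at available counts).
    p0 = counts / total
    cur = counts.copy()
    remaining = total - target_depth
    while remaining > 0:
        active = cur > 0
        p = p0[active]
        draw = rng.multinomial(remaining, p / p.sum())
        removed = np.minimum(draw, cur[active])
        cur[active] -= removed
        remaining -= int(removed.sum())
    return cur


def downsample_paired(
    reads: np.ndarray,
    umis: np.ndarray,
    target_depth: int,
    seed: int | np.random.Generator = 0,
    variant: Variant = "hypergeometric",
    fixed_ratio: bool = False,
    min_count: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Downsample a DGE sample's reads with coupled UMI removal.

    Each read removal from gene g removes one of its UMIs with probability
    u_g/c_g.  With the ratio recomputed from current counts (the default)
    this is exactly the urn process "delete one uniformly random read; u of
    the c reads carry a distinct UMI", so given r_g removed reads the number
    of removed UMIs is Hypergeometric(c_g, u_g, r_g) — drawn directly.  With
    ``fixed_ratio=True`` the ratio stays at its initial value u0/c0 and the
    removal count is Binomial(r_g, u0/c0) clipped so that 0 <= u <= c holds.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    reads = np.asarray(reads, dtype=np.int64)
    umis = np.asarray(umis, dtype=np.int64)
    if reads.shape != umis.shape:
        raise ValueError("reads and umis must have the same shape")
    if np.any(umis > reads):
        raise ValueError("umis exceed reads for at least one gene")
    if np.any(umis < 0):
        raise ValueError("umis must be non-negative")

    new_reads = downsample_sample(reads, target_depth, variant=variant, seed=rng,
                                  min_count=min_count)
    # Genes zeroed by the pre-filter lose their UMIs as well.
    base_reads = reads.copy()
    if min_count > 0:
        filtered = reads < min_count
        base_reads[filtered] = 0
    removed = base_reads - new_reads
    umis_eff = np.minimum(umis, base_reads)

    if fixed_ratio:
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = np.where(base_reads > 0, umis_eff / np.maximum(base_reads, 1), 0.0)
        umi_removed = rng.binomial(removed, ratio)
        new_umis = umis_eff - umi_removed
        new_umis = np.clip(new_umis, np.maximum(0, umis_eff - removed), None)
        new_umis = np.minimum(new_umis, new_reads)
    else:
        umi_removed = np.zeros_like(reads)
        mask = removed > 0
        if mask.any():
            umi_removed[mask] = rng.hypergeometric(
                umis_eff[mask], base_reads[mask] - umis_eff[mask], removed[mask]
            )
        new_umis = umis_eff - umi_removed
    return new_reads, new_umis


def downsample_matrix(
    matrix: CountMatrix,
    target_depth: int,
    variant: Variant = "hypergeometric",
    seed: int = 0,
    min_count: int = 4,
    summed_filter: bool = False,
) -> DownsampleResult:
    """Downsample every sample of a matrix to the same target depth.

    The low-expression pre-filter (< ``min_count`` counts) is applied per
    sample by default; with ``summed_filter=True`` it is applied to counts
    summed across samples instead.  Columns whose (post-filter) total is
    already below the target are left unchanged.
    """
    rng = np.random.default_rng(seed)
    out = np.empty_like(matrix.counts)
    removed_union: set[str] = set()
    gene_arr = np.asarray(matrix.gene_ids)
    counts = matrix.counts
    if summed_filter and min_count > 0:
        keep = counts.sum(axis=1) >= min_count
        removed_union.update(gene_arr[~keep])
        counts = np.where(keep[:, None], counts, 0)
        per_sample_min = 0
    else:
        per_sample_min = min_count
    for j in range(matrix.n_samples):
        col = counts[:, j].copy()
        if per_sample_min > 0:
            low = (col > 0) & (col < per_sample_min)
            removed_union.update(gene_arr[low])
            col[low] = 0
        avail = int(col.sum())
        tgt = min(target_depth, avail)
        out[:, j] = downsample_sample(col, tgt, variant=variant, seed=rng)
    result = CountMatrix(matrix.gene_ids, matrix.samples, out, matrix.unit)
    log.info(
        "downsampled %d samples to depth %d (%s); %d low-expression genes removed",
        matrix.n_samples, target_depth, variant, len(removed_union),
    )
    return DownsampleResult(
        counts_at_depth=result,
        removed_low_expression_genes=sorted(removed_union),
        target_depth=target_depth,
        seed=seed if isinstance(seed, int) else -1,
        variant=variant,
    )


def downsample_to_common_depth(
    matrices: Sequence[CountMatrix],
    seed: int = 0,
    variant: Variant = "hypergeometric",
    min_count: int = 4,
) -> list[DownsampleResult]:
    """Downsample every sample of every matrix to the global minimum depth.

    The common depth is the smallest per-sample column sum across all the
    matrices (computed before the low-count pre-filter; post-filter columns
    smaller than the target are kept at their available total).
    """
    if not matrices:
        raise ValueError("need at least one matrix")
    common = int(min(int(m.column_sums().min()) for m in matrices))
    log.info("common depth across %d matrices: %d", len(matrices), common)
    return [
        downsample_matrix(m, common, variant=variant, seed=seed + i, min_count=min_count)
        for i, m in enumerate(matrices)
    ]


def downsample_replicates(
    matrix: CountMatrix,
    target_depth: int,
    n_reps: int = 16,
    seed: int = 0,
    detection_threshold: int = 4,
    variant: Variant = "hypergeometric",
) -> dict:
    """Repeat stochastic downsampling and summarize replicate variability.

    Returns per-sample detected-gene counts for each of ``n_reps``
    independent downsampling replicates together with their coefficient of
    variation, to verify that the stochastic removal contributes negligible
    variability.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    detected = np.zeros((n_reps, matrix.n_samples), dtype=np.int64)
    for r in range(n_reps):
        res = downsample_matrix(matrix, target_depth, variant=variant,
                                seed=seed + r, min_count=0)
        detected[r] = (res.counts_at_depth.counts >= detection_threshold).sum(axis=0)
    means = detected.mean(axis=0)
    sds = detected.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cvs = np.where(means > 0, sds / means, 0.0)
    return {
        "sample_ids": matrix.sample_ids,
        "detected": detected,
        "mean_detected": means,
        "cv_detected": cvs,
        "n_reps": n_reps,
        "target_depth": target_depth,
    }
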