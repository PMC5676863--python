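"""Gene-detection sensitivity as a function of sequencing depth.

A gene counts as "detected" in a sample when it has at least a threshold
number of counts (default 4).  Progressive in-silico downsampling produces
detection-saturation curves, which are summarized by a Michaelis-Menten
model G(d) = Vmax * d / (Km + d): Vmax is the asymptotic number of
detectable genes and Km the depth at half-saturation.  The module also
partitions detected genes between methods at matched depth and profiles
per-gene alignment fidelity (fraction of a gene's reads aligning uniquely
to it).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .containers import CountMatrix
from .downsample import Variant, downsample_sample

log = logging.getLogger("dgecompare")

__all__ = [
    "DetectionCurve",
    "MMFit",
    "FidelityProfile",
    "count_detected",
    "detection_curve",
    "average_detection_curves",
    "fit_michaelis_menten",
    "differential_detection",
    "alignment_fidelity",
]


@dataclass
class DetectionCurve:
    depths: np.ndarray
    detected: np.ndarray
    threshold: int
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths)
        self.detected = np.asarray(self.detected, dtype=float)
        if self.depths.shape != self.detected.shape:
            raise ValueError("depths and detected must have equal length")
        if np.any(np.diff(self.depths) < 0):
            raise ValueError("depths must be nondecreasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"depth": self.depths, "detected": self.detected,
             "sample_id": self.sample_id}
        )


@dataclass
class MMFit:
    vmax: float
    km: float
    rss: float
    converged: bool
    message: str = ""

    def predict(self, depth: np.ndarray) -> np.ndarray:
        depth = np.asarray(depth, dtype=float)
        return self.vmax * depth / (self.km + depth)


@dataclass
class FidelityProfile:
    gene_ids: list[str]
    unique_proportion: np.ndarray
    unquantifiable_genes: set[str]
    min_total_reads: int
    cutoff: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "unique_proportion": self.unique_proportion,
                "unquantifiable": [g in self.unquantifiable_genes for g in self.gene_ids],
            }
        )


def count_detected(counts: np.ndarray, threshold: int = 4) -> int:
    """Number of genes with at least ``threshold`` counts."""
    if threshold < 1:
        raise ValueError("detection threshold must be >= 1")
    return int((np.asarray(counts) >= threshold).sum())


def default_depth_grid(full_depth: int, n_points: int = 30, low: int = 10_000) -> np.ndarray:
    """Logarithmically spaced depth grid from ``low`` to the sample depth."""
    low = min(low, full_depth)
    grid = np.unique(np.round(np.geomspace(max(low, 1), full_depth, n_points)).astype(np.int64))
    return grid


def detection_curve(
    sample: np.ndarray,
    depth_grid: np.ndarray,
    threshold: int = 4,
    seed: int | np.random.Generator = 0,
    variant: Variant = "hypergeometric",
    sample_id: str = "",
) -> DetectionCurve:
    """Detected-gene count after downsampling a sample to each grid depth."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sample = np.asarray(sample, dtype=np.int64)
    total = int(sample.sum())
    depth_grid = np.sort(np.asarray(depth_grid, dtype=np.int64))
    if depth_grid.size and depth_grid[-1] > total:
        raise ValueError("depth grid exceeds the sample's depth")
    detected = np.empty(depth_grid.size, dtype=float)
    for i, d in enumerate(depth_grid):
        sub = downsample_sample(sample, int(d), variant=variant, seed=rng)
        detected[i] = count_detected(sub, threshold)
    return DetectionCurve(depth_grid, detected, threshold, sample_id)


def average_detection_curves(curves: list[DetectionCurve]) -> DetectionCurve:
    """Pointwise average of curves sharing the same depth grid."""
    if not curves:
        raise ValueError("no curves to average")
    depths = curves[0].depths
    for c in curves[1:]:
        if not np.array_equal(c.depths, depths):
            raise ValueError("curves must share the same depth grid")
    mean = np.mean([c.detected for c in curves], axis=0)
    return DetectionCurve(depths, mean, curves[0].threshold, sample_id="average")


def fit_michaelis_menten(curve: DetectionCurve) -> MMFit:
    """Nonlinear least-squares fit of G(d) = Vmax d / (Km + d).

    Initialization: Vmax0 = max observed detection; Km0 = smallest grid
    depth whose detection reaches Vmax0 / 2 (robust for hyperbolic data).
    Non-convergence is reported through ``converged=False`` rather than an
    exception.
    """
    d = np.asarray(curve.depths, dtype=float)
    g = np.asarray(curve.detected, dtype=float)
    if np.unique(d).size < 3:
        raise ValueError("need at least 3 distinct depths to fit")
    vmax0 = float(g.max())
    if vmax0 <= 0:
        return MMFit(0.0, 0.0, float(np.sum(g**2)), False, "all detections are zero")
    above = d[g >= vmax0 / 2]
    km0 = float(above.min()) if above.size else float(np.median(d))

    def mm(x: np.ndarray, vmax: float, km: float) -> np.ndarray:
        return vmax * x / (km + x)

    try:
        popt, _ = curve_fit(
            mm, d, g, p0=[vmax0, max(km0, 1.0)],
            bounds=([0.0, 0.0], [np.inf, np.inf]), maxfev=10_000,
        )
    except RuntimeError as exc:  # no convergence
        return MMFit(vmax0, km0, float(np.sum((g - mm(d, vmax0, km0)) ** 2)), False, str(exc))
    rss = float(np.sum((g - mm(d, *popt)) ** 2))
    return MMFit(float(popt[0]), float(popt[1]), rss, True)


def _group_detected(
    matrix: CountMatrix, threshold: int, min_fraction: float
) -> set[str]:
    """Genes detected in at least ``min_fraction`` of the matrix's samples."""
    hits = (matrix.counts >= threshold).sum(axis=1)
    need = max(1, int(np.ceil(min_fraction * matrix.n_samples)))
    genes = np.asarray(matrix.gene_ids)
    return set(genes[hits >= need])


def differential_detection(
    conv: CountMatrix,
    dge: CountMatrix,
    threshold: int = 4,
    min_fraction: float = 0.5,
) -> dict:
    """Partition detected genes between methods, per treatment.

    Both matrices must share the gene universe and sit at a common depth.
    For each treatment, a gene is "detected" by a method when it passes the
    count threshold in at least ``min_fraction`` of that group's replicates.
    Returns per-treatment conv-only / dge-only / shared sets plus the
    intersections of the method-only sets across treatments (the consistency
    check that differential detection is treatment-independent).
    """
    if conv.gene_ids != dge.gene_ids:
        raise ValueError("matrices must share an identical gene universe")
    treatments = sorted({s.treatment for s in conv.samples} | {s.treatment for s in dge.samples})
    per_treatment: dict[str, dict[str, set[str]]] = {}
    for t in treatments:
        c = _group_detected(conv.select(treatment=t), threshold, min_fraction)
        d = _group_detected(dge.select(treatment=t), threshold, min_fraction)
        per_treatment[t] = {
            "conv_only": c - d,
            "dge_only": d - c,
            "shared": c & d,
        }
    conv_only_all = set.intersection(*(per_treatment[t]["conv_only"] for t in treatments))
    dge_only_all = set.intersection(*(per_treatment[t]["dge_only"] for t in treatments))
    return {
        "per_treatment": per_treatment,
        "conv_only_all_treatments": conv_only_all,
        "dge_only_all_treatments": dge_only_all,
    }


def alignment_fidelity(
    unique_reads: np.ndarray,
    total_reads: np.ndarray,
    gene_ids: list[str] | None = None,
    min_total: int = 4,
    cutoff: float = 0.10,
) -> FidelityProfile:
    """Per-gene unique-alignment proportion and the unquantifiable-gene set.

    Only genes with ``total_reads >= min_total`` are profiled; those whose
    unique proportion falls below ``cutoff`` cannot be reliably quantified
    from 3'-end tags and are flagged.
    """
    unique = np.asarray(unique_reads, dtype=np.int64)
    total = np.asarray(total_reads, dtype=np.int64)
    if unique.shape != total.shape:
        raise ValueError("unique and total vectors must have equal length")
    if np.any(unique > total):
        raise ValueError("unique reads exceed total reads for at least one gene")
    if min_total < 1:
        raise ValueError("min_total must be >= 1")
    if gene_ids is None:
        gene_ids = [f"G{i:05d}" for i in range(unique.size)]
    keep = total >= min_total
    genes = [g for g, k in zip(gene_ids, keep) if k]
    prop = unique[keep] / total[keep]
    flagged = {g for g, p in zip(genes, prop) if p < cutoff}
    log.info(
        "alignment fidelity: %d/%d genes profiled, %d unquantifiable (<%.2f)",
        keep.sum(), keep.size, len(flagged), cutoff,
    )
    return FidelityProfile(genes, prop, flagged, min_total, cutoff)
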