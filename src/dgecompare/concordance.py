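"""Quantitative cross-method comparison at matched sequencing depth.

Conventional random-primed read counts scale with transcript length; UMI
counts do not.  Dividing conventional counts by mean transcript length (kb)
puts the two technologies on comparable footing, after which per-sample
scaling to a fixed total (CPM-style) and a log2(x+1) transform make
scatterplots and Pearson correlations meaningful.  A band parallel to
x = y, k standard deviations of the cross-method log-residual wide, flags
genes with evidence of method-specific quantification bias.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CountMatrix, CountUnit, GeneTable, NormalizedMatrix

log = logging.getLogger("dgecompare")

__all__ = [
    "BiasReport",
    "length_normalize",
    "cpm_rescale",
    "scale_comparable",
    "correlation_matrix",
    "cross_method_concordance",
    "flag_bias",
]

CPM_TOTAL = 1e6


@dataclass
class BiasReport:
    gene_ids: list[str]
    conv_mean: np.ndarray       # log2 scale
    dge_mean: np.ndarray        # log2 scale
    residual: np.ndarray        # dge - conv
    band_halfwidth: float       # log2 units
    dge_biased_genes: set[str]
    conv_biased_genes: set[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "conv_mean_log2": self.conv_mean,
                "dge_mean_log2": self.dge_mean,
                "residual": self.residual,
                "dge_biased": [g in self.dge_biased_genes for g in self.gene_ids],
                "conv_biased": [g in self.conv_biased_genes for g in self.gene_ids],
            }
        )


def length_normalize(
    matrix: CountMatrix, genes: GeneTable, force: bool = False
) -> NormalizedMatrix:
    """Divide counts by mean transcript length in kilobases.

    Refuses UMI matrices unless ``force=True``: UMI counts are
    length-independent by construction, so length normalization would
    *introduce* a length artifact rather than remove one.
    """
    if matrix.unit == CountUnit.UMI and not force:
        raise ValueError(
            "refusing to length-normalize a UMI count matrix (UMI counts are "
            "length-independent); pass force=True to override"
        )
    missing = [g for g in matrix.gene_ids if g not in genes.lengths.index]
    if missing:
        raise ValueError(f"no transcript length for gene {missing[0]!r}")
    kb = genes.lengths.loc[matrix.gene_ids].to_numpy() / 1000.0
    values = matrix.counts / kb[:, None]
    return NormalizedMatrix(
        list(matrix.gene_ids),
        list(matrix.samples),
        values,
        normalization="length",
        scale_note="counts per kb of mean transcript length",
    )


def as_normalized(matrix: CountMatrix) -> NormalizedMatrix:
    """Wrap raw counts as an (un-normalized) real-valued matrix."""
    return NormalizedMatrix(
        list(matrix.gene_ids), list(matrix.samples),
        matrix.counts.astype(float), normalization="none",
        scale_note=f"raw {matrix.unit.value} counts",
    )


def cpm_rescale(values: np.ndarray, total: float = CPM_TOTAL) -> np.ndarray:
    """Rescale each column to sum to ``total`` (idempotent projection)."""
    values = np.asarray(values, dtype=float)
    sums = values.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(sums > 0, values / sums * total, 0.0)
    return out


def scale_comparable(
    a: NormalizedMatrix, b: NormalizedMatrix, log: bool = True
) -> tuple[NormalizedMatrix, NormalizedMatrix]:
    """Put two matrices on a comparable unit scale.

    Each sample is rescaled to a fixed total of 10^6 (the rescale step is
    idempotent), then log2(x+1)-transformed for correlation and scatter
    use.  Requires a matched gene universe.
    """
    if a.gene_ids != b.gene_ids:
        raise ValueError("matrices must share an identical gene universe")

    def _one(m: NormalizedMatrix) -> NormalizedMatrix:
        v = cpm_rescale(m.values)
        note = "per-sample total scaled to 1e6"
        if log:
            v = np.log2(v + 1.0)
            note += ", log2(x+1)"
        return NormalizedMatrix(
            list(m.gene_ids), list(m.samples), v,
            normalization=m.normalization + "+depth", scale_note=note,
        )

    return _one(a), _one(b)


def correlation_matrix(values: NormalizedMatrix) -> pd.DataFrame:
    """Symmetric Pearson correlation matrix across samples.

    Zero-variance samples yield NaN against every other sample (reported
    as missing, not an error); the diagonal is 1 by definition.
    """
    if len(values.samples) < 2:
        raise ValueError("need at least 2 samples")
    v = values.values
    sd = v.std(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        r = np.corrcoef(v, rowvar=False)
    r[sd == 0, :] = np.nan
    r[:, sd == 0] = np.nan
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=values.sample_ids, columns=values.sample_ids)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    return float(np.corrcoef(x, y)[0, 1])


def cross_method_concordance(
    conv: CountMatrix,
    dge: CountMatrix,
    genes: GeneTable,
    pairing: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per-pair Pearson r between methods, with and without length normalization.

    ``pairing`` maps conventional sample ids to DGE sample ids measuring the
    same biological sample; by default samples are paired by (treatment,
    replicate).  Unpaired samples are excluded with a warning.  Returns a
    DataFrame with columns conv_sample, dge_sample, r_raw, r_length_norm.
    """
    if conv.gene_ids != dge.gene_ids:
        raise ValueError("matrices must share an identical gene universe")
    if pairing is None:
        by_key = {(s.treatment, s.replicate): s.sample_id for s in dge.samples}
        pairing = {}
        for s in conv.samples:
            key = (s.treatment, s.replicate)
            if key in by_key:
                pairing[s.sample_id] = by_key[key]
            else:
                log.warning("conventional sample %s has no DGE pair; excluded", s.sample_id)

    raw_a, raw_b = scale_comparable(as_normalized(conv), as_normalized(dge))
    ln_a, ln_b = scale_comparable(length_normalize(conv, genes), as_normalized(dge))

    conv_pos = {s: j for j, s in enumerate(conv.sample_ids)}
    dge_pos = {s: j for j, s in enumerate(dge.sample_ids)}
    rows = []
    for cs, ds in pairing.items():
        if cs not in conv_pos or ds not in dge_pos:
            log.warning("pair (%s, %s) not present in the matrices; excluded", cs, ds)
            continue
        i, j = conv_pos[cs], dge_pos[ds]
        rows.append(
            {
                "conv_sample": cs,
                "dge_sample": ds,
                "r_raw": _pearson(raw_a.values[:, i], raw_b.values[:, j]),
                "r_length_norm": _pearson(ln_a.values[:, i], ln_b.values[:, j]),
            }
        )
    return pd.DataFrame(rows)


def flag_bias(
    conv_means: np.ndarray,
    dge_means: np.ndarray,
    gene_ids: list[str] | None = None,
    k: float = 2.0,
) -> BiasReport:
    """Flag genes outside a band parallel to x = y on the mean-vs-mean plot.

    ``conv_means`` and ``dge_means`` are per-gene means across all
    depth-matched samples on the comparable log2 scale.  The residual
    d_g = dge_g - conv_g is compared against a half-width of k * SD(d)
    (default k = 2, covering the typical variance): genes above the band
    are dge-biased, below are conv-biased.
    """
    conv_means = np.asarray(conv_means, dtype=float)
    dge_means = np.asarray(dge_means, dtype=float)
    if conv_means.shape != dge_means.shape:
        raise ValueError("mean vectors must have equal length")
    if conv_means.size < 10:
        raise ValueError("need at least 10 genes for a stable band width")
    if gene_ids is None:
        gene_ids = [f"G{i:05d}" for i in range(conv_means.size)]
    resid = dge_means - conv_means
    halfwidth = k * float(resid.std(ddof=1))
    genes = np.asarray(gene_ids)
    dge_biased = set(genes[resid > halfwidth])
    conv_biased = set(genes[resid < -halfwidth])
    log.info(
        "bias band halfwidth %.4f log2 units: %d dge-biased, %d conv-biased of %d genes",
        halfwidth, len(dge_biased), len(conv_biased), conv_means.size,
    )
    return BiasReport(
        gene_ids=list(gene_ids),
        conv_mean=conv_means,
        dge_mean=dge_means,
        residual=resid,
        band_halfwidth=halfwidth,
        dge_biased_genes=dge_biased,
        conv_biased_genes=conv_biased,
    )
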