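"""Synthetic paired conventional / 3'-DGE count data with known ground truth.

The generator emulates the structure of a paired benchmarking experiment in
which the same RNA samples are split between a conventional random-primed
library (quantified by read counts, which scale with transcript length) and
a 3'-end UMI-counted library (quantified by UMI counts, length-independent,
with read counts inflated above UMI counts by PCR amplification).  Defaults
mirror the study design the analyses assume: ~22,000 genes, 8 control + 4
"large-effect" treated + 4 "no-effect" treated samples per arm, library
sizes of a few million counts, and a dataset-wide reads-per-UMI ratio of
about 2-3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CountMatrix, CountUnit, GeneTable, Method, SampleMeta

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "generate_gene_table",
    "simulate_paired_experiment",
    "simulate_alignment_fidelity",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the paired-experiment generator.

    Attributes
    ----------
    n_genes
        Number of genes in the shared universe.
    n_control, n_treated
        Biological replicates in the control and treated groups.
    library_size_mean, library_size_cv
        Mean and coefficient of variation of per-sample library size
        (total counts; log-normal across samples).
    dispersion
        Negative-binomial dispersion phi (variance = mu + phi * mu^2);
        0 gives Poisson counts.
    n_de_genes
        Number of genes with a true treatment effect.
    de_log2fc_mean, de_log2fc_sd
        Mean and log-scale spread of the absolute log2 fold-change of DE
        genes; magnitudes are drawn log-normally with expectation exactly
        ``de_log2fc_mean`` and signs are random.  ``de_log2fc_sd=0`` gives
        every DE gene magnitude ``de_log2fc_mean``.
    amplification_ratio_range
        Per-gene expected reads per UMI, drawn uniformly from this interval
        (must lie within [1, inf)).
    length_lognormal_params
        (log-mean, log-sd) of mean transcript length in bp.
    baseline_lognormal_sd
        Log-sd of the heavy-tailed baseline expression distribution.
    detection_dropout
        Probability that a low-abundance gene fails reverse transcription
        in the DGE arm (zeroed in every DGE sample).
    dropout_quantile
        Abundance quantile below which genes are eligible for dropout.
    conv_length_bias
        If True (the realistic default), conventional expected read counts
        scale with transcript length; set False for negative controls.
    exact_library_sizes
        Force column sums to the drawn library sizes by multinomial
        rescaling.
    seed
        Base seed for all randomness.
    """

    n_genes: int = 22_000
    n_control: int = 8
    n_treated: int = 4
    library_size_mean: float = 3.5e6
    library_size_cv: float = 0.15
    dispersion: float = 0.1
    n_de_genes: int = 3000
    de_log2fc_mean: float = 1.0
    de_log2fc_sd: float = 0.4
    amplification_ratio_range: tuple[float, float] = (2.0, 3.0)
    length_lognormal_params: tuple[float, float] = (7.6, 0.7)
    baseline_lognormal_sd: float = 1.5
    detection_dropout: float = 0.3
    dropout_quantile: float = 0.5
    conv_length_bias: bool = True
    exact_library_sizes: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.n_control < 1 or self.n_treated < 0:
            raise ValueError("replicate counts invalid")
        if not 0 <= self.n_de_genes <= self.n_genes:
            raise ValueError("n_de_genes must lie in [0, n_genes]")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        lo, hi = self.amplification_ratio_range
        if lo < 1 or hi < lo:
            raise ValueError("amplification ratio range must lie within [1, inf)")
        if not 0 <= self.detection_dropout <= 1:
            raise ValueError("detection_dropout must be a probability")
        if not 0 <= self.dropout_quantile <= 1:
            raise ValueError("dropout_quantile must lie in [0, 1]")
        if self.library_size_mean <= 0 or self.library_size_cv < 0:
            raise ValueError("library size parameters invalid")


@dataclass
class SyntheticTruth:
    """Per-gene ground truth of a simulated experiment."""

    gene_ids: list[str]
    baseline_mean: np.ndarray        # arbitrary abundance units
    transcript_length: np.ndarray    # bp
    amplification_ratio: np.ndarray  # expected reads per UMI, >= 1
    is_de: np.ndarray                # bool
    true_log2fc: np.ndarray          # 0 where not DE
    dge_dropout: np.ndarray          # bool: gene zeroed in the DGE arm

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "baseline_mean": self.baseline_mean,
                "transcript_length": self.transcript_length,
                "amplification_ratio": self.amplification_ratio,
                "is_de": self.is_de.astype(int),
                "true_log2fc": self.true_log2fc,
                "dge_dropout": self.dge_dropout.astype(int),
            }
        )


def generate_gene_table(config: SimulationConfig) -> tuple[GeneTable, SyntheticTruth]:
    """Draw per-gene ground truth: lengths, baseline means, DE effects.

    Transcript lengths are log-normal; baseline expression is heavy-tailed
    log-normal; DE genes are a uniform random subset; effect magnitudes are
    log-normal with expectation ``de_log2fc_mean`` and random sign.
    Deterministic given the config seed.
    """
    rng = np.random.default_rng(config.seed)
    gene_ids = [f"G{i:05d}" for i in range(config.n_genes)]
    mu_len, sd_len = config.length_lognormal_params
    lengths = rng.lognormal(mu_len, sd_len, config.n_genes)
    baseline = rng.lognormal(0.0, config.baseline_lognormal_sd, config.n_genes)

    is_de = np.zeros(config.n_genes, dtype=bool)
    lfc = np.zeros(config.n_genes)
    if config.n_de_genes > 0:
        de_idx = rng.choice(config.n_genes, size=config.n_de_genes, replace=False)
        is_de[de_idx] = True
        sd = config.de_log2fc_sd
        if sd > 0:
            # log-normal with mean exactly de_log2fc_mean
            mag = config.de_log2fc_mean * rng.lognormal(-0.5 * sd**2, sd, config.n_de_genes)
        else:
            mag = np.full(config.n_de_genes, config.de_log2fc_mean)
        sign = rng.choice([-1.0, 1.0], size=config.n_de_genes)
        lfc[de_idx] = sign * mag

    dropout = np.zeros(config.n_genes, dtype=bool)
    if config.detection_dropout > 0 and config.dropout_quantile > 0:
        cut = np.quantile(baseline, config.dropout_quantile)
        eligible = baseline <= cut
        dropout = eligible & (rng.random(config.n_genes) < config.detection_dropout)

    amp = rng.uniform(*config.amplification_ratio_range, config.n_genes)
    truth = SyntheticTruth(
        gene_ids=gene_ids,
        baseline_mean=baseline,
        transcript_length=lengths,
        amplification_ratio=amp,
        is_de=is_de,
        true_log2fc=lfc,
        dge_dropout=dropout,
    )
    return GeneTable(pd.Series(lengths, index=gene_ids)), truth


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    """NB(mu, variance mu + phi mu^2) counts; Poisson when phi == 0."""
    mean = np.maximum(mean, 0.0)
    if phi == 0:
        return rng.poisson(mean)
    shape = 1.0 / phi
    lam = rng.gamma(shape, scale=mean * phi)
    return rng.poisson(lam)


def _force_library_size(rng: np.random.Generator, counts: np.ndarray, target: int) -> np.ndarray:
    """Rescale a count vector to an exact total by multinomial resampling."""
    total = counts.sum()
    if total == 0:
        return counts
    return rng.multinomial(target, counts / total)


def simulate_paired_experiment(
    config: SimulationConfig,
    truth: SyntheticTruth | None = None,
) -> tuple[CountMatrix, CountMatrix, CountMatrix, SyntheticTruth]:
    """Simulate one treatment contrast measured by both technologies.

    Returns ``(conv_reads, dge_reads, dge_umis, truth)`` for
    ``n_control`` control and ``n_treated`` treated samples per arm.
    Expected conventional read counts are proportional to abundance x
    transcript length (unless ``conv_length_bias`` is off); expected DGE UMI
    counts are proportional to abundance with per-gene dropout for
    low-abundance genes; DGE read counts add per-molecule PCR amplification
    on top of the UMI counts (support >= 1 per molecule, so reads >= umis
    in every cell).
    """
    if truth is None:
        _, truth = generate_gene_table(config)
    rng = np.random.default_rng(config.seed + 1)
    G = config.n_genes
    n_ctl, n_trt = config.n_control, config.n_treated
    n = n_ctl + n_trt
    treatments = ["CTRL"] * n_ctl + ["TRT"] * n_trt

    abundance = np.empty((G, n))
    for j in range(n):
        eff = truth.baseline_mean * (
            2.0 ** truth.true_log2fc if treatments[j] != "CTRL" else 1.0
        )
        abundance[:, j] = eff

    conv_weight = abundance * (
        truth.transcript_length[:, None] if config.conv_length_bias else 1.0
    )
    dge_weight = abundance.copy()
    dge_weight[truth.dge_dropout, :] = 0.0

    sigma = np.sqrt(np.log1p(config.library_size_cv**2))
    lib_conv = rng.lognormal(np.log(config.library_size_mean) - sigma**2 / 2, sigma, n)
    lib_dge = rng.lognormal(np.log(config.library_size_mean) - sigma**2 / 2, sigma, n)
    mean_amp = truth.amplification_ratio.mean()

    conv = np.empty((G, n), dtype=np.int64)
    umis = np.empty((G, n), dtype=np.int64)
    reads = np.empty((G, n), dtype=np.int64)
    for j in range(n):
        # conventional arm: NB reads at the target depth
        mu = conv_weight[:, j] / conv_weight[:, j].sum() * lib_conv[j]
        y = _nb_draw(rng, mu, config.dispersion)
        if config.exact_library_sizes:
            y = _force_library_size(rng, y, int(round(lib_conv[j])))
        conv[:, j] = y

        # DGE arm: UMI molecules at a depth such that reads ~ library size
        umi_target = lib_dge[j] / mean_amp
        w = dge_weight[:, j]
        mu_u = w / w.sum() * umi_target
        u = _nb_draw(rng, mu_u, config.dispersion)
        if config.exact_library_sizes:
            u = _force_library_size(rng, u, int(round(umi_target)))
        # per-molecule amplification: shifted Poisson with mean amp_g
        # (each UMI contributes >= 1 read), so reads >= umis always.
        extra = rng.poisson(u * (truth.amplification_ratio - 1.0))
        umis[:, j] = u
        reads[:, j] = u + extra

    def _samples(method: Method, prefix: str) -> list[SampleMeta]:
        out = []
        rep = {"CTRL": 0, "TRT": 0}
        for t in treatments:
            rep[t] += 1
            out.append(SampleMeta(f"{prefix}_{t}_{rep[t]}", method, t, rep[t]))
        return out

    conv_samples = _samples(Method.CONVENTIONAL, "Conv")
    dge_samples = _samples(Method.DGE, "DGE")
    return (
        CountMatrix(truth.gene_ids, conv_samples, conv, CountUnit.READ),
        CountMatrix(truth.gene_ids, dge_samples, reads, CountUnit.READ),
        CountMatrix(truth.gene_ids, dge_samples, umis, CountUnit.UMI),
        truth,
    )


def simulate_alignment_fidelity(
    config: SimulationConfig,
    fraction_low: float = 0.05,
    mean_total: float = 200.0,
) -> pd.DataFrame:
    """Simulate per-gene (unique_reads, total_reads) alignment tallies.

    A small fraction of genes (3'-end sequence shared with other genes)
    align mostly non-uniquely: their unique proportion is drawn below 0.10.
    The rest align almost entirely uniquely (proportion above 0.95),
    mimicking the strongly bimodal distribution seen in real tag data.
    Returns a DataFrame with columns gene_id, unique_reads, total_reads,
    is_low (truth flag).
    """
    if not 0 <= fraction_low <= 1:
        raise ValueError("fraction_low must be a probability")
    rng = np.random.default_rng(config.seed + 2)
    G = config.n_genes
    gene_ids = [f"G{i:05d}" for i in range(G)]
    low = rng.random(G) < fraction_low
    prop = np.where(
        low,
        rng.uniform(0.0, 0.08, G),
        rng.uniform(0.96, 1.0, G),
    )
    total = rng.poisson(rng.lognormal(np.log(mean_total), 1.0, G)) + 4
    unique = rng.binomial(total, prop)
    # keep realized proportions inside the contract bands (binomial noise can
    # cross them for small totals): high genes stay > 0.95, low genes < 0.10
    hi_floor = np.floor(0.95 * total).astype(np.int64) + 1
    lo_ceil = np.maximum(np.ceil(0.10 * total).astype(np.int64) - 1, 0)
    unique = np.where(low, np.minimum(unique, lo_ceil), np.maximum(unique, hi_floor))
    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            "unique_reads": unique,
            "total_reads": total,
            "is_low": low.astype(int),
        }
    )
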