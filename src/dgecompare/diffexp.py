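"""Classic negative-binomial differential-expression stack.

Re-implements the pairwise-comparison pipeline popularized by edgeR:
trimmed-mean-of-M-values (TMM) between-sample normalization, quantile
adjustment of counts to a common library size, conditional maximum
(quantile-adjusted) likelihood estimation of the NB dispersion (common and
tagwise with empirical-Bayes shrinkage), the conditional NB exact test for
a two-group comparison, and Benjamini-Hochberg FDR control.  The NB model
uses the mean/dispersion parameterization variance = mu + phi * mu^2.

The implementation here is self-contained (edgeR is used only as an
independent cross-check in the test suite); small numeric differences from
edgeR can arise from the interpolation used in the quantile adjustment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln
from scipy.stats import nbinom, poisson, rankdata
from statsmodels.stats.multitest import multipletests

from .containers import CountMatrix
from .downsample import downsample_matrix

log = logging.getLogger("dgecompare")

__all__ = [
    "DEResult",
    "DispersionEstimate",
    "tmm_factors",
    "equalize_lib_sizes",
    "estimate_dispersion",
    "nb_exact_test",
    "bh_fdr",
    "run_de",
    "degs_vs_depth",
]

_MIN_PHI = 1e-6


@dataclass
class DispersionEstimate:
    common_dispersion: float
    tagwise: np.ndarray | None = None

    def per_gene(self, n_genes: int) -> np.ndarray:
        if self.tagwise is not None:
            return self.tagwise
        return np.full(n_genes, self.common_dispersion)


@dataclass
class DEResult:
    table: pd.DataFrame  # gene_id, log_cpm, log2fc, p_value, fdr
    contrast: tuple[str, str]  # (treatment, control)
    fdr_cutoff: float
    n_deg_at_cutoff: int
    dispersion: DispersionEstimate

    @property
    def deg_genes(self) -> list[str]:
        t = self.table
        return list(t.loc[t["fdr"] < self.fdr_cutoff, "gene_id"])


# ---------------------------------------------------------------------------
# TMM normalization
# ---------------------------------------------------------------------------

def tmm_factors(
    counts: np.ndarray | CountMatrix,
    reference: int | str = "auto",
    trim_m: float = 0.3,
    trim_a: float = 0.05,
) -> np.ndarray:
    """Trimmed-mean-of-M-values scaling factors, geometric mean 1.

    For each sample against a reference sample, library-size-adjusted
    log2-ratios (M) and average log2 abundances (A) are computed over genes
    positive in both; the M values are trimmed 30% on each side and the A
    values 5%, and the factor is 2 to the precision-weighted mean of the
    surviving M values (weights = inverse asymptotic variances).
    """
    if isinstance(counts, CountMatrix):
        counts = counts.counts
    y = np.asarray(counts, dtype=float)
    lib = y.sum(axis=0)
    if np.any(lib == 0):
        raise ValueError("a sample has all-zero counts; cannot normalize")
    n = y.shape[1]
    if n < 2:
        raise ValueError("need at least 2 samples for TMM")

    if reference == "auto":
        f75 = np.quantile(y / lib, 0.75, axis=0)
        ref = int(np.argmin(np.abs(f75 - f75.mean())))
    else:
        ref = int(reference)

    factors = np.ones(n)
    yr, nr = y[:, ref], lib[ref]
    for k in range(n):
        if k == ref:
            continue
        yk, nk = y[:, k], lib[k]
        ok = (yk > 0) & (yr > 0)
        if not ok.any():
            continue
        pk, pr = yk[ok] / nk, yr[ok] / nr
        m = np.log2(pk / pr)
        a = 0.5 * np.log2(pk * pr)
        w = (nk - yk[ok]) / (nk * yk[ok]) + (nr - yr[ok]) / (nr * yr[ok])
        if np.allclose(m, m[0], atol=1e-10):
            factors[k] = 2 ** m[0]
            continue
        ng = m.size
        lo_m, hi_m = np.floor(ng * trim_m) + 1, ng + 1 - np.floor(ng * trim_m)
        lo_a, hi_a = np.floor(ng * trim_a) + 1, ng + 1 - np.floor(ng * trim_a)
        rm, ra = rankdata(m), rankdata(a)
        keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        if not keep.any() or w[keep].sum() == 0:
            factors[k] = 1.0
            continue
        factors[k] = 2 ** (np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep]))
    factors /= np.exp(np.mean(np.log(factors)))
    return factors


# ---------------------------------------------------------------------------
# library-size equalization (quantile-adjusted pseudo-counts)
# ---------------------------------------------------------------------------

def _q2q_nbinom(
    y: np.ndarray, mu_in: np.ndarray, mu_out: np.ndarray, phi: float
) -> np.ndarray:
    """Map counts to a common library size by NB quantile matching.

    Uses the mid-p percentile of y under NB(mu_in, phi) and inverts it under
    NB(mu_out, phi) with linear interpolation on the discrete CDF, so a
    count maps to itself when the two means coincide.
    """
    y = np.asarray(y, dtype=np.int64)
    mu_in = np.maximum(np.asarray(mu_in, dtype=float), 1e-12)
    mu_out = np.maximum(np.asarray(mu_out, dtype=float), 1e-12)
    if phi < _MIN_PHI:
        din = poisson(mu_in)
        dout = poisson(mu_out)
    else:
        r = 1.0 / phi
        din = nbinom(r, r / (r + mu_in))
        dout = nbinom(r, r / (r + mu_out))
    p_mid = din.cdf(y - 1) + 0.5 * din.pmf(y)
    p_mid = np.clip(p_mid, 1e-12, 1.0 - 1e-12)
    k = dout.ppf(p_mid)
    f_k = dout.pmf(k)
    f_km1 = dout.cdf(k - 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(f_k > 0, (p_mid - f_km1) / f_k, 0.5)
    frac = np.clip(frac, 0.0, 1.0)
    return np.maximum(k - 0.5 + frac, 0.0)


def equalize_lib_sizes(
    counts: np.ndarray,
    lib_sizes: np.ndarray,
    dispersion: float,
    common_lib: float | None = None,
) -> tuple[np.ndarray, float]:
    """Quantile-adjust counts to a common (geometric-mean) library size."""
    counts = np.asarray(counts)
    lib_sizes = np.asarray(lib_sizes, dtype=float)
    if common_lib is None:
        common_lib = float(np.exp(np.mean(np.log(lib_sizes))))
    lam = counts.sum(axis=1) / lib_sizes.sum()
    mu_in = lam[:, None] * lib_sizes[None, :]
    mu_out = np.broadcast_to((lam * common_lib)[:, None], counts.shape)
    pseudo = _q2q_nbinom(counts, mu_in, mu_out, dispersion)
    return pseudo, common_lib


# ---------------------------------------------------------------------------
# dispersion estimation (conditional likelihood on equalized counts)
# ---------------------------------------------------------------------------

def _cond_loglik_per_gene(pseudo: np.ndarray, group_cols: list[np.ndarray], phi: float) -> np.ndarray:
    """Per-gene conditional NB log-likelihood at dispersion phi.

    For a group of n samples with (pseudo-)counts y_i and total z, the
    likelihood conditional on z under equal library sizes is
    prod Gamma(y_i + r) * Gamma(n r) / (Gamma(z + n r) * Gamma(r)^n) up to a
    phi-free constant, with r = 1/phi.  Groups of size 1 contribute 0.
    """
    r = 1.0 / max(phi, _MIN_PHI)
    total = np.zeros(pseudo.shape[0])
    for cols in group_cols:
        n = cols.size
        if n < 2:
            continue
        yg = pseudo[:, cols]
        z = yg.sum(axis=1)
        total += (
            gammaln(yg + r).sum(axis=1)
            + gammaln(n * r)
            - gammaln(z + n * r)
            - n * gammaln(r)
        )
    return total


def estimate_dispersion(
    matrix: CountMatrix | np.ndarray,
    groups: np.ndarray,
    lib_sizes: np.ndarray | None = None,
    tagwise: bool = True,
    prior_n: float = 10.0,
    grid_size: int = 45,
) -> DispersionEstimate:
    """Estimate the NB dispersion by conditional maximum likelihood.

    Counts are quantile-adjusted to a common library size, then the common
    dispersion maximizes the summed conditional log-likelihood across genes
    and groups (one adjustment/estimation refinement pass).  Tagwise
    dispersions maximize each gene's likelihood plus ``prior_n`` times the
    genome-wide average likelihood (weighted-likelihood shrinkage toward
    the common value).
    """
    counts = matrix.counts if isinstance(matrix, CountMatrix) else np.asarray(matrix)
    groups = np.asarray(groups)
    if lib_sizes is None:
        lib_sizes = counts.sum(axis=0).astype(float)
    labels = np.unique(groups)
    group_cols = [np.flatnonzero(groups == g) for g in labels]
    if all(c.size < 2 for c in group_cols):
        raise ValueError("every group has a single sample; dispersion is not estimable")

    def common_at(pseudo: np.ndarray) -> float:
        def neg(logphi: float) -> float:
            return -float(_cond_loglik_per_gene(pseudo, group_cols, np.exp(logphi)).sum())

        res = minimize_scalar(neg, bounds=(np.log(1e-6), np.log(20.0)), method="bounded",
                              options={"xatol": 1e-4})
        return float(np.exp(res.x))

    pseudo, _ = equalize_lib_sizes(counts, lib_sizes, 0.0)
    phi = common_at(pseudo)
    pseudo, _ = equalize_lib_sizes(counts, lib_sizes, phi)
    phi = common_at(pseudo)

    tw = None
    if tagwise:
        grid = np.concatenate([np.geomspace(1e-4, 5.0, grid_size), [phi]])
        grid.sort()
        ll = np.stack(
            [_cond_loglik_per_gene(pseudo, group_cols, g) for g in grid], axis=1
        )  # genes x grid
        score = ll + prior_n * ll.mean(axis=0)[None, :]
        tw = grid[np.argmax(score, axis=1)]
    log.info("common dispersion %.5f%s", phi, " (+tagwise)" if tagwise else "")
    return DispersionEstimate(common_dispersion=phi, tagwise=tw)


# ---------------------------------------------------------------------------
# exact NB test
# ---------------------------------------------------------------------------

def _sum_logpmf(a: np.ndarray, size: np.ndarray, mean: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """log pmf of a sum of iid NB counts: NB(size=n/phi) or Poisson when phi ~ 0."""
    out = np.empty(a.shape, dtype=float)
    pois = phi < _MIN_PHI
    if pois.any():
        lam = mean[pois]
        out[pois] = a[pois] * np.log(np.maximum(lam, 1e-300)) - lam - gammaln(a[pois] + 1)
    nb = ~pois
    if nb.any():
        r = size[nb]
        mu = mean[nb]
        p = r / (r + mu)
        out[nb] = (
            gammaln(a[nb] + r) - gammaln(r) - gammaln(a[nb] + 1)
            + r * np.log(p) + a[nb] * np.log1p(-p)
        )
    return out


def nb_exact_test(
    group_a: np.ndarray,
    group_b: np.ndarray,
    dispersion: float | np.ndarray,
    max_chunk_points: int = 4_000_000,
) -> np.ndarray:
    """Conditional NB exact test per gene between two groups.

    ``group_a`` and ``group_b`` are genes x replicates matrices of counts
    equalized to a common library size.  For each gene the group totals
    A and B are conditioned on T = A + B; outcome probabilities over
    a = 0..T follow the NB sum distributions under the null common mean,
    and the two-sided p-value doubles the smaller tail (inclusive of the
    observed outcome), capped at 1.
    """
    ya = np.atleast_2d(np.asarray(group_a, dtype=float))
    yb = np.atleast_2d(np.asarray(group_b, dtype=float))
    n_a, n_b = ya.shape[1], yb.shape[1]
    G = ya.shape[0]
    phi = np.broadcast_to(np.asarray(dispersion, dtype=float), (G,)).copy()
    phi = np.maximum(phi, 0.0)

    sa = np.rint(ya.sum(axis=1)).astype(np.int64)
    sb = np.rint(yb.sum(axis=1)).astype(np.int64)
    t = sa + sb
    mu = t / (n_a + n_b)  # per-sample null mean

    pvals = np.ones(G)
    order = np.arange(G)
    # chunk genes so the flattened enumeration stays in memory
    start = 0
    sizes = t + 1
    while start < G:
        end = start
        pts = 0
        while end < G and (pts + sizes[end] <= max_chunk_points or end == start):
            pts += sizes[end]
            end += 1
        idx = order[start:end]
        pvals[idx] = _exact_test_chunk(sa[idx], t[idx], mu[idx], phi[idx], n_a, n_b)
        start = end
    return pvals


def _exact_test_chunk(
    sa: np.ndarray, t: np.ndarray, mu: np.ndarray, phi: np.ndarray, n_a: int, n_b: int
) -> np.ndarray:
    m = t.size
    sizes = (t + 1).astype(np.int64)
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    total_pts = int(offsets[-1])
    gene_of = np.repeat(np.arange(m), sizes)
    a = np.arange(total_pts, dtype=np.int64) - np.repeat(offsets[:-1], sizes)

    phi_f = phi[gene_of]
    with np.errstate(divide="ignore"):
        size_a = np.where(phi_f > 0, n_a / np.maximum(phi_f, _MIN_PHI), np.inf)
        size_b = np.where(phi_f > 0, n_b / np.maximum(phi_f, _MIN_PHI), np.inf)
    mean_a = n_a * mu[gene_of]
    mean_b = n_b * mu[gene_of]
    w = _sum_logpmf(a, size_a, mean_a, phi_f) + _sum_logpmf(
        t[gene_of] - a, size_b, mean_b, phi_f
    )
    # stabilize per gene
    wmax = np.maximum.reduceat(w, offsets[:-1])
    ew = np.exp(w - wmax[gene_of])
    cs = np.cumsum(ew)
    seg_end = cs[offsets[1:] - 1]
    seg_before = np.concatenate([[0.0], seg_end[:-1]])
    norm = seg_end - seg_before
    obs_pos = offsets[:-1] + sa
    p_le = cs[obs_pos] - seg_before
    below_obs = np.where(sa > 0, cs[obs_pos - 1] - seg_before, 0.0)
    # guard sa==0: obs_pos-1 underflows into previous segment
    below_obs = np.where(sa > 0, below_obs, 0.0)
    p_ge = norm - below_obs
    p = 2.0 * np.minimum(p_le, p_ge) / norm
    return np.minimum(p, 1.0)


# ---------------------------------------------------------------------------
# FDR and the composed pipeline
# ---------------------------------------------------------------------------

def bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_de(
    matrix: CountMatrix,
    contrast: tuple[str, str],
    fdr_cutoff: float = 0.1,
    min_total: int = 4,
    dispersion_mode: str = "tagwise",
    prior_lfc_count: float = 0.5,
) -> DEResult:
    """TMM -> equalization -> dispersion -> exact test -> BH, for one contrast.

    ``contrast`` is (treatment, control); genes with fewer than
    ``min_total`` counts summed across the contrast's samples are excluded
    before testing.
    """
    treat, ctrl = contrast
    sel = [s.sample_id for s in matrix.samples if s.treatment in (treat, ctrl)]
    sub = matrix.subset_samples(sel)
    groups = np.array([s.treatment for s in sub.samples])
    if (groups == treat).sum() == 0 or (groups == ctrl).sum() == 0:
        raise ValueError(f"contrast {contrast} has an empty group")

    keep = sub.counts.sum(axis=1) >= min_total
    genes = np.asarray(sub.gene_ids)[keep]
    counts = sub.counts[keep]
    log.info(
        "run_de %s vs %s: %d/%d genes pass the %d-count filter",
        treat, ctrl, keep.sum(), keep.size, min_total,
    )
    if counts.shape[0] == 0:
        raise ValueError("no genes pass the expression filter")

    factors = tmm_factors(counts)
    eff_lib = counts.sum(axis=0) * factors
    disp = estimate_dispersion(
        counts, groups, lib_sizes=eff_lib, tagwise=(dispersion_mode == "tagwise")
    )
    phi_test = disp.per_gene(counts.shape[0]) if dispersion_mode == "tagwise" \
        else np.full(counts.shape[0], disp.common_dispersion)
    pseudo, common_lib = equalize_lib_sizes(counts, eff_lib, disp.common_dispersion)
    a_cols = np.flatnonzero(groups == treat)
    b_cols = np.flatnonzero(groups == ctrl)
    p = nb_exact_test(pseudo[:, a_cols], pseudo[:, b_cols], phi_test)
    p = np.clip(p, np.nextafter(0, 1), 1.0)
    fdr = bh_fdr(p)

    mean_a = pseudo[:, a_cols].mean(axis=1)
    mean_b = pseudo[:, b_cols].mean(axis=1)
    lfc = np.log2((mean_a + prior_lfc_count) / (mean_b + prior_lfc_count))
    log_cpm = np.log2((mean_a + mean_b) / 2 / common_lib * 1e6 + 1e-6)
    table = pd.DataFrame(
        {
            "gene_id": genes,
            "log_cpm": log_cpm,
            "log2fc": lfc,
            "p_value": p,
            "fdr": fdr,
        }
    )
    n_deg = int((fdr < fdr_cutoff).sum())
    log.info("run_de %s vs %s: %d DEGs at FDR < %g", treat, ctrl, n_deg, fdr_cutoff)
    return DEResult(table=table, contrast=contrast, fdr_cutoff=fdr_cutoff,
                    n_deg_at_cutoff=n_deg, dispersion=disp)


def degs_vs_depth(
    matrix: CountMatrix,
    contrast: tuple[str, str],
    depth_grid: np.ndarray,
    seed: int = 0,
    n_reps: int = 1,
    fdr_cutoff: float = 0.1,
    **de_kwargs,
) -> pd.DataFrame:
    """DEG count after progressive downsampling to each grid depth.

    The matrix is downsampled by its own counts (UMI counts for a DGE
    matrix, read counts for a conventional one — matching how depth is
    expressed on each technology's axis), ``run_de`` is applied at each
    depth, and DEG counts are averaged over ``n_reps`` stochastic
    downsampling replicates.
    """
    rows = []
    for d in np.asarray(depth_grid, dtype=np.int64):
        counts_at_depth = []
        for r in range(n_reps):
            res = downsample_matrix(matrix, int(d), seed=seed + 1000 * r + int(d) % 997,
                                    min_count=0)
            if d == 0:
                counts_at_depth.append(0)
                continue
            de = run_de(res.counts_at_depth, contrast, fdr_cutoff=fdr_cutoff, **de_kwargs)
            counts_at_depth.append(de.n_deg_at_cutoff)
        rows.append(
            {
                "depth": int(d),
                "mean_degs": float(np.mean(counts_at_depth)),
                "sd_degs": float(np.std(counts_at_depth, ddof=1)) if n_reps > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)
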