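"""Signed rank-rank hypergeometric overlap (RRHO) between two DE rankings.

Genes are ranked by signed significance s = sign(log2fc) * (-log10 p), most
significantly up-regulated first and most significantly down-regulated
last.  For a stepped grid of rank-cutoff pairs (x, y) the overlap between
the top-x genes of one list and the top-y genes of the other is scored by
Fisher's exact (hypergeometric) test — right tail when the overlap exceeds
its expectation x*y/N, left tail otherwise — and stored as a signed
-log10 p, producing the familiar RRHO heatmap grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .diffexp import DEResult

__all__ = ["RankedList", "RRHOMap", "signed_rank", "rrho_map", "export_heatmap_table"]

_TINY_P = np.finfo(float).tiny  # clamp for p == 0 before -log10


@dataclass
class RankedList:
    """Genes ordered by signed significance, scores retained."""

    gene_ids: list[str]
    scores: np.ndarray  # nonincreasing

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.gene_ids) != self.scores.size:
            raise ValueError("gene list and scores must have equal length")
        if np.any(np.diff(self.scores) > 1e-12):
            raise ValueError("scores must be nonincreasing down the list")

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass
class RRHOMap:
    cutoffs_a: np.ndarray
    cutoffs_b: np.ndarray
    overlap: np.ndarray        # |cutoffs_a| x |cutoffs_b|
    signed_log10_p: np.ndarray
    step: int
    universe_size: int


def signed_rank(de: DEResult | pd.DataFrame) -> RankedList:
    """Rank genes by signed -log10 p (up-regulated first).

    Ties in the score are broken lexicographically by gene id so the
    ordering is deterministic; p-values of exactly 0 are clamped to the
    smallest positive float before taking the logarithm.
    """
    table = de.table if isinstance(de, DEResult) else de
    p = np.clip(table["p_value"].to_numpy(float), _TINY_P, 1.0)
    lfc = table["log2fc"].to_numpy(float)
    s = np.sign(lfc) * (-np.log10(p))
    genes = table["gene_id"].to_numpy(str)
    order = np.lexsort((genes, -s))  # score descending, then gene id ascending
    return RankedList(list(genes[order]), s[order])


def _grid_cutoffs(n: int, step: int) -> np.ndarray:
    cut = np.arange(step, n + 1, step, dtype=np.int64)
    if cut.size == 0 or cut[-1] != n:
        cut = np.append(cut, n)
    return cut


def rrho_map(a: RankedList, b: RankedList, step: int = 10) -> RRHOMap:
    """Stepped overlap-significance map between two rankings.

    Both lists must be permutations of the same gene universe.  Cutoffs are
    {step, 2*step, ..., N} with N always included, so the full-overlap
    corner overlap(N, N) = N exists.  Overlap counts come from a 2-D
    cumulative histogram of each gene's (rank in a, rank in b).
    """
    if step < 1:
        raise ValueError("step must be >= 1")
    if set(a.gene_ids) != set(b.gene_ids) or len(a) != len(b):
        raise ValueError("the two rankings must cover the identical gene universe")
    n = len(a)
    rank_b = {g: i for i, g in enumerate(b.gene_ids)}  # 0-based
    ra = np.arange(n)
    rb = np.fromiter((rank_b[g] for g in a.gene_ids), dtype=np.int64, count=n)

    cuts_a = _grid_cutoffs(n, step)
    cuts_b = _grid_cutoffs(n, step)
    edges_a = np.concatenate([[0], cuts_a])
    edges_b = np.concatenate([[0], cuts_b])
    # 0-based ranks with left-closed bins: rank r (1-based) lands in the bin
    # whose upper edge is the smallest cutoff >= r
    hist, _, _ = np.histogram2d(ra, rb, bins=[edges_a, edges_b])
    overlap = hist.cumsum(axis=0).cumsum(axis=1).astype(np.int64)

    x = cuts_a[:, None].astype(float)
    y = cuts_b[None, :].astype(float)
    k = overlap
    expected = x * y / n
    # right tail: P(X >= k); left tail: P(X <= k); X ~ Hypergeom(N, x, y)
    p_right = hypergeom.sf(k - 1, n, x.astype(np.int64), y.astype(np.int64))
    p_left = hypergeom.cdf(k, n, x.astype(np.int64), y.astype(np.int64))
    enriched = k > expected
    p = np.where(enriched, p_right, p_left)
    signed = np.where(enriched, 1.0, -1.0) * (-np.log10(np.clip(p, _TINY_P, 1.0)))
    return RRHOMap(
        cutoffs_a=cuts_a, cutoffs_b=cuts_b, overlap=overlap,
        signed_log10_p=signed, step=step, universe_size=n,
    )


def export_heatmap_table(map_: RRHOMap, path: str | Path | None = None) -> pd.DataFrame:
    """Dense TSV/DataFrame of signed -log10 p with cutoff coordinates as labels."""
    df = pd.DataFrame(map_.signed_log10_p, index=map_.cutoffs_a, columns=map_.cutoffs_b)
    df.index.name = "cutoff_a"
    if path is not None:
        df.to_csv(path, sep="\t")
    return df
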