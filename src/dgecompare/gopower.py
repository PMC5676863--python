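"""Power to detect gene-ontology process enrichment per method.

When a sequencing method cannot detect part of the transcriptome, its
ability to call enrichment of a biological process by Fisher's exact test
drops.  For each process the 2x2 construction is: group 1 = genes in the
process (within the shared universe), group 2 = genes outside it, "success"
= membership in the method's detected gene set; p1 and p2 are the two
detection fractions.  Power is estimated by Monte Carlo: draw
X ~ Binom(n1, p1) and Y ~ Binom(n2, p2), apply the two-sided Fisher exact
test to [[X, n1-X], [Y, n2-Y]], and report the fraction of simulations with
p <= alpha.  Processes are classified at a power threshold (default 0.8)
into both_powered / a_only / b_only / neither.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .containers import GeneSetCollection

log = logging.getLogger("dgecompare")

__all__ = ["PowerResult", "fisher_power", "process_power_profile", "fisher_exact_two_sided"]


@dataclass
class PowerResult:
    table: pd.DataFrame  # process_id, size, power_a, power_b, delta, classification
    alpha: float
    threshold: float
    n_sim: int
    seed: int

    def classification_counts(self) -> dict[str, int]:
        return self.table["classification"].value_counts().to_dict()


def fisher_exact_two_sided(x: int, n1: int, y: int, n2: int) -> float:
    """Two-sided Fisher exact p for the table [[x, n1-x], [y, n2-y]].

    Sums hypergeometric probabilities of all outcomes with the observed
    margins whose probability does not exceed that of the observed table
    (with a small relative tolerance against ties lost to rounding).
    """
    k_total = x + y
    dist = hypergeom(n1 + n2, k_total, n1)
    support = np.arange(max(0, k_total - n2), min(n1, k_total) + 1)
    pmf = dist.pmf(support)
    p_obs = dist.pmf(x)
    return float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-7)].sum()))


def fisher_power(
    n1: int,
    n2: int,
    p1: float,
    p2: float,
    alpha: float = 0.05,
    n_sim: int = 1000,
    seed: int = 0,
) -> float:
    """Monte-Carlo power of the two-sided Fisher exact test.

    Standard error of the estimate is at most 1 / (2 sqrt(n_sim)).
    Repeated (X, Y) outcomes share one exact-p computation via a cache.
    """
    if not (0 <= p1 <= 1 and 0 <= p2 <= 1):
        raise ValueError("proportions must lie in [0, 1]")
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")
    rng = np.random.default_rng(seed)
    xs = rng.binomial(n1, p1, n_sim)
    ys = rng.binomial(n2, p2, n_sim)
    pairs, counts = np.unique(np.stack([xs, ys], axis=1), axis=0, return_counts=True)
    hits = 0
    for (x, y), c in zip(pairs, counts):
        if fisher_exact_two_sided(int(x), n1, int(y), n2) <= alpha:
            hits += int(c)
    return hits / n_sim


def _process_seed(base_seed: int, process_id: str) -> int:
    # stable per-process stream, independent of iteration order
    return (base_seed + zlib.crc32(process_id.encode())) % (2**31 - 1)


def process_power_profile(
    detected_a: set[str],
    detected_b: set[str],
    universe: set[str],
    ontology: GeneSetCollection,
    alpha: float = 0.05,
    threshold: float = 0.8,
    n_sim: int = 1000,
    seed: int = 0,
) -> PowerResult:
    """Per-process enrichment-detection power for two methods.

    ``detected_a`` / ``detected_b`` are each method's detected gene sets
    (subsets of ``universe``).  Processes with no members in the universe
    are skipped with a log entry.
    """
    if not detected_a <= universe or not detected_b <= universe:
        raise ValueError("detected gene sets must be subsets of the universe")
    n_universe = len(universe)
    rows = []
    for gs in ontology:
        members = gs.members & universe
        n1 = len(members)
        if n1 == 0:
            log.info("process %s has no members in the universe; skipped", gs.set_id)
            continue
        n2 = n_universe - n1
        pseed = _process_seed(seed, gs.set_id)
        powers = {}
        for label, detected in (("a", detected_a), ("b", detected_b)):
            p1 = len(members & detected) / n1
            p2 = (len(detected) - len(members & detected)) / n2 if n2 > 0 else 0.0
            powers[label] = fisher_power(n1, n2, p1, p2, alpha=alpha, n_sim=n_sim,
                                         seed=pseed)
        pa, pb = powers["a"], powers["b"]
        if pa > threshold and pb > threshold:
            cls = "both_powered"
        elif pa > threshold:
            cls = "a_only"
        elif pb > threshold:
            cls = "b_only"
        else:
            cls = "neither"
        rows.append(
            {
                "process_id": gs.set_id,
                "process_size": n1,
                "power_a": pa,
                "power_b": pb,
                "delta": pa - pb,
                "classification": cls,
            }
        )
    table = pd.DataFrame(rows)
    return PowerResult(table=table, alpha=alpha, threshold=threshold, n_sim=n_sim, seed=seed)
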