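"""Core in-memory containers for paired-method RNA-seq count data.

The package compares two library strategies for bulk mRNA-seq run on the
same RNA samples: conventional random-primed sequencing quantified by read
counts, and 3'-end digital gene expression (3'-DGE) quantified by UMI
(unique molecular identifier) counts, with raw read counts available as an
intermediate.  All downstream analyses operate on the types defined here.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Method",
    "CountUnit",
    "SampleMeta",
    "CountMatrix",
    "GeneTable",
    "GeneSet",
    "GeneSetCollection",
    "NormalizedMatrix",
]


class Method(str, enum.Enum):
    """Library preparation / quantification strategy of a sample."""

    CONVENTIONAL = "conventional"
    DGE = "dge"


class CountUnit(str, enum.Enum):
    """What one count in a matrix represents."""

    READ = "read"
    UMI = "umi"


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one sequenced sample.

    Parameters
    ----------
    sample_id
        Unique sample identifier (the count-matrix column header).
    method
        Library strategy, ``conventional`` or ``dge``.
    treatment
        Treatment label, e.g. ``CTRL`` / ``SOR`` / ``SUN``.
    replicate
        1-based biological replicate index within (method, treatment).
    """

    sample_id: str
    method: Method
    treatment: str
    replicate: int

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValueError("sample_id must be non-empty")
        if not isinstance(self.method, Method):
            object.__setattr__(self, "method", Method(self.method))
        if not self.treatment:
            raise ValueError(f"sample {self.sample_id!r}: treatment must be non-empty")
        if self.replicate < 1:
            raise ValueError(f"sample {self.sample_id!r}: replicate must be >= 1")


class CountMatrix:
    """Gene x sample matrix of non-negative integer counts.

    Genes are rows, samples are columns.  ``unit`` records whether entries
    are read counts or UMI counts; several operations (e.g. transcript-length
    normalization) behave differently for the two.
    """

    def __init__(
        self,
        gene_ids: Sequence[str],
        samples: Sequence[SampleMeta],
        counts: np.ndarray,
        unit: CountUnit | str = CountUnit.READ,
    ) -> None:
        self.gene_ids = list(gene_ids)
        self.samples = list(samples)
        counts = np.asarray(counts)
        if counts.ndim != 2:
            raise ValueError("counts must be a 2-D array (genes x samples)")
        if counts.shape != (len(self.gene_ids), len(self.samples)):
            raise ValueError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.samples)} samples"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            rounded = np.rint(counts)
            if not np.array_equal(rounded, counts):
                raise ValueError("non-integer count encountered")
            counts = rounded.astype(np.int64)
        if counts.size and counts.min() < 0:
            raise ValueError("negative count encountered")
        self.counts = counts.astype(np.int64, copy=False)
        self.unit = CountUnit(unit)

        if len(set(self.gene_ids)) != len(self.gene_ids):
            seen: set[str] = set()
            for g in self.gene_ids:
                if g in seen:
                    raise ValueError(f"duplicate gene id: {g!r}")
                seen.add(g)
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample ids in sample list")

    # -- basic introspection -------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def column_sums(self) -> np.ndarray:
        """Per-sample library size (total counts)."""
        return self.counts.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)

    # -- subsetting ----------------------------------------------------------

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def subset_genes(self, genes: Sequence[str]) -> "CountMatrix":
        idx = self.gene_index()
        rows = [idx[g] for g in genes]
        return CountMatrix(list(genes), self.samples, self.counts[rows, :], self.unit)

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        pos = {s.sample_id: j for j, s in enumerate(self.samples)}
        cols = [pos[s] for s in sample_ids]
        return CountMatrix(
            self.gene_ids, [self.samples[j] for j in cols], self.counts[:, cols], self.unit
        )

    def with_counts(self, counts: np.ndarray, unit: CountUnit | str | None = None) -> "CountMatrix":
        return CountMatrix(self.gene_ids, self.samples, counts, unit or self.unit)

    def select(self, method: Method | str | None = None, treatment: str | None = None) -> "CountMatrix":
        """Subset samples by method and/or treatment."""
        keep = [
            s.sample_id
            for s in self.samples
            if (method is None or s.method == Method(method))
            and (treatment is None or s.treatment == treatment)
        ]
        return self.subset_samples(keep)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return (
            self.gene_ids == other.gene_ids
            and self.samples == other.samples
            and self.unit == other.unit
            and np.array_equal(self.counts, other.counts)
        )

    def __repr__(self) -> str:
        return (
            f"CountMatrix({self.n_genes} genes x {self.n_samples} samples, "
            f"unit={self.unit.value})"
        )


class GeneTable:
    """Per-gene mean transcript length (bp), used to normalize random-primed counts.

    Random priming yields fragments along the whole transcript, so read
    counts scale with transcript length; 3'-DGE UMI counts do not.
    """

    def __init__(self, lengths: Mapping[str, float] | pd.Series) -> None:
        s = pd.Series(lengths, dtype=float)
        if s.index.has_duplicates:
            dup = s.index[s.index.duplicated()][0]
            raise ValueError(f"duplicate gene id in gene table: {dup!r}")
        if s.size and (s <= 0).any():
            bad = s.index[s <= 0][0]
            raise ValueError(f"non-positive transcript length for gene {bad!r}")
        self.lengths = s

    @property
    def gene_ids(self) -> list[str]:
        return list(self.lengths.index)

    def length_of(self, gene: str) -> float:
        try:
            return float(self.lengths[gene])
        except KeyError:
            raise KeyError(f"no transcript length for gene {gene!r}") from None

    def __len__(self) -> int:
        return self.lengths.size

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneTable):
            return NotImplemented
        return self.lengths.equals(other.lengths)


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    description: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.set_id!r} has no members")


class GeneSetCollection:
    """Ordered collection of named gene sets (e.g. GO biological processes)."""

    def __init__(self, sets: Iterable[GeneSet] = ()) -> None:
        self.sets: list[GeneSet] = list(sets)
        ids = [s.set_id for s in self.sets]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate set ids in collection")
        self._by_id = {s.set_id: s for s in self.sets}

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.sets)

    def __getitem__(self, set_id: str) -> GeneSet:
        return self._by_id[set_id]

    def __contains__(self, set_id: str) -> bool:
        return set_id in self._by_id

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneSetCollection):
            return NotImplemented
        return self.sets == other.sets


@dataclass
class NormalizedMatrix:
    """Real-valued gene x sample matrix after normalization / unit scaling.

    ``normalization`` records the chain applied (``none``, ``length``,
    ``length+depth`` ...); ``scale_note`` is a free-text description of the
    unit scaling so results stay self-describing.
    """

    gene_ids: list[str]
    samples: list[SampleMeta]
    values: np.ndarray
    normalization: str = "none"
    scale_note: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.samples)):
            raise ValueError("values shape does not match gene/sample lists")
        if self.values.size and np.nanmin(self.values) < 0:
            raise ValueError("normalized values must be non-negative")

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)
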