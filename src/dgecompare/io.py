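"""Readers and writers for on-disk artifacts.

Everything is plain text: TSV count matrices with a mandatory header row
(first column = gene id), TSV sample sheets, TSV gene-length tables, GMT
gene-set files, and TSV/JSON result tables.  Gene ids are opaque strings;
no symbol remapping is ever attempted.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import (
    CountMatrix,
    CountUnit,
    GeneSet,
    GeneSetCollection,
    GeneTable,
    Method,
    SampleMeta,
)

log = logging.getLogger("dgecompare")

__all__ = [
    "read_sample_sheet",
    "write_sample_sheet",
    "read_count_matrix",
    "write_count_matrix",
    "read_gene_table",
    "write_gene_table",
    "read_gene_sets",
    "write_gene_sets",
    "intersect_gene_universe",
]


def read_sample_sheet(path: str | Path) -> dict[str, SampleMeta]:
    """Read a TSV sample sheet (sample_id, method, treatment, replicate)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "method", "treatment", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet {path}: missing columns {sorted(missing)}")
    sheet: dict[str, SampleMeta] = {}
    for _, row in df.iterrows():
        meta = SampleMeta(
            sample_id=row["sample_id"],
            method=Method(row["method"]),
            treatment=row["treatment"],
            replicate=int(row["replicate"]),
        )
        if meta.sample_id in sheet:
            raise ValueError(f"duplicate sample id in sample sheet: {meta.sample_id!r}")
        sheet[meta.sample_id] = meta
    return sheet


def write_sample_sheet(samples: Sequence[SampleMeta], path: str | Path) -> None:
    pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "method": [s.method.value for s in samples],
            "treatment": [s.treatment for s in samples],
            "replicate": [s.replicate for s in samples],
        }
    ).to_csv(path, sep="\t", index=False)


def read_count_matrix(
    path: str | Path,
    sample_sheet: str | Path | dict[str, SampleMeta],
    unit: CountUnit | str = CountUnit.READ,
) -> CountMatrix:
    """Read a TSV count matrix and attach sample metadata.

    The first column holds gene ids; every remaining column header must
    appear in the sample sheet.  Counts must be non-negative integers;
    a fractional entry raises ``ValueError("non-integer count ...")``.
    """
    if not isinstance(sample_sheet, dict):
        sample_sheet = read_sample_sheet(sample_sheet)
    df = pd.read_csv(path, sep="\t", index_col=0)
    gene_ids = [str(g) for g in df.index]
    seen: set[str] = set()
    for g in gene_ids:
        if g in seen:
            raise ValueError(f"duplicate gene id: {g!r} in {path}")
        seen.add(g)
    samples = []
    for col in df.columns:
        if col not in sample_sheet:
            raise ValueError(f"column {col!r} in {path} has no sample-sheet entry")
        samples.append(sample_sheet[col])
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.integer):
        values = np.asarray(values, dtype=float)
        if not np.array_equal(np.rint(values), values):
            bad = np.argwhere(np.rint(values) != values)[0]
            raise ValueError(
                f"non-integer count {values[tuple(bad)]!r} for gene "
                f"{gene_ids[bad[0]]!r}, sample {df.columns[bad[1]]!r}"
            )
        values = values.astype(np.int64)
    log.info("read count matrix %s: %d genes x %d samples", path, len(gene_ids), len(samples))
    return CountMatrix(gene_ids, samples, values, unit)


def write_count_matrix(matrix: CountMatrix, path: str | Path) -> None:
    df = matrix.to_frame()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


def read_gene_table(path: str | Path) -> GeneTable:
    """Read a TSV gene table with columns gene_id, mean_transcript_length."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    cols = list(df.columns)
    if "gene_id" in cols and "mean_transcript_length" in cols:
        s = pd.Series(df["mean_transcript_length"].to_numpy(float), index=df["gene_id"])
    else:  # positional fallback: first column id, second length
        s = pd.Series(df.iloc[:, 1].to_numpy(float), index=df.iloc[:, 0].astype(str))
    return GeneTable(s)


def write_gene_table(table: GeneTable, path: str | Path) -> None:
    pd.DataFrame(
        {"gene_id": table.gene_ids, "mean_transcript_length": table.lengths.to_numpy()}
    ).to_csv(path, sep="\t", index=False)


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: one set per line, ``name<TAB>description<TAB>members...``.

    Member lists are deduplicated; a line with fewer than three fields is an
    error reported with its line number.
    """
    sets: list[GeneSet] = []
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            members = frozenset(m for m in row[2:] if m)
            sets.append(GeneSet(set_id=row[0], description=row[1], members=members))
    return GeneSetCollection(sets)


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        for s in collection:
            w.writerow([s.set_id, s.description, *sorted(s.members)])


def intersect_gene_universe(a: CountMatrix, b: CountMatrix) -> tuple[CountMatrix, CountMatrix]:
    """Restrict two matrices to their shared gene universe, in a's gene order.

    Every cross-method analysis runs on the explicit intersection of the two
    reference gene lists; genes present in only one matrix are dropped (the
    number dropped is logged).
    """
    bset = set(b.gene_ids)
    shared = [g for g in a.gene_ids if g in bset]
    if not shared:
        raise ValueError("gene universes of the two matrices do not intersect")
    dropped = (a.n_genes - len(shared)) + (b.n_genes - len(shared))
    log.info(
        "gene universe intersection: %d shared genes (%d dropped)", len(shared), dropped
    )
    return a.subset_genes(shared), b.subset_genes(shared)
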