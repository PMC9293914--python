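"""In-memory containers shared across the pipeline.

The pipeline moves between three representations:

* :class:`CountMatrix` — sparse genes × cells (or genes × samples) raw
  counts with ordered identifiers, the form data arrives in from a
  10x-style MatrixMarket directory or a bulk TSV.
* :class:`NormalizedMatrix` — dense genes × cells reals carrying a tag
  saying which normalization produced them (``lognorm`` or ``scaled``);
  downstream operations check the tag rather than guessing.
* plain :class:`pandas.DataFrame` tables for per-gene annotation,
  ortholog maps, truth labels and result tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "FormatError",
    "CountMatrix",
    "NormalizedMatrix",
    "GeneSignature",
    "CentroidModel",
    "validate_annotation",
    "validate_ortholog_table",
]


class FormatError(ValueError):
    """A file or table violates its documented format contract."""


def _check_ids(ids, what: str) -> pd.Index:
    idx = pd.Index(ids)
    if idx.has_duplicates:
        dups = idx[idx.duplicated()].unique().tolist()[:5]
        raise FormatError(f"duplicate {what} identifiers: {dups}")
    return idx


@dataclass
class CountMatrix:
    """Sparse non-negative integer count matrix, genes in rows.

    ``cell_ids`` holds sample identifiers when the matrix is bulk
    (genes × samples); the container does not care which.
    """

    values: sp.csr_matrix
    gene_ids: pd.Index
    cell_ids: pd.Index

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        self.gene_ids = _check_ids(self.gene_ids, "gene")
        self.cell_ids = _check_ids(self.cell_ids, "cell")
        g, c = self.values.shape
        if g != len(self.gene_ids) or c != len(self.cell_ids):
            raise FormatError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if self.values.nnz and self.values.data.min() < 0:
            raise FormatError("count matrix contains negative entries")
        data = self.values.data
        if data.size and not np.allclose(data, np.round(data)):
            raise FormatError("count matrix contains non-integer entries")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """Dense genes × cells DataFrame (small matrices only)."""
        return pd.DataFrame(
            self.values.toarray(), index=self.gene_ids, columns=self.cell_ids
        )

    def subset(self, genes=None, cells=None) -> "CountMatrix":
        """Positional or label-based subset preserving order of the arguments."""
        vals = self.values
        gidx, cidx = self.gene_ids, self.cell_ids
        if genes is not None:
            rows = gidx.get_indexer(pd.Index(genes)) if not np.issubdtype(
                np.asarray(genes).dtype, np.integer
            ) else np.asarray(genes)
            if np.any(rows < 0):
                raise KeyError("unknown gene identifiers in subset")
            vals = vals[rows]
            gidx = gidx[rows]
        if cells is not None:
            cols = cidx.get_indexer(pd.Index(cells)) if not np.issubdtype(
                np.asarray(cells).dtype, np.integer
            ) else np.asarray(cells)
            if np.any(cols < 0):
                raise KeyError("unknown cell identifiers in subset")
            vals = vals[:, cols]
            cidx = cidx[cols]
        return CountMatrix(sp.csr_matrix(vals), gidx, cidx)


@dataclass
class NormalizedMatrix:
    """Dense genes × cells real matrix with a normalization tag.

    ``kind`` is ``"lognorm"`` (library-size normalized, log1p) or
    ``"scaled"`` (per-gene z-scored and clipped). Operations that need a
    particular normalization assert on the tag.
    """

    values: pd.DataFrame
    kind: str = "lognorm"
    scale_factor: float = 1e4

    def __post_init__(self) -> None:
        if self.kind not in ("lognorm", "scaled"):
            raise ValueError(f"unknown normalization kind {self.kind!r}")
        if self.scale_factor <= 0:
            raise ValueError("scale_factor must be positive")
        _check_ids(self.values.index, "gene")
        _check_ids(self.values.columns, "cell")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def cell_ids(self) -> pd.Index:
        return self.values.columns


@dataclass
class GeneSignature:
    """Named gene set (a GMT line)."""

    name: str
    description: str
    genes: tuple

    def __post_init__(self) -> None:
        if not self.genes:
            raise FormatError(f"signature {self.name!r} has an empty gene set")
        if len(set(self.genes)) != len(self.genes):
            raise FormatError(f"signature {self.name!r} has duplicate genes")
        self.genes = tuple(self.genes)

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class CentroidModel:
    """Genes × subtypes centroid table for nearest-centroid subtyping."""

    centroids: pd.DataFrame  # genes x subtypes

    def __post_init__(self) -> None:
        if self.centroids.shape[1] < 2:
            raise FormatError("centroid model needs at least 2 subtypes")
        if self.centroids.isna().any().any():
            raise FormatError("centroid model contains missing values")
        _check_ids(self.centroids.index, "gene")
        _check_ids(self.centroids.columns, "subtype")

    @property
    def genes(self) -> pd.Index:
        return self.centroids.index

    @property
    def subtypes(self) -> pd.Index:
        return self.centroids.columns


ANNOTATION_COLUMNS = ("gene_id", "chromosome", "start")


def validate_annotation(ann: pd.DataFrame) -> pd.DataFrame:
    """Validate a gene annotation table (gene_id, chromosome, 0-based start)."""
    missing = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing:
        raise FormatError(f"gene annotation missing columns {missing}")
    if ann["gene_id"].duplicated().any():
        raise FormatError("gene annotation has duplicated gene_id rows")
    if (ann["start"].astype(np.int64) < 0).any():
        raise FormatError("gene annotation has negative start coordinates")
    return ann


ORTHOLOG_COLUMNS = ("source_symbol", "target_symbol", "mapping_class")
_MAPPING_CLASSES = {"one-to-one", "one-to-many", "many-to-one"}


def validate_ortholog_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ORTHOLOG_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"ortholog table missing columns {missing}")
    if table.duplicated(["source_symbol", "target_symbol"]).any():
        raise FormatError("ortholog table has duplicated (source, target) pairs")
    bad = set(table["mapping_class"]) - _MAPPING_CLASSES
    if bad:
        raise FormatError(f"unknown mapping_class values {sorted(bad)}")
    return table
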