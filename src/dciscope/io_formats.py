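"""Readers and writers for the on-disk formats the pipeline touches.

Count matrices travel as 10x-style MatrixMarket triplet directories
(``matrix.mtx`` + ``features.tsv`` + ``barcodes.tsv``); gene sets as GMT;
everything else as headered TSV. All readers validate against the
container contracts in :mod:`dciscope.containers` and never reorder rows
or columns. MatrixMarket indices are 1-based on disk per the standard;
everything in memory is 0-based.
"""

from __future__ import annotations

import logging
import os
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .containers import (
    CentroidModel,
    CountMatrix,
    FormatError,
    GeneSignature,
    validate_annotation,
    validate_ortholog_table,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_mtx_triplet",
    "write_mtx_triplet",
    "read_10x_dir",
    "write_10x_dir",
    "read_gmt",
    "write_gmt",
    "read_gene_annotation",
    "read_centroid_model",
    "read_ortholog_table",
    "read_bulk_counts",
    "write_bulk_counts",
    "write_table",
]


def _read_sidecar(path) -> list:
    """First column of a headerless TSV sidecar (1–3 column 10x dialects)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                out.append(line.split("\t")[0])
    return out


def read_mtx_triplet(matrix_path, features_path, barcodes_path) -> CountMatrix:
    """Read a MatrixMarket triplet matrix with its two sidecar files."""
    try:
        mat = scipy.io.mmread(os.fspath(matrix_path))
    except ValueError as exc:
        raise FormatError(f"cannot parse MatrixMarket file {matrix_path}: {exc}")
    genes = _read_sidecar(features_path)
    cells = _read_sidecar(barcodes_path)
    if mat.shape != (len(genes), len(cells)):
        raise FormatError(
            f"matrix is {mat.shape[0]}x{mat.shape[1]} but sidecars have "
            f"{len(genes)} features and {len(cells)} barcodes"
        )
    mat = sp.coo_matrix(mat)
    if mat.data.size and (
        np.any(mat.data < 0) or not np.allclose(mat.data, np.round(mat.data))
    ):
        raise FormatError("matrix entries must be non-negative integers")
    return CountMatrix(
        sp.csr_matrix(mat).astype(np.int64), pd.Index(genes), pd.Index(cells)
    )


def write_mtx_triplet(cm: CountMatrix, matrix_path, features_path, barcodes_path):
    scipy.io.mmwrite(
        os.fspath(matrix_path), sp.coo_matrix(cm.values), field="integer"
    )
    Path(features_path).write_text(
        "".join(f"{g}\n" for g in cm.gene_ids)
    )
    Path(barcodes_path).write_text(
        "".join(f"{c}\n" for c in cm.cell_ids)
    )


def read_10x_dir(directory) -> CountMatrix:
    d = Path(directory)
    return read_mtx_triplet(
        d / "matrix.mtx", d / "features.tsv", d / "barcodes.tsv"
    )


def write_10x_dir(cm: CountMatrix, directory):
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_mtx_triplet(
        cm, d / "matrix.mtx", d / "features.tsv", d / "barcodes.tsv"
    )


# ---------------------------------------------------------------------------
# GMT


def read_gmt(path) -> list:
    """Parse a GMT file: one ``name<TAB>description<TAB>gene...`` per line.

    Duplicate genes within a line are dropped (first occurrence kept)
    with a warning; a line with fewer than three fields is a format
    error naming the offending line.
    """
    signatures = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, "
                    "expected at least 3 (name, description, genes...)"
                )
            name, desc, genes = fields[0], fields[1], fields[2:]
            genes = [g for g in genes if g]
            seen, unique = set(), []
            for g in genes:
                if g in seen:
                    continue
                seen.add(g)
                unique.append(g)
            if len(unique) < len(genes):
                logger.warning(
                    "signature %r (%s:%d): %d duplicate gene(s) dropped",
                    name, path, lineno, len(genes) - len(unique),
                )
            signatures.append(GeneSignature(name, desc, tuple(unique)))
    return signatures


def write_gmt(signatures, path):
    with open(path, "w") as fh:
        for sig in signatures:
            fh.write("\t".join([sig.name, sig.description, *sig.genes]) + "\n")


# ---------------------------------------------------------------------------
# TSV tables


def _read_tsv(path, required) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    return df


def read_gene_annotation(path) -> pd.DataFrame:
    df = _read_tsv(path, ("gene_id", "chromosome", "start"))
    df["start"] = df["start"].astype(np.int64)
    return validate_annotation(df)


def read_centroid_model(path) -> CentroidModel:
    """Centroid TSV: first column gene identifiers, one column per subtype."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: centroid model needs >= 2 subtype columns")
    return CentroidModel(df.astype(float))


def read_ortholog_table(path) -> pd.DataFrame:
    df = _read_tsv(path, ("source_symbol", "target_symbol", "mapping_class"))
    return validate_ortholog_table(df)


def read_bulk_counts(path) -> CountMatrix:
    """Bulk genes × samples TSV: first column gene ids, header = sample ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] < 1:
        raise FormatError(f"{path}: bulk count table has no sample columns")
    vals = df.to_numpy()
    if np.any(vals < 0) or not np.allclose(vals, np.round(vals)):
        raise FormatError(f"{path}: bulk counts must be non-negative integers")
    return CountMatrix(
        sp.csr_matrix(vals.astype(np.int64)),
        pd.Index(df.index),
        pd.Index(df.columns),
    )


def write_bulk_counts(cm: CountMatrix, path):
    cm.to_frame().rename_axis("gene_id").to_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path):
    df.to_csv(path, sep="\t", index=False)
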