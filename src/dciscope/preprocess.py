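"""QC filtering, normalization, scaling, variable-gene selection and
marker-based cell typing.

The defaults reproduce the conventional droplet-scRNA-seq workflow:
genes kept if expressed in ≥3 cells, cells kept if they express ≥200
genes and carry ≤10% mitochondrial counts; library-size normalization to
10,000 counts followed by log1p; per-gene z-scoring clipped at ±10.
Cell-level filters run before the gene-level filter so that dying cells
cannot rescue genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import CountMatrix, NormalizedMatrix

__all__ = [
    "QCThresholds",
    "QCReport",
    "filter_qc",
    "lognormalize",
    "scale_genes",
    "select_hvg",
    "assign_cell_types",
]


@dataclass(frozen=True)
class QCThresholds:
    min_cells_per_gene: int = 3
    min_genes_per_cell: int = 200
    max_mito_percent: float = 10.0
    mito_gene_flags: tuple = ()  # gene ids; default: names prefixed "mt-"

    def __post_init__(self):
        if min(self.min_cells_per_gene, self.min_genes_per_cell) < 0:
            raise ValueError("QC thresholds must be non-negative")
        if not 0.0 <= self.max_mito_percent <= 100.0:
            raise ValueError("max_mito_percent must lie in [0, 100]")


@dataclass
class QCReport:
    n_cells_in: int
    n_genes_in: int
    cells_removed_low_genes: int
    cells_removed_high_mito: int
    genes_removed_low_cells: int
    removed_cells: pd.DataFrame  # cell_id, reason

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "metric": [
                    "cells_in", "genes_in", "cells_removed_low_genes",
                    "cells_removed_high_mito", "genes_removed_low_cells",
                ],
                "value": [
                    self.n_cells_in, self.n_genes_in,
                    self.cells_removed_low_genes, self.cells_removed_high_mito,
                    self.genes_removed_low_cells,
                ],
            }
        )


def _mito_mask(cm: CountMatrix, thresholds: QCThresholds) -> np.ndarray:
    if thresholds.mito_gene_flags:
        flags = pd.Index(thresholds.mito_gene_flags)
        unknown = flags.difference(cm.gene_ids)
        if len(unknown):
            raise ValueError(
                f"mito flags reference genes absent from the matrix: "
                f"{list(unknown[:5])}"
            )
        return cm.gene_ids.isin(flags)
    return cm.gene_ids.str.lower().str.startswith(("mt-", "mt."))


def filter_qc(cm: CountMatrix, thresholds: QCThresholds = QCThresholds()):
    """Remove low-complexity/high-mito cells, then rarely expressed genes.

    Returns ``(filtered, report)``. Cells failing either cell-level rule
    are removed first; the gene-level prevalence filter is computed on
    the surviving cells only.
    """
    X = cm.values.tocsc()
    mito = _mito_mask(cm, thresholds)

    genes_per_cell = np.asarray((X > 0).sum(axis=0)).ravel()
    totals = np.asarray(X.sum(axis=0)).ravel()
    mito_counts = np.asarray(X[np.flatnonzero(mito), :].sum(axis=0)).ravel() \
        if mito.any() else np.zeros(cm.n_cells)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_pct = np.where(totals > 0, 100.0 * mito_counts / totals, 0.0)

    low_genes = genes_per_cell < thresholds.min_genes_per_cell
    high_mito = mito_pct > thresholds.max_mito_percent
    keep_cells = ~(low_genes | high_mito)
    if not keep_cells.any():
        raise ValueError("QC filtering removed every cell")

    removed = []
    for cid, lg, hm in zip(cm.cell_ids, low_genes, high_mito):
        if lg:
            removed.append((cid, "low_gene_count"))
        elif hm:
            removed.append((cid, "high_mito_percent"))

    sub = X[:, np.flatnonzero(keep_cells)]
    cells_per_gene = np.asarray((sub > 0).sum(axis=1)).ravel()
    keep_genes = cells_per_gene >= thresholds.min_cells_per_gene
    if not keep_genes.any():
        raise ValueError("QC filtering removed every gene")

    filtered = CountMatrix(
        sp.csr_matrix(sub[np.flatnonzero(keep_genes), :]),
        cm.gene_ids[keep_genes],
        cm.cell_ids[keep_cells],
    )
    report = QCReport(
        n_cells_in=cm.n_cells,
        n_genes_in=cm.n_genes,
        cells_removed_low_genes=int(low_genes.sum()),
        cells_removed_high_mito=int((high_mito & ~low_genes).sum()),
        genes_removed_low_cells=int((~keep_genes).sum()),
        removed_cells=pd.DataFrame(removed, columns=["cell_id", "reason"]),
    )
    return filtered, report


def lognormalize(cm: CountMatrix, scale_factor: float = 1e4) -> NormalizedMatrix:
    """``ln(1 + count / cell_total × scale_factor)`` per entry."""
    totals = np.asarray(cm.values.sum(axis=0)).ravel()
    zero = totals == 0
    if zero.any():
        raise ValueError(
            f"cells with zero total counts: {list(cm.cell_ids[zero][:5])}"
        )
    X = cm.values.multiply(scale_factor / totals[None, :]).tocsr()
    X.data = np.log1p(X.data)
    dense = pd.DataFrame(
        X.toarray(), index=cm.gene_ids, columns=cm.cell_ids
    )
    return NormalizedMatrix(dense, kind="lognorm", scale_factor=scale_factor)


def scale_genes(norm: NormalizedMatrix, cap: float = 10.0) -> NormalizedMatrix:
    """Per-gene z-score across cells (sample SD, ddof=1), clipped at ±cap.

    Zero-variance genes become all-zero rows.
    """
    if norm.kind != "lognorm":
        raise ValueError("scale_genes expects a lognorm matrix")
    if cap <= 0:
        raise ValueError("cap must be positive")
    vals = norm.values.to_numpy()
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=1, keepdims=True) if vals.shape[1] > 1 else \
        np.zeros_like(mean)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (vals - mean) / sd, 0.0)
    z = np.clip(z, -cap, cap)
    return NormalizedMatrix(
        pd.DataFrame(z, index=norm.gene_ids, columns=norm.cell_ids),
        kind="scaled",
        scale_factor=norm.scale_factor,
    )


def select_hvg(matrix, n: int) -> pd.Index:
    """Top-``n`` highly variable genes by trend-standardized variance.

    A vst-style selection: a degree-2 polynomial of log10(variance) on
    log10(mean) is fit over expressed genes as the mean–variance trend;
    each gene's values are standardized by the trend SD, clipped at
    √N, and the variance of the clipped standardized values ranks the
    genes. Deterministic; ties broken by gene identifier.

    ``matrix`` may be a :class:`CountMatrix` (the conventional input) or
    a :class:`NormalizedMatrix`.
    """
    if isinstance(matrix, CountMatrix):
        vals = matrix.values.toarray().astype(float)
        genes = matrix.gene_ids
    else:
        vals = matrix.values.to_numpy()
        genes = matrix.gene_ids
    n_genes, n_cells = vals.shape
    if n > n_genes:
        raise ValueError(f"requested {n} HVGs from {n_genes} genes")

    mean = vals.mean(axis=1)
    var = vals.var(axis=1, ddof=1) if n_cells > 1 else np.zeros(n_genes)
    expressed = (mean > 0) & (var > 0)
    if expressed.sum() < 3:
        raise ValueError("too few expressed genes to fit a variance trend")

    coef = np.polyfit(
        np.log10(mean[expressed]), np.log10(var[expressed]), deg=2
    )
    sd_trend = np.sqrt(
        10 ** np.polyval(coef, np.log10(np.maximum(mean, 1e-12)))
    )
    clip = np.sqrt(n_cells)
    z = np.clip(
        (vals - mean[:, None]) / sd_trend[:, None], -clip, clip
    )
    std_var = z.var(axis=1, ddof=1) if n_cells > 1 else np.zeros(n_genes)
    std_var[~expressed] = 0.0

    order = pd.DataFrame({"v": std_var, "g": genes}).sort_values(
        ["v", "g"], ascending=[False, True], kind="mergesort"
    )
    return pd.Index(order["g"].iloc[:n])


def assign_cell_types(scaled: NormalizedMatrix, marker_signatures):
    """Label each cell with the argmax mean scaled marker expression.

    Returns ``(labels, scores)`` where ``scores`` is a cells × signatures
    frame of mean scaled expression. Ties go to the earlier signature.
    """
    if scaled.kind != "scaled":
        raise ValueError("assign_cell_types expects a scaled matrix")
    score_cols = {}
    for sig in marker_signatures:
        present = scaled.gene_ids.intersection(pd.Index(sig.genes))
        if len(present) == 0:
            raise ValueError(
                f"signature {sig.name!r} shares no genes with the matrix"
            )
        score_cols[sig.name] = scaled.values.loc[present].mean(axis=0)
    scores = pd.DataFrame(score_cols)
    # idxmax takes the first maximum -> ties break by signature order
    labels = scores.idxmax(axis=1)
    labels.name = "cell_type"
    return labels, scores
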