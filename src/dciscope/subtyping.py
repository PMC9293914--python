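"""Nearest-centroid molecular subtyping of bulk expression samples.

The PAM50-style procedure: gene-median-center the expression matrix,
then assign each sample the subtype whose centroid it correlates with
best over the shared genes. Spearman correlation is the default metric
(rank-based, robust to monotone transforms of the sample vector);
Pearson is available for sensitivity analysis. Centroid values are an
external input supplied as a genes × subtypes table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats

from .containers import CentroidModel

__all__ = ["median_center", "nearest_centroid"]


def median_center(matrix: pd.DataFrame) -> pd.DataFrame:
    """Subtract each gene's median across samples (idempotent)."""
    return matrix.sub(matrix.median(axis=1), axis=0)


def nearest_centroid(
    matrix: pd.DataFrame,
    model: CentroidModel,
    metric: str = "spearman",
    min_overlap: int | None = None,
) -> pd.DataFrame:
    """Correlate each sample with every centroid; label by argmax.

    ``min_overlap`` defaults to half the model's genes. Ties are broken
    by subtype order in the model and flagged in the ``tie`` column.
    Returns one row per sample with the call, every correlation, the
    margin (best minus second-best) and the overlap size.
    """
    if metric not in ("spearman", "pearson"):
        raise ValueError(f"unknown metric {metric!r}")
    if min_overlap is None:
        min_overlap = int(np.ceil(len(model.genes) / 2))
    shared = model.genes.intersection(matrix.index)
    if len(shared) < min_overlap:
        raise ValueError(
            f"only {len(shared)} genes shared with the centroid model "
            f"(minimum {min_overlap})"
        )
    expr = matrix.loc[shared].to_numpy()
    cent = model.centroids.loc[shared].to_numpy()
    if metric == "spearman":
        expr = scipy.stats.rankdata(expr, axis=0)
        cent = scipy.stats.rankdata(cent, axis=0)
    expr_c = expr - expr.mean(axis=0, keepdims=True)
    cent_c = cent - cent.mean(axis=0, keepdims=True)
    num = expr_c.T @ cent_c
    denom = np.outer(
        np.sqrt((expr_c ** 2).sum(axis=0)), np.sqrt((cent_c ** 2).sum(axis=0))
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(denom > 0, num / denom, 0.0)

    subtypes = list(model.subtypes)
    rows = []
    for i, sample in enumerate(matrix.columns):
        r = corr[i]
        best = int(np.argmax(r))  # argmax takes the first -> model order
        ordered = np.sort(r)[::-1]
        margin = float(ordered[0] - ordered[1]) if len(r) > 1 else 0.0
        tie = bool(np.sum(r == r[best]) > 1)
        row = {
            "sample_id": sample,
            "subtype": subtypes[best],
            "margin": margin,
            "n_genes_used": len(shared),
            "tie": tie,
        }
        row.update({f"r_{s}": float(r[j]) for j, s in enumerate(subtypes)})
        rows.append(row)
    return pd.DataFrame(rows)
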