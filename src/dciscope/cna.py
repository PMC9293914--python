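"""Copy-number-aberration profiles inferred from expression.

The transform follows the standard expression-based CNA inference recipe
for scRNA-seq: drop lowly expressed genes (mean log-normalized
expression below a cutoff), subtract the mean profile of presumed-diploid
reference cells, clip extreme residuals, average over a moving window of
genes ordered along each chromosome, and finally subtract each cell's
median so cells sit on a common baseline. The result is a genes × cells
matrix whose coherent stretches of positive (negative) values stand in
for copy gains (losses). Defaults: expression cutoff 0.1, window 101
genes, residual cap ±3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import NormalizedMatrix, validate_annotation

__all__ = [
    "CNAParams",
    "CNAProfileMatrix",
    "filter_by_mean_expression",
    "center_on_reference",
    "smooth_by_chromosome",
    "recenter_cells",
    "infer_cna_profiles",
]


@dataclass(frozen=True)
class CNAParams:
    expression_cutoff: float = 0.1
    window_length: int = 101
    max_centered_threshold: float = 3.0
    reference_cell_ids: tuple = ()

    def __post_init__(self):
        if self.window_length < 1 or self.window_length % 2 == 0:
            raise ValueError("window_length must be odd and >= 1")
        if self.expression_cutoff < 0:
            raise ValueError("expression_cutoff must be non-negative")
        if self.max_centered_threshold <= 0:
            raise ValueError("max_centered_threshold must be positive")


@dataclass
class CNAProfileMatrix:
    """Smoothed reference-relative profiles, genes ordered along the genome."""

    values: pd.DataFrame          # genes x cells
    gene_order: pd.DataFrame      # gene_id, chromosome, start (sorted)

    def __post_init__(self):
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("CNA profile contains non-finite values")

    @property
    def cell_ids(self) -> pd.Index:
        return self.values.columns

    def chromosome_blocks(self):
        """Yield (chromosome, row-slice) pairs in genome order."""
        chroms = self.gene_order["chromosome"].to_numpy()
        start = 0
        for i in range(1, len(chroms) + 1):
            if i == len(chroms) or chroms[i] != chroms[start]:
                yield chroms[start], slice(start, i)
                start = i


def filter_by_mean_expression(
    norm: NormalizedMatrix, cutoff: float = 0.1
) -> pd.Index:
    """Genes whose mean log-normalized expression across cells ≥ cutoff."""
    if norm.kind != "lognorm":
        raise ValueError("expression filtering expects a lognorm matrix")
    means = norm.values.mean(axis=1)
    keep = means.index[means >= cutoff]
    if len(keep) == 0:
        raise ValueError("no genes survive the mean-expression cutoff")
    return keep


def center_on_reference(
    norm: NormalizedMatrix, params: CNAParams
) -> pd.DataFrame:
    """Subtract the reference-cell mean per gene; clip at ±threshold."""
    ref = norm.cell_ids.intersection(pd.Index(params.reference_cell_ids))
    if len(ref) == 0:
        raise ValueError("reference cell set is empty after intersection")
    ref_mean = norm.values[ref].mean(axis=1)
    centered = norm.values.sub(ref_mean, axis=0)
    t = params.max_centered_threshold
    return centered.clip(lower=-t, upper=t)


def _window_means(block: np.ndarray, window: int) -> np.ndarray:
    """Moving average along axis 0 with edge truncation (shorter windows
    at chromosome ends), exact via cumulative sums."""
    n = block.shape[0]
    half = window // 2
    cs = np.vstack([np.zeros((1, block.shape[1])), np.cumsum(block, axis=0)])
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half, n - 1) + 1
    sums = cs[hi] - cs[lo]
    return sums / (hi - lo)[:, None]


def smooth_by_chromosome(
    centered: pd.DataFrame,
    annotation: pd.DataFrame,
    window: int = 101,
    strict: bool = True,
) -> CNAProfileMatrix:
    """Chromosome-wise moving average over genes sorted by start coordinate.

    Windows are truncated at chromosome boundaries; chromosomes are
    never mixed. Genes without an annotation row raise in strict mode
    and are dropped with a warning otherwise.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    annotation = validate_annotation(annotation)
    ann = annotation.set_index("gene_id")
    missing = centered.index.difference(ann.index)
    if len(missing):
        if strict:
            raise ValueError(
                f"genes without annotation: {list(missing[:10])}"
                + ("..." if len(missing) > 10 else "")
            )
        import logging

        logging.getLogger(__name__).warning(
            "dropping %d unannotated gene(s)", len(missing)
        )
        centered = centered.drop(index=missing)
    ann = ann.loc[centered.index]
    order = ann.sort_values(
        ["chromosome", "start"], kind="mergesort"
    ).index
    ordered = centered.loc[order]
    gene_order = (
        ann.loc[order]
        .reset_index()
        .rename(columns={"index": "gene_id"})[["gene_id", "chromosome", "start"]]
    )

    vals = ordered.to_numpy(copy=True)
    chroms = gene_order["chromosome"].to_numpy()
    start = 0
    for i in range(1, len(chroms) + 1):
        if i == len(chroms) or chroms[i] != chroms[start]:
            vals[start:i] = _window_means(vals[start:i], window)
            start = i
    return CNAProfileMatrix(
        pd.DataFrame(vals, index=order, columns=ordered.columns), gene_order
    )


def recenter_cells(profiles: CNAProfileMatrix) -> CNAProfileMatrix:
    """Subtract each cell's median so every column is centered at zero."""
    vals = profiles.values
    centered = vals.sub(vals.median(axis=0), axis=1)
    return CNAProfileMatrix(centered, profiles.gene_order.copy())


def infer_cna_profiles(
    norm: NormalizedMatrix,
    annotation: pd.DataFrame,
    params: CNAParams,
    strict: bool = True,
    sample_labels: pd.Series | None = None,
) -> CNAProfileMatrix:
    """Full chain: expression filter → reference-center+clip → smooth →
    per-cell median recentering.

    With ``sample_labels`` (cell id → sample id) the residuals are
    additionally centered per sample: after the reference-mean
    subtraction, each sample's per-gene mean residual is removed from
    that sample's cells. This absorbs systematic inter-sample offsets
    against the reference (which typically comes from a different
    experiment) at the cost of making profiles relative to the sample
    average — aberrations shared by every cell of a sample cancel, and
    normal cells show the mirror image of the aberrations carried by the
    sample's malignant cells. Reference columns are retained in the
    output so correlation references can be built from them downstream.
    """
    keep = filter_by_mean_expression(norm, params.expression_cutoff)
    sub = NormalizedMatrix(
        norm.values.loc[keep], kind="lognorm", scale_factor=norm.scale_factor
    )
    ref = sub.cell_ids.intersection(pd.Index(params.reference_cell_ids))
    if len(ref) == 0:
        raise ValueError("reference cell set is empty after intersection")
    centered = sub.values.sub(sub.values[ref].mean(axis=1), axis=0)
    if sample_labels is not None:
        lab = sample_labels.loc[centered.columns]
        for sample in lab.unique():
            cols = centered.columns[(lab == sample).to_numpy()]
            centered[cols] = centered[cols].sub(
                centered[cols].mean(axis=1), axis=0
            )
    t = params.max_centered_threshold
    centered = centered.clip(lower=-t, upper=t)
    smoothed = smooth_by_chromosome(
        centered, annotation, params.window_length, strict=strict
    )
    return recenter_cells(smoothed)
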