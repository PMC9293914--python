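"""High-level chains combining the modules into the standard analyses."""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .classify import ClassifierParams, call_malignant_cells
from .cna import CNAParams, infer_cna_profiles
from .containers import CountMatrix
from .preprocess import QCThresholds, filter_qc, lognormalize

__all__ = ["concat_samples", "malignancy_analysis"]


def concat_samples(samples: dict) -> tuple:
    """Column-concatenate per-sample count matrices sharing a gene index.

    Returns ``(matrix, sample_labels)`` where ``sample_labels`` maps each
    cell id to its sample id.
    """
    if not samples:
        raise ValueError("no samples given")
    items = list(samples.items())
    genes = items[0][1].gene_ids
    for sid, cm in items[1:]:
        if not cm.gene_ids.equals(genes):
            raise ValueError(f"sample {sid!r} has a different gene index")
    mat = sp.hstack([cm.values for _, cm in items]).tocsr()
    cells = pd.Index(np.concatenate([cm.cell_ids for _, cm in items]))
    labels = pd.Series(
        np.concatenate([[sid] * cm.n_cells for sid, cm in items]),
        index=cells,
        name="sample_id",
    )
    return CountMatrix(mat, genes, cells), labels


def malignancy_analysis(
    samples: dict,
    annotation: pd.DataFrame,
    cell_types: pd.Series,
    reference_sample: str,
    epithelial_label: str = "epithelial",
    qc: QCThresholds = QCThresholds(),
    cna_params: CNAParams | None = None,
    classifier_params: ClassifierParams = ClassifierParams(),
):
    """QC → log-normalize → CNA profiles → dual-correlation calls.

    ``cell_types`` maps cell id to a type label (from marker-based
    typing or prior annotation); epithelial cells of ``reference_sample``
    serve as the diploid reference, epithelial cells of every other
    sample are the classification candidates, classified per sample with
    per-sample residual centering. Returns ``(calls, profiles, report)``.
    """
    combined, sample_labels = concat_samples(samples)
    filtered, report = filter_qc(combined, qc)
    norm = lognormalize(filtered)
    kept = filtered.cell_ids
    sample_labels = sample_labels.loc[kept]
    types = cell_types.loc[kept]

    is_epi = (types == epithelial_label).to_numpy()
    in_ref = (sample_labels == reference_sample).to_numpy()
    reference_cells = kept[is_epi & in_ref]
    candidates = kept[is_epi & ~in_ref]
    if len(reference_cells) == 0:
        raise ValueError("no epithelial cells in the reference sample")
    if len(candidates) == 0:
        raise ValueError("no candidate epithelial cells outside the reference")

    params = cna_params or CNAParams()
    params = CNAParams(
        params.expression_cutoff,
        params.window_length,
        params.max_centered_threshold,
        tuple(reference_cells),
    )
    profiles = infer_cna_profiles(
        norm, annotation, params, sample_labels=sample_labels
    )
    calls = call_malignant_cells(
        profiles,
        candidates,
        params=classifier_params,
        sample_labels=sample_labels,
    )
    return calls, profiles, report
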