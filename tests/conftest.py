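import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from dciscope import lognormalize, scale_genes, synthetic
from dciscope.pipeline import concat_samples

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_run():
    """Standard staged-progression simulation with preprocessing applied."""
    config = synthetic.default_config(seed=11, cells_per_replicate=300)
    samples, annotation, truth = synthetic.simulate_experiment(config)
    counts, sample_labels = concat_samples(samples)
    norm = lognormalize(counts)
    scaled = scale_genes(norm)
    return {
        "config": config,
        "samples": samples,
        "annotation": annotation,
        "truth": truth.set_index("cell_id"),
        "counts": counts,
        "sample_labels": sample_labels,
        "norm": norm,
        "scaled": scaled,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def classifier_chain_metrics(
    seed,
    with_segments=True,
    n_cells=3000,
    n_reference_cells=500,
    multiplier=None,
):
    """Run the full CNA → dual-correlation chain on the standard
    tumor-plus-reference scenario and score the calls against truth.

    ``multiplier`` overrides the planted gain (the loss becomes its
    reciprocal), for dose-response checks.
    """
    import dataclasses

    from dciscope.pipeline import malignancy_analysis

    config = synthetic.classifier_config(
        seed=seed,
        n_cells=n_cells,
        with_segments=with_segments,
        n_reference_cells=n_reference_cells,
    )
    if multiplier is not None:
        config = dataclasses.replace(
            config,
            cna_segments=(
                synthetic.CNASegment("chr1", 0, 200, multiplier),
                synthetic.CNASegment("chr3", 0, 200, 1.0 / multiplier),
            ),
        )
    samples, annotation, truth = synthetic.simulate_experiment(config)
    truth = truth.set_index("cell_id")
    calls, _, _ = malignancy_analysis(
        samples, annotation, truth["cell_type"], "normalref_rep1"
    )
    calls = calls.set_index("cell_id")
    predicted = (calls["call"] == "malignant").to_numpy()
    actual = truth.loc[calls.index, "is_malignant"].to_numpy()
    tp = (predicted & actual).sum()
    tn = (~predicted & ~actual).sum()
    phi = (
        np.corrcoef(predicted.astype(float), actual.astype(float))[0, 1]
        if predicted.any() and not predicted.all()
        else 0.0
    )
    return {
        "sensitivity": tp / actual.sum(),
        "specificity": tn / (~actual).sum(),
        "phi": float(phi),
        "fraction_called": float(predicted.mean()),
        "n_candidates": int(len(calls)),
    }


def toy_norm_matrix(values, genes=None, cells=None, kind="lognorm"):
    """Small dense NormalizedMatrix from a nested list."""
    from dciscope.containers import NormalizedMatrix

    arr = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    cells = cells or [f"c{i}" for i in range(arr.shape[1])]
    return NormalizedMatrix(
        pd.DataFrame(arr, index=genes, columns=cells), kind=kind
    )
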