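"""Molecular subtyping of bulk expression samples by nearest centroid.

Simulates two-subtype bulk RNA-seq counts, applies upper-quartile
normalization, log2 transform and gene-median centering, then assigns
each sample the subtype whose centroid it rank-correlates with best.
"""

from dciscope import bulk_prepare, nearest_centroid, synthetic

config = synthetic.BulkConfig(
    n_genes=500,
    subtypes=(
        synthetic.BulkSubtype("basal", tuple(f"g{i:04d}" for i in range(50)), 4.0),
        synthetic.BulkSubtype(
            "luminal", tuple(f"g{i:04d}" for i in range(50, 100)), 4.0
        ),
    ),
    n_samples_per_subtype=10,
    seed=0,
)
counts, truth = synthetic.simulate_bulk(config)
model = synthetic.derive_centroids(config)  # stands in for an external predictor

prepared = bulk_prepare(counts)            # UQ normalize, log2, median center
calls = nearest_centroid(prepared.values, model, metric="spearman")

called = calls.set_index("sample_id")["subtype"]
accuracy = (called.loc[truth.index] == truth).mean()
print(calls[["sample_id", "subtype", "r_basal", "r_luminal", "margin"]]
      .round(3).head(6).to_string(index=False))
print(f"\naccuracy against truth labels: {accuracy:.2f} "
      f"({len(calls)} samples)")
# The margin (best minus second-best correlation) measures call
# confidence; with 50-gene subtype programs at 4-fold the calls are
# unambiguous and recovery is perfect.
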