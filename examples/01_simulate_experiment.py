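"""Simulate a staged tumor-progression scRNA-seq experiment.

Builds the standard three-state design (prepuberty → DCIS-like → tumor,
two replicates each), draws negative-binomial counts with planted
copy-number segments and signature programs, and prints what the ground
truth contains.
"""

from dciscope import synthetic

config = synthetic.default_config(seed=0, cells_per_replicate=400)
samples, annotation, truth = synthetic.simulate_experiment(config)

print(f"samples: {list(samples)}")
first = next(iter(samples.values()))
print(f"each matrix: {first.n_genes} genes x {first.n_cells} cells (sparse counts)")
print(f"annotation rows: {len(annotation)} (gene, chromosome, start)")
print("\ncells per state and type:")
print(truth.groupby(["state", "cell_type"]).size().unstack(fill_value=0))
print("\nmalignant cells per state (epithelial cells carrying the planted "
      "1.5x gain on chr1 and 0.5x loss on chr3):")
print(truth.groupby("state")["is_malignant"].sum())
# The truth table is the reference for every recovery test downstream:
# cell type, malignancy, dying-cell flag and active expression programs.
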