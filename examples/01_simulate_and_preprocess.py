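"""Simulate a multi-cell-type scRNA-seq count matrix and preprocess it.

Builds the default synthetic dataset (2000 cells x 200 genes, three cell
types of which one is rare), applies the standard filter (cells with < 10
counts, genes detected in < 3 cells) and log-normalization (10,000 counts
per cell, then log1p), and prints summary statistics.
"""

import numpy as np

from scdiffuse import FixtureSpec, simulate_counts, filter_cells_genes, normalize_log

spec = FixtureSpec(seed=0)
raw = simulate_counts(spec)
print(f"simulated: {raw.n_cells} cells x {raw.n_genes} genes")
print("cell types:", raw.cell_labels["cell_type"].value_counts().to_dict())
print(f"zero fraction: {float((raw.values == 0).mean()):.3f} "
      "(typical sparsity for counts at these depths)")

filtered = filter_cells_genes(raw)
print(f"after filtering: {filtered.n_cells} cells x {filtered.n_genes} genes")

lognorm = normalize_log(filtered)
print(f"log-normalized values span [0, {lognorm.values.max():.2f}]; "
      "each cell now sums to 1e4 counts before log1p")
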