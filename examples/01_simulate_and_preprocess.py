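"""Simulate a multi-batch dataset and run the preprocessing chain.

Generates a closed-set dataset (3 batches, 4 cell types, known gene-wise
multiplicative batch distortions), then filters, normalizes, log-transforms
and builds the cross-batch same-type connectivity graph.
"""

import numpy as np

from imaae import PipelineConfig, SimulationConfig, preprocess_pipeline, simulate_counts
from imaae.evaluate import asw, top_pcs

cfg = SimulationConfig(scenario="closed", seed=0)
m = simulate_counts(cfg)
print(f"simulated: {m.n_cells} cells x {m.n_genes} genes, "
      f"batches={m.batches()}, types={m.cell_types()}")

prep, graph = preprocess_pipeline(
    m, PipelineConfig(min_genes_per_cell=50, min_cells_per_gene=3, n_pcs_graph=20)
)
print(f"preprocessed: {prep.n_cells} cells x {prep.n_genes} genes "
      f"(layer={prep.layer_tag}), graph edges={len(graph.edges)}")

emb = top_pcs(np.asarray(prep.values, float), 50)
print(f"batch silhouette before correction: {asw(emb, prep.batch):.3f}")
print("-> a clearly positive value: the batches are separated in expression "
      "space before any correction, which is the planted batch effect.")
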