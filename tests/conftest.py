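import numpy as np
import pytest

from imaae import (
    AnnotatedMatrix,
    PipelineConfig,
    SimulationConfig,
    preprocess_pipeline,
    simulate_counts,
)

# small-data preprocessing thresholds used throughout the suite
SMALL_PREP = dict(min_genes_per_cell=5, min_cells_per_gene=2, n_hvg=2000, n_pcs_graph=10)


@pytest.fixture
def tiny_matrix() -> AnnotatedMatrix:
    """6 cells x 4 genes, 2 batches, 2 shared types, hand-written counts."""
    values = np.array(
        [
            [5, 0, 2, 1],
            [4, 1, 0, 2],
            [0, 6, 1, 3],
            [6, 0, 3, 0],
            [3, 2, 1, 1],
            [0, 5, 2, 2],
        ],
        dtype=np.int64,
    )
    return AnnotatedMatrix(
        values=values,
        cell_ids=np.array([f"c{i}" for i in range(6)], dtype=object),
        gene_ids=np.array(["g0", "g1", "g2", "g3"], dtype=object),
        batch=np.array(["b0", "b0", "b0", "b1", "b1", "b1"], dtype=object),
        cell_type=np.array(["A", "A", "B", "A", "A", "B"], dtype=object),
        layer_tag="raw_counts",
    )


@pytest.fixture(scope="session")
def sim_small() -> AnnotatedMatrix:
    """Closed-set simulation small enough for fast training tests."""
    cfg = SimulationConfig(
        n_batches=2,
        cell_types=["t0", "t1", "t2"],
        scenario="closed",
        cells_per_type_per_batch=40,
        n_genes=120,
        batch_effect_sigma=0.8,
        library_size_mean=1200.0,
        seed=7,
    )
    return simulate_counts(cfg)


@pytest.fixture(scope="session")
def prepped_small(sim_small):
    cfg = PipelineConfig(min_genes_per_cell=20, min_cells_per_gene=3, n_hvg=2000, n_pcs_graph=15, graph_k=5)
    return preprocess_pipeline(sim_small, cfg)
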