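"""Preprocessing chain: filter -> HVG -> normalize -> log1p -> PCA -> graph.

The chain follows the standard single-cell recipe.  Cells expressing fewer
than ``min_genes_per_cell`` genes and genes expressed in fewer than
``min_cells_per_gene`` cells are removed first; a dispersion-based
highly-variable-gene selection restricts the matrix; each surviving cell is
scaled to a common total count and log1p-transformed.  PCA and the
cross-batch same-type mutual-nearest-neighbour graph are optional: when the
graph is skipped, downstream anchor mapping falls back to random same-type
pairing, which mixes batches more aggressively at the cost of batch-specific
substructure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .datamodel import AnnotatedMatrix, PipelineConfig


@dataclass
class PCAResult:
    """Mean-centred principal component analysis of a cells × genes matrix."""

    embedding: np.ndarray          # cells x n_components
    components: np.ndarray         # n_components x genes, orthonormal rows
    explained_variance: np.ndarray # non-increasing
    mean: np.ndarray               # per-gene centre used


@dataclass
class ConnectivityGraph:
    """Cross-batch same-type mutual nearest-neighbour edges.

    ``edges`` holds unordered cell-index pairs (i < j); ``metadata`` records,
    per edge, the two batch labels and the shared cell type.
    """

    edges: list[tuple[int, int]]
    metadata: list[tuple[str, str, str]]

    def neighbors(self) -> dict[int, list[int]]:
        out: dict[int, list[int]] = {}
        for i, j in self.edges:
            out.setdefault(i, []).append(j)
            out.setdefault(j, []).append(i)
        return out


def filter_cells_genes(
    m: AnnotatedMatrix, min_genes_per_cell: int = 600, min_cells_per_gene: int = 3
) -> AnnotatedMatrix:
    """Drop low-coverage cells, then genes rarely seen in the surviving cells.

    A cell is kept when it expresses (count > 0) at least ``min_genes_per_cell``
    genes of the *original* gene set; a gene is kept when it is expressed in at
    least ``min_cells_per_gene`` of the *retained* cells.  Order is preserved.
    """
    if m.layer_tag != "raw_counts":
        raise ValueError("filtering operates on raw counts")
    expressed = m.values > 0
    cell_mask = expressed.sum(axis=1) >= min_genes_per_cell
    if not cell_mask.any():
        raise ValueError(
            f"all {m.n_cells} cells express fewer than {min_genes_per_cell} genes; "
            "lower min_genes_per_cell"
        )
    gene_mask = expressed[cell_mask].sum(axis=0) >= min_cells_per_gene
    return m.subset_cells(cell_mask).subset_genes(gene_mask)


def select_hvg(m: AnnotatedMatrix, n_hvg: int = 2000, target_sum: float = 20000.0) -> AnnotatedMatrix:
    """Restrict to the ``n_hvg`` most variable genes, preserving gene order.

    The dispersion statistic (variance/mean of log-normalized expression,
    z-scored within 20 mean bins) is computed on a temporarily normalized and
    log-transformed copy; the returned matrix keeps the input's layer (the raw
    counts are subset, not transformed).
    """
    if n_hvg > m.n_genes:
        raise ValueError(f"n_hvg={n_hvg} exceeds gene count {m.n_genes}")
    if n_hvg == m.n_genes:
        return m
    import scanpy as sc

    ad = m.to_anndata()
    ad.X = ad.X.astype(np.float64)
    sc.pp.normalize_total(ad, target_sum=target_sum)
    sc.pp.log1p(ad)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sc.pp.highly_variable_genes(ad, flavor="seurat", n_top_genes=n_hvg)
    mask = np.asarray(ad.var["highly_variable"], dtype=bool)
    # scanpy can return a few more/less genes on ties; enforce exactly n_hvg
    if mask.sum() != n_hvg:
        disp = np.asarray(ad.var["dispersions_norm"], dtype=float)
        disp = np.where(np.isfinite(disp), disp, -np.inf)
        order = np.argsort(-disp, kind="stable")[:n_hvg]
        mask = np.zeros(m.n_genes, dtype=bool)
        mask[order] = True
    return m.subset_genes(mask)


def normalize_total(m: AnnotatedMatrix, target_sum: float = 20000.0) -> AnnotatedMatrix:
    """Scale every cell so its total count equals ``target_sum``."""
    totals = np.asarray(m.values, dtype=float).sum(axis=1)
    if np.any(totals <= 0):
        bad = np.flatnonzero(totals <= 0)[0]
        raise ValueError(
            f"cell {m.cell_ids[bad]!r} has zero total count; filter cells first"
        )
    scaled = np.asarray(m.values, dtype=float) * (target_sum / totals)[:, None]
    return m.with_values(scaled, layer_tag="normalized")


def log1p_transform(m: AnnotatedMatrix) -> AnnotatedMatrix:
    """Elementwise natural log of (value + 1); zeros stay zero."""
    vals = np.asarray(m.values, dtype=float)
    if vals.size and vals.min() < 0:
        raise ValueError("log1p requires non-negative values")
    return m.with_values(np.log1p(vals), layer_tag="lognormalized")


def compute_pca(m: AnnotatedMatrix | np.ndarray, n_components: int) -> PCAResult:
    """Mean-centred PCA (no variance scaling) of log-normalized expression."""
    X = m.values if isinstance(m, AnnotatedMatrix) else np.asarray(m)
    X = np.asarray(X, dtype=float)
    if isinstance(m, AnnotatedMatrix) and m.layer_tag != "lognormalized":
        raise ValueError("PCA expects log-normalized values")
    n, g = X.shape
    if n_components > min(n, g):
        raise ValueError(f"n_components={n_components} exceeds min(cells, genes)={min(n, g)}")
    from sklearn.decomposition import PCA

    pca = PCA(n_components=n_components, svd_solver="full")
    emb = pca.fit_transform(X)
    return PCAResult(
        embedding=emb,
        components=pca.components_,
        explained_variance=pca.explained_variance_,
        mean=pca.mean_,
    )


def build_cross_batch_graph(
    pca: PCAResult | np.ndarray,
    batch: np.ndarray,
    cell_type: np.ndarray,
    k: int = 5,
) -> ConnectivityGraph:
    """Mutual k-nearest-neighbour graph between same-type cells of different batches.

    For every ordered pair of distinct batches (A, B) and every cell type
    present in both, each type-t cell of A is linked to its ``k`` nearest
    (Euclidean, in PCA space) type-t cells of B; an edge is kept only when the
    relation is mutual.  Distance ties break toward the lower cell index.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    emb = pca.embedding if isinstance(pca, PCAResult) else np.asarray(pca, dtype=float)
    batch = np.asarray(batch, dtype=object)
    cell_type = np.asarray(cell_type, dtype=object)
    batches = list(dict.fromkeys(batch))
    edges: set[tuple[int, int]] = set()
    meta: dict[tuple[int, int], tuple[str, str, str]] = {}
    warned = False
    for bi in range(len(batches)):
        for bj in range(bi + 1, len(batches)):
            A, B = batches[bi], batches[bj]
            types = set(cell_type[batch == A]) & set(cell_type[batch == B])
            for t in sorted(types, key=str):
                ia = np.flatnonzero((batch == A) & (cell_type == t))
                ib = np.flatnonzero((batch == B) & (cell_type == t))
                ka = min(k, len(ib))
                kb = min(k, len(ia))
                if (ka < k or kb < k) and not warned:
                    warnings.warn(
                        f"k={k} capped to candidate count for type {t!r} "
                        f"between batches {A!r} and {B!r}"
                    )
                    warned = True
                d = np.linalg.norm(emb[ia][:, None, :] - emb[ib][None, :, :], axis=2)
                # stable argsort breaks distance ties toward the lower index
                nn_ab = np.argsort(d, axis=1, kind="stable")[:, :ka]   # for each a, cols of b
                nn_ba = np.argsort(d.T, axis=1, kind="stable")[:, :kb] # for each b, rows of a
                ba_sets = [set(row) for row in nn_ba]
                for ai in range(len(ia)):
                    for bj_local in nn_ab[ai]:
                        if ai in ba_sets[bj_local]:
                            i, j = int(ia[ai]), int(ib[bj_local])
                            e = (min(i, j), max(i, j))
                            edges.add(e)
                            meta[e] = (str(A), str(B), str(t))
    ordered = sorted(edges)
    return ConnectivityGraph(edges=ordered, metadata=[meta[e] for e in ordered])


def preprocess_pipeline(
    m: AnnotatedMatrix, config: PipelineConfig | None = None, build_graph: bool | None = None
) -> tuple[AnnotatedMatrix, ConnectivityGraph | None]:
    """Run the full chain on raw counts; returns the log-normalized matrix and,
    optionally, the cross-batch connectivity graph."""
    cfg = config or PipelineConfig()
    if build_graph is None:
        build_graph = cfg.use_graph_mapping
    m = filter_cells_genes(m, cfg.min_genes_per_cell, cfg.min_cells_per_gene)
    if cfg.n_hvg < m.n_genes:
        m = select_hvg(m, cfg.n_hvg, cfg.target_sum)
    m = log1p_transform(normalize_total(m, cfg.target_sum))
    graph = None
    if build_graph:
        n_pcs = min(cfg.n_pcs_graph, m.n_cells, m.n_genes)
        pca = compute_pca(m, n_pcs)
        graph = build_cross_batch_graph(pca, m.batch, m.cell_type, cfg.graph_k)
    return m, graph
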