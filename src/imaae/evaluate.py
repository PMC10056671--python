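"""Integration quality metrics: silhouette, ARI, NMI and their F1 combinations.

The protocol: restrict to cell types present in *every* batch, take the top
50 principal components of the corrected expression matrix, then score both
label axes.  Batch-axis scores should be low after good integration (batches
indistinguishable); cell-type-axis scores should stay high (biology
preserved).  Each metric family is folded into a single number by the
harmonic-style combination

    F1 = 2 * (1 - S_batch) * S_celltype / ((1 - S_batch) + S_celltype)

so that higher is better on both axes at once.

ARI and NMI need a partition to compare against each label axis; it is
produced by k-means (k-means++ init, 10 restarts, fixed seed) on the same
50-PC embedding with k equal to the number of classes on the scored axis.
NMI uses arithmetic-mean entropy normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score, silhouette_score

from .correct import CorrectionResult
from .preprocess import compute_pca


@dataclass
class MetricReport:
    asw_batch: float
    asw_celltype: float
    ari_batch: float
    ari_celltype: float
    nmi_batch: float
    nmi_celltype: float
    f1_asw: float
    f1_ari: float
    f1_nmi: float
    n_cells_evaluated: int
    celltypes_used: list

    def to_dict(self) -> dict:
        return asdict(self)


def restrict_cooccurring(
    values: np.ndarray, batch: np.ndarray, cell_type: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list]:
    """Keep only cells whose type occurs in every batch."""
    batch = np.asarray(batch, dtype=object)
    cell_type = np.asarray(cell_type, dtype=object)
    batches = list(dict.fromkeys(batch))
    if len(batches) < 2:
        raise ValueError("need at least two batches to evaluate integration")
    shared = set(cell_type)
    for b in batches:
        shared &= set(cell_type[batch == b])
    if not shared:
        raise ValueError("no cell type is present in every batch")
    mask = np.asarray([t in shared for t in cell_type], dtype=bool)
    return values[mask], batch[mask], cell_type[mask], sorted(shared, key=str)


def top_pcs(corrected_expression: np.ndarray, n: int = 50) -> np.ndarray:
    """Top-``n`` principal components of a corrected expression matrix."""
    X = np.asarray(corrected_expression, dtype=float)
    n = min(n, min(X.shape))
    return compute_pca(X, n).embedding


def asw(embedding: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette coefficient (Euclidean) of ``labels`` on ``embedding``."""
    labels = np.asarray(labels)
    if len(set(map(str, labels))) < 2:
        raise ValueError("silhouette needs at least two distinct labels")
    return float(silhouette_score(np.asarray(embedding, dtype=float), labels.astype(str)))


def ari(labels_a: np.ndarray, labels_b: np.ndarray) -> float:
    """Adjusted Rand index between two partitions."""
    if len(labels_a) != len(labels_b):
        raise ValueError("label vectors must have equal length")
    return float(adjusted_rand_score(np.asarray(labels_a).astype(str), np.asarray(labels_b).astype(str)))


def nmi(labels_a: np.ndarray, labels_b: np.ndarray) -> float:
    """Normalized mutual information (arithmetic-mean entropy normalization)."""
    if len(labels_a) != len(labels_b):
        raise ValueError("label vectors must have equal length")
    return float(
        normalized_mutual_info_score(
            np.asarray(labels_a).astype(str),
            np.asarray(labels_b).astype(str),
            average_method="arithmetic",
        )
    )


def cluster_for_label_metrics(embedding: np.ndarray, k: int, seed: int = 0) -> np.ndarray:
    """k-means partition (k-means++ init, 10 restarts, fixed seed) of the embedding."""
    embedding = np.asarray(embedding, dtype=float)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > embedding.shape[0]:
        raise ValueError(f"k={k} exceeds the number of cells {embedding.shape[0]}")
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed)
    return km.fit_predict(embedding)


def f1_combine(score_batch: float, score_celltype: float) -> float:
    """Fold a (batch, cell-type) score pair into one number; higher is better."""
    denom = (1.0 - score_batch) + score_celltype
    if denom == 0:
        raise ValueError("degenerate score pair: (1 - batch) + celltype is zero")
    return 2.0 * (1.0 - score_batch) * score_celltype / denom


def evaluate_all(
    corrected: CorrectionResult | np.ndarray,
    batch: np.ndarray,
    cell_type: np.ndarray,
    n_pcs: int = 50,
    seed: int = 0,
) -> MetricReport:
    """Full protocol: co-occurring restriction -> top PCs -> ASW/ARI/NMI -> F1."""
    X = corrected.corrected_expression if isinstance(corrected, CorrectionResult) else corrected
    Xr, batch_r, type_r, shared = restrict_cooccurring(np.asarray(X, dtype=float), batch, cell_type)
    emb = top_pcs(Xr, n_pcs)
    asw_b = asw(emb, batch_r)
    asw_t = asw(emb, type_r)
    k_b = len(set(map(str, batch_r)))
    k_t = len(set(map(str, type_r)))
    part_b = cluster_for_label_metrics(emb, k_b, seed)
    part_t = cluster_for_label_metrics(emb, k_t, seed)
    ari_b = ari(part_b, batch_r)
    ari_t = ari(part_t, type_r)
    nmi_b = nmi(part_b, batch_r)
    nmi_t = nmi(part_t, type_r)
    return MetricReport(
        asw_batch=asw_b,
        asw_celltype=asw_t,
        ari_batch=ari_b,
        ari_celltype=ari_t,
        nmi_batch=nmi_b,
        nmi_celltype=nmi_t,
        f1_asw=f1_combine(asw_b, asw_t),
        f1_ari=f1_combine(ari_b, ari_t),
        f1_nmi=f1_combine(nmi_b, nmi_t),
        n_cells_evaluated=int(Xr.shape[0]),
        celltypes_used=[str(t) for t in shared],
    )
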