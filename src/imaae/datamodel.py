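"""Annotated expression-matrix data model and its on-disk formats.

The in-memory carrier for the whole pipeline is :class:`AnnotatedMatrix`: a
dense cells × genes matrix plus per-cell batch and cell-type labels.  Three
interchange formats are supported:

``mtx_dir``
    A directory holding ``matrix.mtx`` (MatrixMarket triplets), ``barcodes.tsv``
    (cell ids), ``features.tsv`` (gene ids) and ``labels.tsv`` (cell id, batch,
    cell type).  On-disk orientation follows the 10x convention of genes × cells
    unless an explicit orientation argument says otherwise.

``delimited``
    A single delimited text file: header row of gene ids, first column the cell
    id, one row per cell; labels in a ``<name>.labels.tsv`` sidecar keyed by
    cell id.

``h5_container``
    An ``.h5ad`` annotated-matrix container with labels stored under the
    conventional ``obs`` keys ``batch`` and ``cell_type``.
"""

from __future__ import annotations

import os
import tomllib
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import yaml

LayerTag = Literal["raw_counts", "normalized", "lognormalized"]
_LAYER_TAGS = ("raw_counts", "normalized", "lognormalized")

Format = Literal["mtx_dir", "delimited", "h5_container"]


@dataclass
class AnnotatedMatrix:
    """Cells × genes expression values with batch and cell-type annotation.

    Parameters
    ----------
    values
        Non-negative expression matrix, one row per cell.
    cell_ids, gene_ids
        Unique string identifiers for rows and columns.
    batch, cell_type
        Categorical label per cell.
    layer_tag
        Which processing layer the values live on: ``raw_counts``,
        ``normalized`` (library-size scaled) or ``lognormalized`` (log1p of
        normalized).
    """

    values: np.ndarray
    cell_ids: np.ndarray
    gene_ids: np.ndarray
    batch: np.ndarray
    cell_type: np.ndarray
    layer_tag: str = "raw_counts"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.batch = np.asarray(self.batch, dtype=object)
        self.cell_type = np.asarray(self.cell_type, dtype=object)
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        n, g = self.values.shape
        if not (len(self.cell_ids) == len(self.batch) == len(self.cell_type) == n):
            raise ValueError(
                f"row annotation length mismatch: {n} cells but "
                f"{len(self.cell_ids)} ids / {len(self.batch)} batch / "
                f"{len(self.cell_type)} cell_type labels"
            )
        if len(self.gene_ids) != g:
            raise ValueError(f"{g} columns but {len(self.gene_ids)} gene ids")
        if self.layer_tag not in _LAYER_TAGS:
            raise ValueError(f"unknown layer_tag {self.layer_tag!r}")
        if self.values.size:
            if not np.all(np.isfinite(self.values.astype(float))):
                raise ValueError("expression values must be finite")
            if float(self.values.min()) < 0:
                raise ValueError(f"negative expression value under layer_tag {self.layer_tag}")
        for name, ids in (("cell", self.cell_ids), ("gene", self.gene_ids)):
            seen: set = set()
            for x in ids:
                if x in seen:
                    raise ValueError(f"duplicate {name} id: {x!r}")
                seen.add(x)
        # supervised method: every cell must carry a usable type label
        for lab_name, lab in (("batch", self.batch), ("cell_type", self.cell_type)):
            for v in lab:
                if v is None or (isinstance(v, float) and np.isnan(v)) or str(v) == "":
                    raise ValueError(f"missing {lab_name} label; the method is supervised")

    # -- convenience ------------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def batches(self) -> list[str]:
        """Distinct batch labels in first-occurrence order."""
        return list(dict.fromkeys(self.batch))

    def cell_types(self) -> list[str]:
        return list(dict.fromkeys(self.cell_type))

    def subset_cells(self, mask_or_idx) -> "AnnotatedMatrix":
        idx = np.asarray(mask_or_idx)
        return AnnotatedMatrix(
            self.values[idx],
            self.cell_ids[idx],
            self.gene_ids,
            self.batch[idx],
            self.cell_type[idx],
            self.layer_tag,
        )

    def subset_genes(self, mask_or_idx) -> "AnnotatedMatrix":
        idx = np.asarray(mask_or_idx)
        return AnnotatedMatrix(
            self.values[:, idx],
            self.cell_ids,
            self.gene_ids[idx],
            self.batch,
            self.cell_type,
            self.layer_tag,
        )

    def with_values(self, values: np.ndarray, layer_tag: str | None = None) -> "AnnotatedMatrix":
        return AnnotatedMatrix(
            values, self.cell_ids, self.gene_ids, self.batch, self.cell_type,
            layer_tag if layer_tag is not None else self.layer_tag,
        )

    def to_anndata(self):
        import anndata

        ad = anndata.AnnData(
            X=np.asarray(self.values),
            obs=pd.DataFrame(
                {"batch": pd.Categorical(list(map(str, self.batch))),
                 "cell_type": pd.Categorical(list(map(str, self.cell_type)))},
                index=list(map(str, self.cell_ids)),
            ),
            var=pd.DataFrame(index=list(map(str, self.gene_ids))),
        )
        ad.uns["layer_tag"] = self.layer_tag
        return ad

    @classmethod
    def from_anndata(cls, ad) -> "AnnotatedMatrix":
        for col in ("batch", "cell_type"):
            if col not in ad.obs.columns:
                raise ValueError(f"annotation column {col!r} missing from container")
        X = ad.X
        if scipy.sparse.issparse(X):
            X = X.toarray()
        return cls(
            np.asarray(X),
            np.asarray(ad.obs_names, dtype=object),
            np.asarray(ad.var_names, dtype=object),
            np.asarray(ad.obs["batch"].astype(str), dtype=object),
            np.asarray(ad.obs["cell_type"].astype(str), dtype=object),
            str(ad.uns.get("layer_tag", "raw_counts")),
        )


# ---------------------------------------------------------------------------
# pipeline configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PipelineConfig:
    """Preprocessing thresholds and graph options.

    Defaults are the published protocol: cells expressing fewer than 600 genes
    and genes seen in fewer than 3 cells are dropped, 2000 highly variable
    genes are kept, and every cell is scaled to a total count of 20,000.
    """

    min_genes_per_cell: int = 600
    min_cells_per_gene: int = 3
    n_hvg: int = 2000
    target_sum: float = 20000.0
    n_pcs_graph: int = 50
    graph_k: int = 5
    use_graph_mapping: bool = True
    random_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("min_genes_per_cell", "min_cells_per_gene", "n_hvg", "n_pcs_graph", "graph_k"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or isinstance(v, bool) or v <= 0:
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        if not self.target_sum > 0:
            raise ValueError(f"target_sum must be positive, got {self.target_sum!r}")


def load_config(path: str | os.PathLike) -> PipelineConfig:
    """Load a :class:`PipelineConfig` from a TOML or YAML key-value file.

    Unspecified keys take the defaults; unknown keys raise ``ValueError``.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".toml":
        data = tomllib.loads(text)
    else:
        data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must hold a key-value table")
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}; known keys: {sorted(known)}")
    return PipelineConfig(**data)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_LABEL_COLS = ("batch", "cell_type")


def _read_labels_table(path: Path, cell_ids: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    tab = pd.read_csv(path, sep="\t", dtype=str)
    if "cell_id" not in tab.columns:
        raise ValueError(f"annotation column 'cell_id' missing from {path}")
    for col in _LABEL_COLS:
        if col not in tab.columns:
            raise ValueError(f"annotation column {col!r} missing from {path}")
    tab = tab.set_index("cell_id")
    missing = [c for c in map(str, cell_ids) if c not in tab.index]
    if missing:
        raise ValueError(f"cells missing from label table: {missing[:5]}")
    tab = tab.loc[list(map(str, cell_ids))]
    return (
        np.asarray(tab["batch"], dtype=object),
        np.asarray(tab["cell_type"], dtype=object),
    )


def _write_labels_table(path: Path, m: AnnotatedMatrix) -> None:
    pd.DataFrame(
        {"cell_id": list(map(str, m.cell_ids)),
         "batch": list(map(str, m.batch)),
         "cell_type": list(map(str, m.cell_type))}
    ).to_csv(path, sep="\t", index=False)


def read_matrix(
    path: str | os.PathLike,
    format: Format,
    orientation: Literal["cells_by_genes", "genes_by_cells"] | None = None,
    layer_tag: str = "raw_counts",
) -> AnnotatedMatrix:
    """Read an :class:`AnnotatedMatrix`, normalising orientation to cells × genes.

    ``orientation`` describes the on-disk layout.  It defaults to
    ``genes_by_cells`` for ``mtx_dir`` (the 10x convention) and
    ``cells_by_genes`` for the other formats.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if format == "mtx_dir":
        orientation = orientation or "genes_by_cells"
        mat = scipy.io.mmread(path / "matrix.mtx")
        mat = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat)
        barcodes = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None, dtype=str)[0]
        features = pd.read_csv(path / "features.tsv", sep="\t", header=None, dtype=str)[0]
        if orientation == "genes_by_cells":
            mat = mat.T
        cell_ids = np.asarray(barcodes, dtype=object)
        gene_ids = np.asarray(features, dtype=object)
        if mat.shape != (len(cell_ids), len(gene_ids)):
            raise ValueError(
                f"matrix shape {mat.shape} does not match {len(cell_ids)} barcodes "
                f"x {len(gene_ids)} features (orientation={orientation})"
            )
        batch, cell_type = _read_labels_table(path / "labels.tsv", cell_ids)
    elif format == "delimited":
        orientation = orientation or "cells_by_genes"
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        tab = pd.read_csv(path, sep=sep, index_col=0)
        bad = tab.columns[[not pd.api.types.is_numeric_dtype(tab[c]) for c in tab.columns]]
        if len(bad):
            col = bad[0]
            row = tab.index[pd.to_numeric(tab[col], errors="coerce").isna()][0]
            raise ValueError(f"non-numeric value at cell {row!r}, gene {col!r}")
        mat = tab.to_numpy()
        ids_rows = np.asarray(tab.index.astype(str), dtype=object)
        ids_cols = np.asarray(tab.columns.astype(str), dtype=object)
        if orientation == "genes_by_cells":
            mat = mat.T
            cell_ids, gene_ids = ids_cols, ids_rows
        else:
            cell_ids, gene_ids = ids_rows, ids_cols
        batch, cell_type = _read_labels_table(path.with_suffix(path.suffix + ".labels.tsv"), cell_ids)
    elif format == "h5_container":
        import anndata

        ad = anndata.read_h5ad(path)
        m = AnnotatedMatrix.from_anndata(ad)
        if orientation == "genes_by_cells":
            raise ValueError("h5 container is always stored cells x genes")
        return m
    else:
        raise ValueError(f"unknown format {format!r}")
    return AnnotatedMatrix(mat, cell_ids, gene_ids, batch, cell_type, layer_tag)


def write_matrix(m: AnnotatedMatrix, path: str | os.PathLike, format: Format) -> None:
    """Write ``m`` in the requested format; round-trips through
    :func:`read_matrix` exactly for integer counts and to 1e-6 relative for
    floats."""
    path = Path(path)
    if format == "mtx_dir":
        path.mkdir(parents=True, exist_ok=True)
        sp = scipy.sparse.coo_matrix(np.asarray(m.values, dtype=float).T)  # genes x cells on disk
        is_int = np.allclose(m.values, np.round(m.values)) if m.values.size else True
        if is_int:
            sp = sp.astype(np.int64)
        scipy.io.mmwrite(path / "matrix.mtx", sp, field="integer" if is_int else "real")
        pd.Series(list(map(str, m.cell_ids))).to_csv(path / "barcodes.tsv", sep="\t", index=False, header=False)
        pd.Series(list(map(str, m.gene_ids))).to_csv(path / "features.tsv", sep="\t", index=False, header=False)
        _write_labels_table(path / "labels.tsv", m)
    elif format == "delimited":
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        pd.DataFrame(
            m.values, index=list(map(str, m.cell_ids)), columns=list(map(str, m.gene_ids))
        ).to_csv(path, sep=sep)
        _write_labels_table(path.with_suffix(path.suffix + ".labels.tsv"), m)
    elif format == "h5_container":
        m.to_anndata().write_h5ad(path)
    else:
        raise ValueError(f"unknown format {format!r}")
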