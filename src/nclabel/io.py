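"""Dataset containers and on-disk formats.

Two modalities are handled through one container type: a labeled reference
gene-expression matrix (GEM, from scRNA-seq) and an unlabeled target
gene-activity matrix (GAM, the gene-level view of scATAC-seq).  Matrices are
stored cells x genes, dense or scipy-sparse.  Supported on-disk forms are
Matrix Market triplets with one-id-per-line cell/gene sidecars, dense
CSV/TSV, and (optionally, if anndata is installed) ``.h5ad``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

__all__ = [
    "ExpressionDataset",
    "LowDimRep",
    "LabelVocabulary",
    "read_mtx_dataset",
    "read_csv_dataset",
    "read_h5ad_dataset",
    "write_mtx_dataset",
    "align_genes",
    "normalize_log_cpm",
    "encode_labels",
    "write_predictions",
    "write_embeddings",
]


class DatasetFormatError(ValueError):
    """Raised when an on-disk matrix and its sidecars are inconsistent."""


@dataclass
class ExpressionDataset:
    """A cells x genes non-negative matrix with identifiers and optional labels.

    Parameters
    ----------
    matrix
        ``(n_cells, n_genes)`` array or scipy sparse matrix of non-negative
        expression / gene-activity values.
    cell_ids
        Unique cell identifiers, one per row.
    gene_names
        Unique gene names, one per column.
    labels
        Optional per-cell class labels (cell types); required for the
        reference modality, absent for the target.
    """

    matrix: np.ndarray | sp.spmatrix
    cell_ids: list[str]
    gene_names: list[str]
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        n_cells, n_genes = self.matrix.shape
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_names = [str(g).strip() for g in self.gene_names]
        if len(self.cell_ids) != n_cells:
            raise DatasetFormatError(
                f"{len(self.cell_ids)} cell ids for a matrix with {n_cells} rows"
            )
        if len(self.gene_names) != n_genes:
            raise DatasetFormatError(
                f"{len(self.gene_names)} gene names for a matrix with {n_genes} columns"
            )
        if len(set(self.cell_ids)) != n_cells:
            raise DatasetFormatError("duplicate cell ids")
        if len(set(self.gene_names)) != n_genes:
            raise DatasetFormatError("duplicate gene names")
        if self.labels is not None:
            self.labels = [str(y) for y in self.labels]
            if len(self.labels) != n_cells:
                raise DatasetFormatError("labels length does not match number of cells")
            if any(y == "" for y in self.labels):
                raise DatasetFormatError("empty label string")

    # ------------------------------------------------------------------ views
    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[1]

    def to_dense(self) -> np.ndarray:
        """Return the matrix as a dense float64 array (copying if sparse)."""
        if sp.issparse(self.matrix):
            return np.asarray(self.matrix.todense(), dtype=np.float64)
        return np.asarray(self.matrix, dtype=np.float64)

    def subset_genes(self, gene_order: list[str]) -> "ExpressionDataset":
        index = {g: j for j, g in enumerate(self.gene_names)}
        cols = [index[g] for g in gene_order]
        matrix = self.matrix.tocsc()[:, cols].tocsr() if sp.issparse(self.matrix) else self.matrix[:, cols]
        return ExpressionDataset(matrix, list(self.cell_ids), list(gene_order),
                                 None if self.labels is None else list(self.labels))


@dataclass
class LowDimRep:
    """Low-dimensional coordinates of the target cells' raw chromatin features.

    Typically principal-component or tSNE coordinates computed on the peak /
    bin matrix before gene-activity conversion; this is the space in which
    the neighborhood graph is built.
    """

    coords: np.ndarray
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        self.cell_ids = [str(c) for c in self.cell_ids]
        if self.coords.ndim != 2 or self.coords.shape[1] < 1:
            raise DatasetFormatError("coords must be a 2-D matrix with >= 1 column")
        if self.coords.shape[0] != len(self.cell_ids):
            raise DatasetFormatError("coords rows do not match cell ids")
        if not np.all(np.isfinite(self.coords)):
            raise DatasetFormatError("non-finite values in low-dimensional coordinates")

    def check_aligned(self, ds: ExpressionDataset) -> None:
        if self.cell_ids != ds.cell_ids:
            raise DatasetFormatError(
                "low-dimensional representation cell ids do not match the target dataset"
            )


@dataclass
class LabelVocabulary:
    """Bijective mapping between class names and contiguous integer codes.

    Classes are ordered lexicographically so that encoding is deterministic
    across runs.
    """

    classes: list[str]
    mapping: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        if len(set(self.classes)) != len(self.classes):
            raise ValueError("duplicate class names")
        self.mapping = {c: i for i, c in enumerate(self.classes)}

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def encode(self, labels: list[str]) -> np.ndarray:
        return np.array([self.mapping[y] for y in labels], dtype=np.int64)

    def decode(self, codes: np.ndarray) -> list[str]:
        return [self.classes[int(c)] for c in codes]

    def __contains__(self, label: str) -> bool:
        return label in self.mapping


# --------------------------------------------------------------------- readers
def _read_lines(path: Path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip() != ""]


def read_mtx_dataset(
    matrix_path: str | Path,
    cells_path: str | Path,
    genes_path: str | Path,
    labels_path: str | Path | None = None,
) -> ExpressionDataset:
    """Read a Matrix Market matrix with cell/gene sidecar files.

    Orientation is resolved from the sidecar line counts: the matrix may be
    stored cells x genes or genes x cells, and is transposed if needed.  A
    square matrix with equally long sidecars is ambiguous and rejected.
    """
    matrix = mmread(str(matrix_path))
    if sp.issparse(matrix):
        matrix = matrix.tocsr()
    cell_ids = _read_lines(Path(cells_path))
    gene_names = _read_lines(Path(genes_path))
    n_rows, n_cols = matrix.shape

    cells_match = (n_rows, n_cols) == (len(cell_ids), len(gene_names))
    genes_match = (n_rows, n_cols) == (len(gene_names), len(cell_ids))
    if cells_match and genes_match:
        # square matrix with equal sidecar lengths: orientation undecidable
        raise DatasetFormatError(
            f"ambiguous orientation for {matrix_path}: matrix is "
            f"{n_rows}x{n_cols} and both sidecars have matching lengths"
        )
    if genes_match:
        matrix = matrix.T.tocsr() if sp.issparse(matrix) else matrix.T
    elif not cells_match:
        raise DatasetFormatError(
            f"matrix {matrix_path} is {n_rows}x{n_cols} but sidecars have "
            f"{len(cell_ids)} cells ({cells_path}) and {len(gene_names)} genes ({genes_path})"
        )

    labels = None
    if labels_path is not None:
        labels = _read_lines(Path(labels_path))
        if len(labels) != len(cell_ids):
            raise DatasetFormatError(
                f"labels file {labels_path} has {len(labels)} lines for {len(cell_ids)} cells"
            )
    return ExpressionDataset(matrix, cell_ids, gene_names, labels)


def write_mtx_dataset(ds: ExpressionDataset, prefix: str | Path) -> dict[str, Path]:
    """Write ``<prefix>.mtx`` plus ``<prefix>.cells.txt`` / ``.genes.txt``
    (and ``.labels.txt`` when labels are present).  Returns the paths."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": prefix.with_suffix(".mtx"),
        "cells": Path(str(prefix) + ".cells.txt"),
        "genes": Path(str(prefix) + ".genes.txt"),
    }
    matrix = ds.matrix if sp.issparse(ds.matrix) else sp.coo_matrix(ds.matrix)
    mmwrite(str(paths["matrix"]), matrix)
    paths["cells"].write_text("".join(c + "\n" for c in ds.cell_ids))
    paths["genes"].write_text("".join(g + "\n" for g in ds.gene_names))
    if ds.labels is not None:
        paths["labels"] = Path(str(prefix) + ".labels.txt")
        paths["labels"].write_text("".join(y + "\n" for y in ds.labels))
    return paths


def read_csv_dataset(
    path: str | Path, labels_column: str | None = None, sep: str = ","
) -> ExpressionDataset:
    """Read a dense cells x genes CSV/TSV: first column cell ids, header genes."""
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise DatasetFormatError(f"duplicate cell id {dup!r} in {path}")
    labels = None
    if labels_column is not None:
        if labels_column not in df.columns:
            raise DatasetFormatError(f"labels column {labels_column!r} not found in {path}")
        labels = df[labels_column].astype(str).tolist()
        df = df.drop(columns=[labels_column])
    try:
        values = df.to_numpy(dtype=np.float64)
    except (TypeError, ValueError) as exc:
        for j, col in enumerate(df.columns):
            converted = pd.to_numeric(df[col], errors="coerce")
            if converted.isna().any() and not df[col].isna().any():
                row = df.index[converted.isna().argmax()]
                raise DatasetFormatError(
                    f"non-numeric entry at row {row!r}, column {col!r} in {path}"
                ) from exc
        raise
    return ExpressionDataset(values, df.index.tolist(), df.columns.tolist(), labels)


def read_h5ad_dataset(path: str | Path, labels_column: str | None = None) -> ExpressionDataset:
    """Read an HDF5-based single-cell container (AnnData ``.h5ad``)."""
    try:
        import anndata
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("reading .h5ad requires the optional 'anndata' dependency") from exc
    adata = anndata.read_h5ad(str(path))
    labels = None
    if labels_column is not None:
        if labels_column not in adata.obs.columns:
            raise DatasetFormatError(f"obs column {labels_column!r} not found in {path}")
        labels = adata.obs[labels_column].astype(str).tolist()
    matrix = adata.X.tocsr() if sp.issparse(adata.X) else np.asarray(adata.X)
    return ExpressionDataset(matrix, adata.obs_names.tolist(), adata.var_names.tolist(), labels)


def read_lowdim_csv(path: str | Path, sep: str = ",") -> LowDimRep:
    """Read a cells x dims coordinate table (first column cell ids)."""
    df = pd.read_csv(path, sep=sep, index_col=0)
    return LowDimRep(df.to_numpy(dtype=np.float64), df.index.tolist())


# ------------------------------------------------------------------ transforms
def align_genes(
    reference: ExpressionDataset, target: ExpressionDataset
) -> tuple[ExpressionDataset, ExpressionDataset]:
    """Restrict both datasets to their shared genes, in reference order.

    Matching is exact (case-sensitive) after whitespace trimming, which the
    containers already apply on construction.  The shared gene set defines M,
    the common feature space both modalities are encoded from.
    """
    target_set = set(target.gene_names)
    shared = [g for g in reference.gene_names if g in target_set]
    if not shared:
        raise DatasetFormatError(
            "no shared genes between reference and target; check that both use "
            "the same gene naming convention (e.g. symbols vs Ensembl ids)"
        )
    return reference.subset_genes(shared), target.subset_genes(shared)


def normalize_log_cpm(ds: ExpressionDataset, scale: float = 1e4) -> ExpressionDataset:
    """Per-cell library-size normalization to ``scale`` followed by log1p.

    All-zero cells are left as zeros.  Applied identically to both modalities
    so that expression and gene-activity profiles live on comparable scales.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    dense = ds.to_dense()
    if (dense < 0).any():
        raise ValueError("normalize_log_cpm requires a non-negative matrix")
    sums = dense.sum(axis=1, keepdims=True)
    nonzero = sums[:, 0] > 0
    out = np.zeros_like(dense)
    out[nonzero] = np.log1p(dense[nonzero] / sums[nonzero] * scale)
    return ExpressionDataset(out, list(ds.cell_ids), list(ds.gene_names),
                             None if ds.labels is None else list(ds.labels))


def encode_labels(labels: list[str]) -> tuple[LabelVocabulary, np.ndarray]:
    """Build a lexicographically ordered vocabulary and encode the labels."""
    if len(labels) == 0:
        raise ValueError("labels must be non-empty")
    labels = [str(y) for y in labels]
    if any(y == "" for y in labels):
        raise ValueError("empty label string")
    vocab = LabelVocabulary(sorted(set(labels)))
    return vocab, vocab.encode(labels)


# --------------------------------------------------------------------- writers
def write_predictions(result, vocab: LabelVocabulary, path: str | Path) -> None:
    """Write per-cell predictions as TSV.

    Columns: cell_id, predicted_type, confidence, novel_confidence, novel_flag
    (if called), then one probability column per class, all printed with six
    significant digits.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = ["cell_id", "predicted_type", "confidence", "novel_confidence"]
    has_flags = getattr(result, "novel_flags", None) is not None
    if has_flags:
        header.append("novel_flag")
    header += [f"prob_{c}" for c in vocab.classes]
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for i, cell_id in enumerate(result.cell_ids):
            row = [
                cell_id,
                vocab.classes[int(result.predicted_code[i])],
                f"{result.confidence[i]:.6g}",
                f"{result.novel_confidence[i]:.6g}",
            ]
            if has_flags:
                row.append("novel" if result.novel_flags[i] else "known")
            row += [f"{p:.6g}" for p in result.probabilities[i]]
            fh.write("\t".join(row) + "\n")


def write_embeddings(cell_ids: list[str], embedding: np.ndarray, path: str | Path) -> None:
    """Write the cells x d embedding matrix as CSV with a cell_id column."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        embedding, index=pd.Index(cell_ids, name="cell_id"),
        columns=[f"dim_{j}" for j in range(embedding.shape[1])],
    )
    df.to_csv(path, float_format="%.6g")
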