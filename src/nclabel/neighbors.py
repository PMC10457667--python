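"""kNN graph over the target cells' raw-feature coordinates.

The contrastive regularizer needs, for every target cell, a fixed set of k0
nearest neighbors computed once, before training, in a low-dimensional
representation of the raw chromatin-accessibility features (not the gene
activity matrix — the point is to preserve structure the gene-level
transform may destroy).  Search is exact Euclidean; ties in distance are
broken by ascending cell index so graphs are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

from .io import LowDimRep

__all__ = ["KnnGraph", "build_knn_graph", "sample_positive_partners"]


@dataclass
class KnnGraph:
    """Per-cell neighbor index lists of size ``k0`` (self excluded)."""

    neighbor_indices: np.ndarray  # (n_cells, k0) int
    k0: int
    n_cells: int

    def __post_init__(self) -> None:
        self.neighbor_indices = np.asarray(self.neighbor_indices, dtype=np.int64)
        if self.neighbor_indices.shape != (self.n_cells, self.k0):
            raise ValueError("neighbor_indices shape does not match (n_cells, k0)")
        if (np.arange(self.n_cells)[:, None] == self.neighbor_indices).any():
            raise ValueError("a cell appears in its own neighbor list")
        if self.neighbor_indices.min() < 0 or self.neighbor_indices.max() >= self.n_cells:
            raise ValueError("neighbor index out of range")

    def to_edge_tsv(self, path: str | Path) -> None:
        """Export as a TSV edge list (source_index, target_index, rank)."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            fh.write("source_index\ttarget_index\trank\n")
            for i in range(self.n_cells):
                for rank, j in enumerate(self.neighbor_indices[i]):
                    fh.write(f"{i}\t{j}\t{rank}\n")


def build_knn_graph(rep: LowDimRep | np.ndarray, k0: int, block_size: int = 2048) -> KnnGraph:
    """Exact Euclidean k0-nearest-neighbor graph with index tie-breaking.

    Distances are computed blockwise against all cells; within each row the
    ordering is (distance, index) lexicographic, so equidistant neighbors are
    taken in ascending index order and the graph is deterministic.
    """
    coords = rep.coords if isinstance(rep, LowDimRep) else np.asarray(rep, dtype=np.float64)
    if not np.all(np.isfinite(coords)):
        raise ValueError("non-finite coordinates")
    n_cells = coords.shape[0]
    if k0 < 1:
        raise ValueError("k0 must be >= 1")
    if k0 >= n_cells:
        raise ValueError(f"k0={k0} requires more than k0 cells (have {n_cells})")

    index = np.arange(n_cells)
    neighbors = np.empty((n_cells, k0), dtype=np.int64)
    for start in range(0, n_cells, block_size):
        stop = min(start + block_size, n_cells)
        dist = cdist(coords[start:stop], coords)  # (block, n_cells)
        dist[index[start:stop] - start, index[start:stop]] = np.inf  # exclude self
        # lexicographic (distance, index): stable mergesort on distance keeps
        # ascending-index order among exact ties
        order = np.argsort(dist, axis=1, kind="stable")
        neighbors[start:stop] = order[:, :k0]
    return KnnGraph(neighbors, k0=k0, n_cells=n_cells)


def sample_positive_partners(
    graph: KnnGraph, batch_indices: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw one uniformly random neighbor per batch cell.

    The sampled neighbor forms the positive pair of the contrastive loss;
    draws are independent across cells and across calls (fresh sampling each
    training step), reproducible under a seeded generator.
    """
    batch_indices = np.asarray(batch_indices, dtype=np.int64)
    if batch_indices.size and (batch_indices.min() < 0 or batch_indices.max() >= graph.n_cells):
        raise IndexError("batch index out of range")
    choice = rng.integers(0, graph.k0, size=batch_indices.shape[0])
    return graph.neighbor_indices[batch_indices, choice]
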