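"""Inter-host microbiome similarity graph.

Nodes are samples (training and test alike); edges connect each sample to its
k nearest neighbors by Euclidean distance in the learned latent space. The
directed kNN relation is symmetrized by union (an edge exists if either
endpoint selects the other), self-loops are added, and the symmetric
normalization D^{-1/2} (A + I) D^{-1/2} used by graph convolution is
precomputed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist


@dataclass
class SimilarityGraph:
    """kNN-union similarity graph over samples with its normalized operator."""

    n: int
    adjacency: np.ndarray
    adjacency_with_self: np.ndarray
    norm_operator: np.ndarray
    node_order: list[str]
    k: int

    def __post_init__(self) -> None:
        a = self.adjacency
        if a.shape != (self.n, self.n):
            raise ValueError("adjacency shape mismatch")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency must have a zero diagonal")
        if len(self.node_order) != self.n:
            raise ValueError("node_order length mismatch")

    def write_edge_list(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("node_id_1\tnode_id_2\n")
            for i, j in zip(*np.nonzero(np.triu(self.adjacency))):
                fh.write(f"{self.node_order[i]}\t{self.node_order[j]}\n")

    def write_operator(self, path: str | Path) -> None:
        header = "\t".join(self.node_order)
        np.savetxt(
            path, self.norm_operator, delimiter="\t", header=header, fmt="%.17g"
        )


def pairwise_euclidean(latent: np.ndarray) -> np.ndarray:
    """Dense sample-sample Euclidean distance matrix (symmetric, zero diagonal)."""
    latent = np.asarray(latent, dtype=float)
    if latent.ndim != 2 or latent.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    if not np.all(np.isfinite(latent)):
        raise ValueError("latent features contain NaN or infinite values")
    d = cdist(latent, latent, metric="euclidean")
    d = 0.5 * (d + d.T)  # enforce exact symmetry against fp asymmetries
    np.fill_diagonal(d, 0.0)
    return d


def _normalized_operator(a_tilde: np.ndarray) -> np.ndarray:
    deg = a_tilde.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(deg)
    return a_tilde * inv_sqrt[:, None] * inv_sqrt[None, :]


def knn_edges(
    distances: np.ndarray, k: int, node_order: list[str] | None = None
) -> SimilarityGraph:
    """Build the kNN-union graph from a distance matrix.

    Each node selects its k closest other nodes (ties at the k-th distance
    broken deterministically toward the lower node index); the directed
    relation is symmetrized by union.
    """
    distances = np.asarray(distances, dtype=float)
    n = distances.shape[0]
    if distances.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if k <= 0:
        raise ValueError("k must be positive")
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the node count n={n}")
    if node_order is None:
        node_order = [str(i) for i in range(n)]

    directed = np.zeros((n, n), dtype=float)
    masked = distances.copy()
    np.fill_diagonal(masked, np.inf)
    for i in range(n):
        # stable sort on distance keeps index order among ties
        nearest = np.argsort(masked[i], kind="stable")[:k]
        directed[i, nearest] = 1.0
    adjacency = np.maximum(directed, directed.T)
    a_tilde = adjacency + np.eye(n)
    return SimilarityGraph(
        n=n,
        adjacency=adjacency,
        adjacency_with_self=a_tilde,
        norm_operator=_normalized_operator(a_tilde),
        node_order=list(node_order),
        k=k,
    )


def build_graph(
    train_latent: np.ndarray,
    test_latent: np.ndarray,
    k: int,
    node_order: list[str] | None = None,
) -> SimilarityGraph:
    """Single graph over concatenated train + test samples (train first)."""
    train_latent = np.asarray(train_latent, dtype=float)
    test_latent = np.asarray(test_latent, dtype=float)
    if train_latent.shape[1] != test_latent.shape[1]:
        raise ValueError("train and test latent dimensions differ")
    latent = np.vstack([train_latent, test_latent])
    return knn_edges(pairwise_euclidean(latent), k, node_order=node_order)
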