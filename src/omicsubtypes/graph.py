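"""Patient-to-patient weighted KNN similarity graphs.

For samples i, j with cosine similarity s(i, j) and neighbor sets
eta_i (the K most similar other samples), the adjacency is

    A_ij = s(i,j)/sum_{r in eta_i} s(i,r) * I(j in eta_i)
         + s(i,j)/sum_{r in eta_j} s(r,j) * I(i in eta_j)

which is symmetric by construction. Negative cosines (possible after
z-scoring) are clamped to zero before ranking and weighting so that the
adjacency is nonnegative and GCN degree normalization stays real. The
default neighbor count is K = floor(N / n_clusters), with n_clusters
assumed 6 when unknown.
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = [
    "SimilarityGraph",
    "cosine_similarity",
    "default_neighbor_count",
    "build_adjacency",
    "write_edge_list",
]


@dataclasses.dataclass
class SimilarityGraph:
    """Symmetric weighted KNN adjacency with its neighbor sets."""

    adjacency: np.ndarray
    K: int
    neighbor_sets: list[np.ndarray]

    @property
    def n_samples(self) -> int:
        return self.adjacency.shape[0]


def cosine_similarity(x: np.ndarray, y: np.ndarray) -> float:
    """Cosine of the angle between two nonzero feature vectors."""
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0 or ny == 0:
        raise ValueError("cosine similarity is undefined for a zero vector")
    return float(x @ y / (nx * ny))


def default_neighbor_count(n_samples: int, n_clusters: int | None = None) -> int:
    """K = floor(n_samples / n_clusters), n_clusters = 6 when unknown,
    clipped to the valid neighbor range [1, n_samples - 1]."""
    if n_samples < 2:
        raise ValueError("need at least two samples to have neighbors")
    k_clusters = 6 if n_clusters is None else int(n_clusters)
    if k_clusters < 1:
        raise ValueError("n_clusters must be positive")
    return int(np.clip(n_samples // k_clusters, 1, n_samples - 1))


def _cosine_matrix(X: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(X, axis=1)
    if np.any(norms == 0):
        bad = np.flatnonzero(norms == 0)
        raise ValueError(f"zero-vector rows have no cosine similarity: {bad.tolist()}")
    Xn = X / norms[:, None]
    S = Xn @ Xn.T
    return np.clip(S, -1.0, 1.0)


def build_adjacency(X: np.ndarray, K: int) -> SimilarityGraph:
    """Build the weighted KNN similarity graph for a samples x features matrix.

    Neighbor sets exclude the sample itself; ties at the K-th rank break by
    ascending sample index. If a sample's clamped neighbor-similarity sum is
    zero, its one-sided weights are uniform 1/K over its neighbor set.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("X must be 2-D with at least two samples")
    N = X.shape[0]
    if not 1 <= K <= N - 1:
        raise ValueError(f"K={K} outside the valid range [1, {N - 1}]")
    S = np.maximum(_cosine_matrix(X), 0.0)  # clamp negative cosines
    np.fill_diagonal(S, 0.0)  # self contributes no weight

    # stable top-K among j != i: sort by (-similarity, index) with the
    # diagonal pushed below every candidate so i never ranks itself
    S_rank = S.copy()
    np.fill_diagonal(S_rank, -1.0)
    order = np.lexsort((np.broadcast_to(np.arange(N), (N, N)), -S_rank), axis=1)
    neighbor_sets = [np.sort(order[i, :K]) for i in range(N)]

    W = np.zeros((N, N))  # one-sided weights: W[i, j] for j in eta_i
    for i in range(N):
        eta = neighbor_sets[i]
        denom = S[i, eta].sum()
        if denom > 0:
            W[i, eta] = S[i, eta] / denom
        else:
            W[i, eta] = 1.0 / K
    A = W + W.T
    return SimilarityGraph(adjacency=A, K=int(K), neighbor_sets=neighbor_sets)


def write_edge_list(graph: SimilarityGraph, path) -> None:
    """Export the upper triangle of the adjacency as `i<TAB>j<TAB>weight`."""
    A = graph.adjacency
    with open(path, "w") as fh:
        fh.write("i\tj\tweight\n")
        for i, j in zip(*np.triu_indices_from(A, k=1)):
            if A[i, j] != 0:
                fh.write(f"{i}\t{j}\t{A[i, j]:.17g}\n")
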