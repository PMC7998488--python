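"""Sample-similarity graph construction.

Nodes are samples; two samples are connected when their Euclidean distance in
the (selected, normalized) feature space falls strictly below a threshold,
taken by default as the mean pairwise distance over all distinct node pairs.
Self-loops are materialized on the diagonal so each node's neighbourhood
includes itself during attention.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .errors import ConfigError, ValidationError

__all__ = [
    "DistanceMatrix",
    "Graph",
    "pairwise_euclidean",
    "mean_threshold",
    "build_adjacency",
    "build_graph",
    "graph_summary",
    "write_edge_list",
    "read_edge_list",
    "write_dense_adjacency",
    "read_dense_adjacency",
]


@dataclass
class DistanceMatrix:
    """Symmetric N x N Euclidean distance matrix with node identifiers."""

    values: np.ndarray
    node_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n) or len(self.node_ids) != n:
            raise ValidationError("distance matrix must be square and id-aligned")


@dataclass
class Graph:
    """Binary adjacency (with self-loops) plus row-aligned node features."""

    adjacency: np.ndarray
    features: np.ndarray
    node_ids: list[str]
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        A = np.asarray(self.adjacency)
        self.adjacency = A.astype(float)
        n = A.shape[0]
        if A.shape != (n, n):
            raise ValidationError("adjacency must be square")
        if not np.array_equal(A, A.T):
            raise ValidationError("adjacency must be symmetric")
        if not np.all(np.diag(A) == 1):
            raise ValidationError("adjacency must carry self-loops (unit diagonal)")
        if set(np.unique(A)) - {0.0, 1.0}:
            raise ValidationError("adjacency must be binary")
        self.features = np.asarray(self.features, dtype=float)
        if self.features.shape[0] != n or len(self.node_ids) != n:
            raise ValidationError("features and node_ids must align with adjacency")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (n,):
                raise ValidationError("labels must have one entry per node")

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]


def pairwise_euclidean(
    X: np.ndarray, node_ids: list[str] | None = None
) -> DistanceMatrix:
    """All-pairs Euclidean distances between the rows of ``X``."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValidationError("need a 2-D matrix with at least two rows")
    if not np.isfinite(X).all():
        raise ValidationError("features contain NaN or inf")
    D = squareform(pdist(X, metric="euclidean"))
    ids = node_ids if node_ids is not None else [str(i) for i in range(X.shape[0])]
    return DistanceMatrix(D, list(ids))


def mean_threshold(D: DistanceMatrix) -> float:
    """Mean distance over unordered off-diagonal pairs (the diagonal's zeros
    would otherwise bias the threshold downward)."""
    n = D.values.shape[0]
    iu = np.triu_indices(n, k=1)
    return float(D.values[iu].mean())


def build_adjacency(D: DistanceMatrix, tau: float) -> np.ndarray:
    """Binary adjacency: edge iff distance strictly below ``tau``; unit diagonal."""
    if tau <= 0:
        raise ConfigError(f"threshold must be positive, got {tau}")
    A = (D.values < tau).astype(float)
    np.fill_diagonal(A, 1.0)
    return A


def build_graph(
    X: np.ndarray,
    node_ids: list[str] | None = None,
    labels: np.ndarray | None = None,
    tau: float | None = None,
) -> Graph:
    """Distance matrix -> (mean) threshold -> adjacency -> :class:`Graph`."""
    D = pairwise_euclidean(X, node_ids)
    if tau is None:
        tau = mean_threshold(D)
    return Graph(build_adjacency(D, tau), np.asarray(X, float), D.node_ids, labels)


def graph_summary(G: Graph) -> dict:
    """Node/edge counts and density (self-loops excluded from edge counts)."""
    import networkx as nx

    A = G.adjacency.copy()
    np.fill_diagonal(A, 0.0)
    g = nx.from_numpy_array(A)
    n = G.n_nodes
    undirected = g.number_of_edges()
    return {
        "nodes": n,
        "undirected_edges": undirected,
        "directed_nonzero": int(A.sum()),
        "density": nx.density(g),
        "isolated_nodes": sum(1 for _ in nx.isolates(g)),
    }


def write_edge_list(G: Graph, path: str | Path) -> Path:
    """Write undirected non-self edges as 0-based ``i j`` lines (i < j)."""
    path = Path(path)
    n = G.n_nodes
    lines = [
        f"{i} {j}"
        for i in range(n)
        for j in range(i + 1, n)
        if G.adjacency[i, j] == 1
    ]
    path.write_text("\n".join(lines) + ("\n" if lines else ""))
    return path


def read_edge_list(path: str | Path, n_nodes: int) -> np.ndarray:
    """Read an ``i j`` edge list back into a symmetric adjacency with self-loops."""
    A = np.eye(n_nodes)
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        i, j = (int(t) for t in line.split())
        if not (0 <= i < n_nodes and 0 <= j < n_nodes):
            raise ValidationError(f"edge ({i}, {j}) out of range for {n_nodes} nodes")
        A[i, j] = A[j, i] = 1.0
    return A


def write_dense_adjacency(G: Graph, path: str | Path) -> Path:
    path = Path(path)
    np.savetxt(path, G.adjacency, fmt="%d")
    return path


def read_dense_adjacency(path: str | Path) -> np.ndarray:
    return np.loadtxt(path, ndmin=2)
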