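"""Hypergraph views and the hyperedge-convolution propagation operator.

Two hypergraphs are built per entity type from the same node features
(association profile concatenated with integrated similarity):

* **KNN view** — one hyperedge per vertex containing the vertex and its k
  nearest other vertices by Euclidean distance (square incidence matrix,
  every column sum k+1);
* **K-means view** — one hyperedge per cluster of a seeded k-means run
  (each row of the incidence matrix has exactly one 1).

Embedding propagation uses the degree-normalized operator
``P = D_v^{-1/2} H W D_e^{-1} H^T D_v^{-1/2}``, which is symmetric for
diagonal hyperedge weights and has ``D_v^{1/2} 1`` as an eigenvalue-1
eigenvector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

from .io import AssociationMatrix, InvalidInputError, SimilarityMatrix

__all__ = ["Hypergraph", "NodeFeatures", "build_node_features",
           "knn_hypergraph", "kmeans_hypergraph", "propagation_operator",
           "normalized_adjacency"]


@dataclass
class Hypergraph:
    """Incidence matrix, hyperedge weights and derived degree vectors."""

    H: np.ndarray
    W: np.ndarray

    def __post_init__(self):
        self.H = np.asarray(self.H, dtype=float)
        self.W = np.asarray(self.W, dtype=float)
        if self.H.ndim != 2 or self.W.shape != (self.H.shape[1],):
            raise InvalidInputError("W length must equal the number of "
                                    "hyperedges (columns of H)")
        if (self.W <= 0).any():
            raise InvalidInputError("hyperedge weights must be positive")
        if (self.H.sum(axis=0) == 0).any():
            raise InvalidInputError("empty hyperedge (all-zero column of H)")

    @property
    def n_vertices(self) -> int:
        return self.H.shape[0]

    @property
    def n_edges(self) -> int:
        return self.H.shape[1]

    @property
    def d_v(self) -> np.ndarray:
        """Vertex degrees: sum of weights of incident hyperedges."""
        return self.H @ self.W

    @property
    def d_e(self) -> np.ndarray:
        """Hyperedge degrees: number of member vertices."""
        return self.H.sum(axis=0)

    def to_triplets(self):
        """(vertex_index, edge_index, 1) rows for debug dumps."""
        vs, es = np.nonzero(self.H)
        return [(int(v), int(e), 1) for v, e in zip(vs, es)]


@dataclass
class NodeFeatures:
    """Ordered entity ids with their feature matrix."""

    ids: list
    X: np.ndarray


def build_node_features(T: AssociationMatrix, sim: SimilarityMatrix,
                        axis: str) -> NodeFeatures:
    """Concatenate association profiles with integrated similarity.

    miRNA features are ``[T | IM]`` (M x (D+M)); disease features are
    ``[T' | ID]`` (D x (M+D)).
    """
    if axis == "mirna":
        if sim.ids != T.mirna_ids:
            raise InvalidInputError("similarity ids do not match miRNA ids")
        X = np.hstack([np.asarray(T.T, dtype=float), sim.S])
        return NodeFeatures(list(T.mirna_ids), X)
    if axis == "disease":
        if sim.ids != T.disease_ids:
            raise InvalidInputError("similarity ids do not match disease ids")
        X = np.hstack([np.asarray(T.T, dtype=float).T, sim.S])
        return NodeFeatures(list(T.disease_ids), X)
    raise InvalidInputError(f"axis must be 'mirna' or 'disease', got {axis!r}")


def knn_hypergraph(feat: NodeFeatures, k: int) -> Hypergraph:
    """One hyperedge per vertex: the vertex plus its k nearest other
    vertices (Euclidean distance, ties broken by ascending index)."""
    X = np.asarray(feat.X, dtype=float)
    m = X.shape[0]
    if not 1 <= k <= m - 1:
        raise InvalidInputError(f"k must be in [1, {m - 1}], got {k}")
    D = cdist(X, X)
    np.fill_diagonal(D, np.inf)  # the anchor joins its own hyperedge anyway
    order = np.argsort(D, axis=1, kind="stable")
    H = np.zeros((m, m))
    for i in range(m):
        H[i, i] = 1.0
        H[order[i, :k], i] = 1.0
    return Hypergraph(H, np.ones(m))


def kmeans_hypergraph(feat: NodeFeatures, c: int, seed: int) -> Hypergraph:
    """One hyperedge per K-means cluster; seeded random center
    initialization iterated (at most 300 rounds) to an assignment fixpoint."""
    X = np.asarray(feat.X, dtype=float)
    m = X.shape[0]
    if not 1 <= c <= m:
        raise InvalidInputError(f"c must be in [1, {m}], got {c}")
    km = KMeans(n_clusters=c, init="random", n_init=1, max_iter=300,
                random_state=int(seed) % (2 ** 31), algorithm="lloyd")
    labels = km.fit_predict(X)
    H = np.zeros((m, c))
    H[np.arange(m), labels] = 1.0
    return Hypergraph(H, np.ones(c))


def propagation_operator(hg: Hypergraph, eps: float = 1e-8) -> np.ndarray:
    """``D_v^{-1/2} H W D_e^{-1} H^T D_v^{-1/2}``.

    Zero vertex degrees (isolated vertices) are replaced by ``eps`` before
    the inverse square root; connected inputs are untouched.
    """
    d_v = hg.d_v
    d_e = hg.d_e
    d_v = np.where(d_v > 0, d_v, eps)
    inv_sqrt_dv = 1.0 / np.sqrt(d_v)
    HW = hg.H * hg.W  # scale columns by hyperedge weight
    P = (inv_sqrt_dv[:, None] * HW) @ ((hg.H / d_e[None, :]).T
                                       * inv_sqrt_dv[None, :])
    return P


def normalized_adjacency(sim: SimilarityMatrix) -> np.ndarray:
    """Symmetrically normalized similarity graph with self-loops,
    ``D^{-1/2}(S+I)D^{-1/2}`` — the plain-graph stand-in used by the
    GCN ablation."""
    A = sim.S + np.eye(sim.n)
    d = A.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(np.where(d > 0, d, 1.0))
    return inv_sqrt[:, None] * A * inv_sqrt[None, :]
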