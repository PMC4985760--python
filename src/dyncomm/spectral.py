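"""Normalized-cut spectral clustering primitives.

The relaxed normalized-cut solution embeds nodes by the eigenvectors of
the symmetric normalized Laplacian L = I - D^{-1/2} W D^{-1/2}
associated with its k smallest eigenvalues; k-means on the (row
normalized) embedding yields the hard partition.  The per-snapshot
static baseline applies this directly to each snapshot adjacency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans

from .graph import DynamicNetwork, Partition, SnapshotGraph
from .kernels import SimilarityView

__all__ = [
    "EPS_DEGREE",
    "LaplacianMatrix",
    "Embedding",
    "normalized_laplacian",
    "spectral_embed",
    "cluster_embedding",
    "static_spectral",
    "StaticSpectralClustering",
    "as_network",
]

# Degree regularizer: keeps D^{-1/2} finite for isolated nodes, which
# short-interval snapshots produce routinely.
EPS_DEGREE = 1e-10


@dataclass
class LaplacianMatrix:
    """Symmetric normalized Laplacian plus the raw degree vector."""

    L: np.ndarray
    degrees: np.ndarray
    node_ids: np.ndarray


@dataclass
class Embedding:
    """n x k matrix of (orthonormal) embedding coordinates.

    ``eigenvalues`` is None for composite embeddings (e.g. column-wise
    concatenation of several views' eigenvector blocks).
    """

    U: np.ndarray
    node_ids: np.ndarray
    eigenvalues: np.ndarray | None = None

    @property
    def k(self) -> int:
        return self.U.shape[1]


def normalized_laplacian(view: SimilarityView) -> LaplacianMatrix:
    """L = I - D^{-1/2} W D^{-1/2} with degree regularization.

    Raises on negative similarities; a similarity view must be
    nonnegative for the normalized-cut relaxation to be meaningful.
    """
    W = view.W
    if np.any(W < 0):
        raise ValueError("similarity matrix has negative entries")
    degrees = W.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(degrees + EPS_DEGREE)
    L = np.eye(W.shape[0]) - inv_sqrt[:, None] * W * inv_sqrt[None, :]
    L = (L + L.T) / 2.0
    return LaplacianMatrix(L=L, degrees=degrees, node_ids=view.node_ids)


def spectral_embed(lap: LaplacianMatrix, k: int) -> Embedding:
    """Eigenvectors of the k smallest Laplacian eigenvalues, ascending."""
    n = lap.L.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    vals, vecs = scipy.linalg.eigh(lap.L, subset_by_index=(0, k - 1))
    return Embedding(U=vecs, node_ids=lap.node_ids, eigenvalues=vals)


def _row_normalize(U: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(U, axis=1)
    norms = np.where(norms == 0, 1.0, norms)
    return U / norms[:, None]


def cluster_embedding(emb: Embedding, k: int, seed: int) -> Partition:
    """k-means (10 restarts, greedy k-means++ seeding) on the embedding.

    Rows are normalized to unit length first.  Deterministic given
    ``seed``.  If k-means leaves some cluster empty of distinct points
    the result has fewer than k communities and a warning is issued.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    V = _row_normalize(emb.U)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(V)
    if len(np.unique(labels)) < k:
        warnings.warn(
            f"k-means produced {len(np.unique(labels))} < k={k} nonempty clusters",
            stacklevel=2,
        )
    return Partition(node_ids=emb.node_ids.copy(), labels=labels, k=k)


def static_spectral(graph: SnapshotGraph, k: int, seed: int) -> Partition:
    """Per-snapshot normalized-cut spectral clustering on the adjacency."""
    if graph.adjacency.sum() == 0:
        warnings.warn("graph has no edges; labels are arbitrary", stacklevel=2)
    view = SimilarityView(
        W=graph.adjacency.astype(float), node_ids=graph.node_ids, kernel=None
    )
    emb = spectral_embed(normalized_laplacian(view), k)
    return cluster_embedding(emb, k, seed)


def as_network(X) -> DynamicNetwork:
    """Coerce estimator input to a :class:`DynamicNetwork`.

    Accepts a DynamicNetwork, a list of SnapshotGraph, or a list of
    square adjacency arrays (nodes then numbered 0..n-1).
    """
    if isinstance(X, DynamicNetwork):
        return X
    snaps = []
    for t, item in enumerate(X, start=1):
        if isinstance(item, SnapshotGraph):
            if item.t != t:
                item = SnapshotGraph(item.node_ids, item.adjacency, t=t)
            snaps.append(item)
        else:
            A = np.asarray(item, dtype=float)
            snaps.append(SnapshotGraph(np.arange(A.shape[0]), A, t=t))
    return DynamicNetwork(snapshots=snaps)


def _k_per_snapshot(n_clusters, n_snapshots: int) -> list:
    if np.isscalar(n_clusters):
        return [int(n_clusters)] * n_snapshots
    k_list = [int(k) for k in n_clusters]
    if len(k_list) != n_snapshots:
        raise ValueError("length of n_clusters does not match snapshot count")
    return k_list


class StaticSpectralClustering(BaseEstimator):
    """Two-stage baseline: independent spectral clustering per snapshot.

    Parameters
    ----------
    n_clusters : int or sequence of int
        Communities per snapshot (a scalar applies to all snapshots).
    random_state : int
        Base seed for the k-means stage; snapshot t uses seed
        ``random_state + t``.

    Attributes
    ----------
    labels_ : list of ndarray
        Per-snapshot community labels.
    partitions_ : list of Partition
    """

    def __init__(self, n_clusters: int = 2, random_state: int = 0):
        self.n_clusters = n_clusters
        self.random_state = random_state

    def fit(self, X, y=None):
        net = as_network(X)
        k_list = _k_per_snapshot(self.n_clusters, net.n_snapshots)
        self.partitions_ = [
            static_spectral(snap, k, self.random_state + snap.t)
            for snap, k in zip(net.snapshots, k_list)
        ]
        self.labels_ = [p.labels.copy() for p in self.partitions_]
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_
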