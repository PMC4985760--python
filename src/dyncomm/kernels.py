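"""Similarity views of a snapshot graph.

Each node i is represented by the i-th column of the snapshot adjacency
matrix (an n-dimensional feature vector), and a *similarity view* is a
kernel applied to those feature vectors: the linear kernel (inner
products) or the Gaussian kernel with bandwidth sigma taken as the
median of the pairwise Euclidean distances unless given explicitly.
Diagonals are zeroed by default: self-similarity contributes nothing to
a graph cut.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .graph import SnapshotGraph

__all__ = [
    "SIGMA_FLOOR",
    "KernelSpec",
    "FeatureMatrix",
    "SimilarityView",
    "adjacency_features",
    "median_bandwidth",
    "linear_similarity",
    "gaussian_similarity",
    "build_views",
]

# Floor for a degenerate (zero) median distance: keeps the Gaussian
# kernel defined when all feature columns coincide.
SIGMA_FLOOR = 1e-12


@dataclass(frozen=True)
class KernelSpec:
    """Choice of kernel for one similarity view.

    kind : "linear" or "gaussian"
    sigma : bandwidth for the Gaussian kernel; None means use the
        median pairwise-distance heuristic at build time.
    zero_diagonal : zero self-similarity before Laplacian construction.
    """

    kind: str
    sigma: float | None = None
    zero_diagonal: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "gaussian"):
            raise ValueError(f"unknown kernel kind {self.kind!r}")
        if self.sigma is not None and self.sigma <= 0:
            raise ValueError("sigma must be positive")


@dataclass
class FeatureMatrix:
    """Adjacency-column feature vectors: column i of X describes node i."""

    node_ids: np.ndarray
    X: np.ndarray


@dataclass
class SimilarityView:
    """One kernel's symmetric nonnegative similarity matrix.

    ``kernel`` is None for a raw / precomputed similarity (e.g. the
    adjacency itself as used by the static baseline).
    """

    W: np.ndarray
    node_ids: np.ndarray
    kernel: KernelSpec | None = None

    @property
    def n_nodes(self) -> int:
        return self.W.shape[0]


def adjacency_features(graph: SnapshotGraph) -> FeatureMatrix:
    """Represent each node by its adjacency column, order preserved."""
    return FeatureMatrix(graph.node_ids.copy(), graph.adjacency.astype(float).copy())


def median_bandwidth(features: FeatureMatrix) -> float:
    """Median of pairwise Euclidean distances between feature columns.

    Returns :data:`SIGMA_FLOOR` instead of 0 when the columns coincide,
    so that downstream division by sigma stays defined.
    """
    X = features.X
    if X.shape[1] < 2:
        raise ValueError("median bandwidth needs at least 2 feature columns")
    d = pdist(X.T)
    med = float(np.median(d))
    return med if med > 0 else SIGMA_FLOOR


def _finalize(W: np.ndarray, zero_diagonal: bool) -> np.ndarray:
    W = (W + W.T) / 2.0  # exact symmetry despite BLAS round-off
    if zero_diagonal:
        np.fill_diagonal(W, 0.0)
    return W


def linear_similarity(
    features: FeatureMatrix, zero_diagonal: bool = True
) -> SimilarityView:
    """Inner-product (linear kernel) similarity between feature columns."""
    X = features.X
    W = _finalize(X.T @ X, zero_diagonal)
    spec = KernelSpec("linear", zero_diagonal=zero_diagonal)
    return SimilarityView(W=W, node_ids=features.node_ids.copy(), kernel=spec)


def gaussian_similarity(
    features: FeatureMatrix,
    sigma: float | None = None,
    zero_diagonal: bool = True,
) -> SimilarityView:
    """Gaussian kernel exp(-d^2 / (2 sigma^2)) between feature columns.

    With ``sigma=None`` the median pairwise-distance heuristic is used.
    """
    if sigma is None:
        sigma = median_bandwidth(features)
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    D = squareform(pdist(features.X.T))
    W = _finalize(np.exp(-(D**2) / (2.0 * sigma**2)), zero_diagonal)
    spec = KernelSpec("gaussian", sigma=float(sigma), zero_diagonal=zero_diagonal)
    return SimilarityView(W=W, node_ids=features.node_ids.copy(), kernel=spec)


def build_views(graph: SnapshotGraph, specs) -> list:
    """Build one :class:`SimilarityView` per kernel spec from a snapshot.

    ``specs`` may mix :class:`KernelSpec` instances and kind strings.
    """
    features = adjacency_features(graph)
    views = []
    for spec in specs:
        if isinstance(spec, str):
            spec = KernelSpec(spec)
        if spec.kind == "linear":
            views.append(linear_similarity(features, spec.zero_diagonal))
        else:
            views.append(
                gaussian_similarity(features, spec.sigma, spec.zero_diagonal)
            )
    return views
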