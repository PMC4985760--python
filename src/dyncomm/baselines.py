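"""Evolutionary spectral clustering baselines: PCQ and PCM.

Both methods trade off a current-snapshot clustering cost against a
temporal-smoothness cost with weight alpha (alpha = 1 ignores history):

* PCQ (preserving cluster quality) scores the current partition on the
  *previous data* as well — at the relaxed-eigenproblem level the
  snapshot cost matrix is blended with the previous snapshot's.
* PCM (preserving cluster membership) penalizes distance from the
  *previous relaxed membership* — the current cost matrix is blended
  with the previous embedding's projector U_{t-1} U_{t-1}^T.

Each comes in an NC (normalized cut) and an NA (average association)
variant.  These are structural reconstructions of the published
framework for comparison purposes, not bit-exact ports of its code;
node churn is handled by the same trim / zero-pad alignment as the
co-trained method.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
from sklearn.base import BaseEstimator

from .graph import DynamicNetwork
from .kernels import SimilarityView
from .mssc import CoTrainState, align_history
from .spectral import (
    Embedding,
    as_network,
    _k_per_snapshot,
    cluster_embedding,
    normalized_laplacian,
)

__all__ = ["EvolutionaryConfig", "pcq", "pcm", "EvolutionarySpectralClustering"]


@dataclass
class EvolutionaryConfig:
    """alpha in [0, 1] (weight on the current snapshot), NC/NA variant."""

    alpha: float = 0.9
    variant: str = "NC"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.variant not in ("NC", "NA"):
            raise ValueError(f"unknown variant {self.variant!r}")


def _cost_matrix(adjacency: np.ndarray, node_ids, variant: str) -> np.ndarray:
    """Matrix whose k extremal eigenvectors solve the static relaxation.

    NC: the normalized Laplacian (minimize, k smallest).
    NA: the similarity itself (maximize, k largest) — returned negated
    so that both variants minimize and share one eigensolver path.
    """
    if variant == "NC":
        view = SimilarityView(W=adjacency, node_ids=node_ids, kernel=None)
        return normalized_laplacian(view).L
    return -adjacency


def _bottom_k_embed(M: np.ndarray, node_ids, k: int) -> Embedding:
    vals, vecs = scipy.linalg.eigh(M, subset_by_index=(0, k - 1))
    return Embedding(U=vecs, node_ids=node_ids, eigenvalues=vals)


def _align_matrix(W, prev_ids, node_ids) -> np.ndarray:
    state = CoTrainState(node_ids=prev_ids, views=[W])
    return align_history(state, node_ids).views[0]


def _align_embedding(U, prev_ids, node_ids) -> np.ndarray:
    state = CoTrainState(node_ids=prev_ids, embeddings=[U])
    return align_history(state, node_ids).embeddings[0]


def _run_evolutionary(
    network: DynamicNetwork, k_list, cfg: EvolutionaryConfig, method: str
) -> list:
    k_list = _k_per_snapshot(k_list, network.n_snapshots)
    partitions = []
    prev_cost = prev_U = prev_ids = None
    for snap, k in zip(network.snapshots, k_list):
        A = snap.adjacency.astype(float)
        cost = _cost_matrix(A, snap.node_ids, cfg.variant)
        if prev_ids is None or cfg.alpha == 1.0:
            blended = cost
        elif method == "pcq":
            hist = _align_matrix(prev_cost, prev_ids, snap.node_ids)
            blended = cfg.alpha * cost + (1.0 - cfg.alpha) * hist
        else:  # pcm: reward staying inside the previous membership subspace
            Up = _align_embedding(prev_U, prev_ids, snap.node_ids)
            proj = Up @ Up.T
            n = len(snap.node_ids)
            hist = np.eye(n) - proj if cfg.variant == "NC" else -proj
            blended = cfg.alpha * cost + (1.0 - cfg.alpha) * hist
        emb = _bottom_k_embed((blended + blended.T) / 2.0, snap.node_ids, k)
        partitions.append(cluster_embedding(emb, k, cfg.seed + snap.t))
        prev_cost, prev_U, prev_ids = cost, emb.U, snap.node_ids
    return partitions


def pcq(network: DynamicNetwork, k_list, cfg: EvolutionaryConfig) -> list:
    """Preserving-cluster-quality evolutionary spectral clustering."""
    return _run_evolutionary(network, k_list, cfg, "pcq")


def pcm(network: DynamicNetwork, k_list, cfg: EvolutionaryConfig) -> list:
    """Preserving-cluster-membership evolutionary spectral clustering."""
    return _run_evolutionary(network, k_list, cfg, "pcm")


class EvolutionarySpectralClustering(BaseEstimator):
    """PCQ / PCM baselines behind one estimator.

    Parameters
    ----------
    method : "pcq" or "pcm"
    variant : "NC" (normalized cut) or "NA" (average association)
    alpha : weight on the current snapshot, in [0, 1]; 0.9 is the
        conventional comparison setting.
    """

    def __init__(
        self,
        n_clusters=2,
        method: str = "pcq",
        variant: str = "NC",
        alpha: float = 0.9,
        random_state: int = 0,
    ):
        self.n_clusters = n_clusters
        self.method = method
        self.variant = variant
        self.alpha = alpha
        self.random_state = random_state

    def fit(self, X, y=None):
        if self.method not in ("pcq", "pcm"):
            raise ValueError(f"unknown method {self.method!r}")
        net = as_network(X)
        cfg = EvolutionaryConfig(
            alpha=self.alpha, variant=self.variant, seed=self.random_state
        )
        runner = pcq if self.method == "pcq" else pcm
        self.partitions_ = runner(net, self.n_clusters, cfg)
        self.labels_ = [p.labels.copy() for p in self.partitions_]
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_
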