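"""Multi-similarity spectral clustering with dynamic co-training.

The method clusters each snapshot of a dynamic network using several
similarity views at once (by default a Gaussian and a linear kernel on
adjacency-column features).  Views are *co-trained*: the
cluster-discriminative eigenvectors of each view's normalized Laplacian
are used to project — and thereby denoise — the other views' similarity
matrices.  Temporal smoothness enters through a blended projector

    H_q = alpha * U_q^t (U_q^t)^T + (1 - alpha) * U_q^{t-1} (U_q^{t-1})^T,

a convex combination of the current and previous eigenvector projectors
of view q.  The temporal weight alpha is either fixed or estimated
adaptively from how much the raw similarity matrices drifted between
consecutive snapshots: a large drift keeps more history.  Node churn is
handled by trimming rows/columns of the carried history for removed
nodes and zero-padding for inserted ones (new nodes carry no historical
projection mass).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .graph import DynamicNetwork, Partition
from .kernels import KernelSpec, SimilarityView, build_views
from .spectral import (
    Embedding,
    as_network,
    _k_per_snapshot,
    cluster_embedding,
    normalized_laplacian,
    spectral_embed,
)

__all__ = [
    "MSSCConfig",
    "CoTrainState",
    "TemporalProjector",
    "adaptive_alpha",
    "temporal_projector",
    "cotrain_update",
    "align_history",
    "mssc_step",
    "run_mssc",
    "MultiSimilaritySpectralClustering",
]

_NORM_EPS = 1e-12


@dataclass
class MSSCConfig:
    """Configuration for the co-trained dynamic clustering.

    kernels : at least two kernel specs (or kind strings); the default
        Gaussian (median bandwidth) + linear pair.
    iterations : co-training rounds per snapshot.  One round already
        delivers most of the improvement and the iteration does not
        converge in general, so the default is 1.
    alpha_mode : "adaptive" (drift-based estimate, floored at
        ``alpha_floor``) or "fixed" (use ``alpha_fixed``).
    combine : "concat" (column-wise concatenation of all views' final
        embeddings) or "single_view" (use ``informative_view`` only).
    share_alpha : average the per-view alphas into one shared value.
    """

    kernels: tuple = ("gaussian", "linear")
    iterations: int = 1
    alpha_mode: str = "adaptive"
    alpha_fixed: float = 1.0
    combine: str = "concat"
    informative_view: int = 0
    alpha_floor: float = 0.5
    share_alpha: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.kernels) < 2:
            raise ValueError("co-training needs at least 2 similarity views")
        if self.iterations < 0:
            raise ValueError("iterations must be >= 0")
        if self.alpha_mode not in ("adaptive", "fixed"):
            raise ValueError(f"unknown alpha_mode {self.alpha_mode!r}")
        if not 0.0 <= self.alpha_floor <= 1.0:
            raise ValueError("alpha_floor must lie in [0, 1]")
        if self.alpha_mode == "fixed" and not 0.0 <= self.alpha_fixed <= 1.0:
            raise ValueError("alpha_fixed must lie in [0, 1]")
        if self.combine not in ("concat", "single_view"):
            raise ValueError(f"unknown combine {self.combine!r}")


@dataclass
class CoTrainState:
    """Per-view history carried between snapshots.

    ``embeddings`` holds one n x k eigenvector matrix per view (this
    snapshot's final, post-co-training embeddings), ``views`` the
    pre-co-training similarity matrices (the alpha estimator compares
    raw data drift, not co-trained output).
    """

    node_ids: np.ndarray | None = None
    embeddings: list | None = None
    views: list | None = None
    k: int | None = None
    alphas: list = field(default_factory=list)

    @property
    def is_empty(self) -> bool:
        return self.node_ids is None

    @classmethod
    def empty(cls) -> "CoTrainState":
        return cls()


@dataclass
class TemporalProjector:
    """Symmetric blend of current and historic eigenvector projectors."""

    H: np.ndarray
    alpha: float


def adaptive_alpha(
    view_t: SimilarityView,
    view_prev: SimilarityView,
    floor: float = 0.5,
) -> float:
    """Temporal weight from similarity drift, in [floor, 1].

    alpha = max(floor, 1 - ||W_t - W_{t-1}||_F / max(||W_t||_F,
    ||W_{t-1}||_F)).  Equal views give 1 (ignore history); a large
    relative drift pushes alpha down to the floor, never below: the
    current snapshot always carries at least as much weight as the
    past.  Scale-invariant: rescaling both matrices leaves it unchanged.
    """
    Wt, Wp = view_t.W, view_prev.W
    if Wt.shape != Wp.shape:
        raise ValueError(f"view shapes differ: {Wt.shape} vs {Wp.shape}")
    diff = float(np.linalg.norm(Wt - Wp))
    denom = max(float(np.linalg.norm(Wt)), float(np.linalg.norm(Wp)), _NORM_EPS)
    return float(max(floor, 1.0 - diff / denom))


def _as_u(emb) -> np.ndarray:
    return emb.U if isinstance(emb, Embedding) else np.asarray(emb, dtype=float)


def temporal_projector(U_t, U_prev, alpha: float) -> TemporalProjector:
    """H = alpha * U_t U_t^T + (1 - alpha) * U_prev U_prev^T.

    Column counts may differ (the community count may change between
    snapshots); row counts must agree (histories are aligned first).
    With orthonormal k-column factors trace(H) = alpha*k_t +
    (1-alpha)*k_{t-1}.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    Ut, Up = _as_u(U_t), _as_u(U_prev)
    if Ut.shape[0] != Up.shape[0]:
        raise ValueError(f"row counts differ: {Ut.shape[0]} vs {Up.shape[0]}")
    H = alpha * (Ut @ Ut.T) + (1.0 - alpha) * (Up @ Up.T)
    return TemporalProjector(H=(H + H.T) / 2.0, alpha=float(alpha))


def cotrain_update(view_p: SimilarityView, others: list) -> SimilarityView:
    """Project one view's similarity onto the other views' subspaces.

    S~_p = sym(H_bar S_p) with H_bar the mean of the other views'
    temporal projectors and sym(M) = (M + M^T)/2.
    """
    if not others:
        raise ValueError("co-training needs at least one other view")
    Hbar = np.mean([proj.H for proj in others], axis=0)
    if Hbar.shape[0] != view_p.W.shape[0]:
        raise ValueError("projector/similarity dimension mismatch")
    M = Hbar @ view_p.W
    return SimilarityView(
        W=(M + M.T) / 2.0, node_ids=view_p.node_ids, kernel=view_p.kernel
    )


def align_history(state: CoTrainState, node_ids_t) -> CoTrainState:
    """Align carried history to a snapshot's node set.

    Removed nodes lose their rows (and columns, for similarities);
    inserted nodes get zero rows/columns.  Output row order follows
    ``node_ids_t``.
    """
    node_ids_t = np.asarray(node_ids_t)
    if state.is_empty or np.array_equal(state.node_ids, node_ids_t):
        return state
    old_pos = {int(v): i for i, v in enumerate(state.node_ids)}
    new_idx, kept_old = [], []
    for j, v in enumerate(node_ids_t):
        i = old_pos.get(int(v))
        if i is not None:
            new_idx.append(j)
            kept_old.append(i)
    new_idx = np.asarray(new_idx, dtype=int)
    kept_old = np.asarray(kept_old, dtype=int)
    n_new = len(node_ids_t)

    embeddings = None
    if state.embeddings is not None:
        embeddings = []
        for U in state.embeddings:
            out = np.zeros((n_new, U.shape[1]))
            out[new_idx] = U[kept_old]
            embeddings.append(out)
    views = None
    if state.views is not None:
        views = []
        for W in state.views:
            out = np.zeros((n_new, n_new))
            out[np.ix_(new_idx, new_idx)] = W[np.ix_(kept_old, kept_old)]
            views.append(out)
    return CoTrainState(
        node_ids=node_ids_t.copy(),
        embeddings=embeddings,
        views=views,
        k=state.k,
        alphas=list(state.alphas),
    )


def _embed_matrix(W: np.ndarray, node_ids: np.ndarray, k: int) -> np.ndarray:
    view = SimilarityView(W=W, node_ids=node_ids, kernel=None)
    return spectral_embed(normalized_laplacian(view), k).U


def _sanitize(W: np.ndarray) -> np.ndarray:
    # Projection can create small negative entries and a nonzero
    # diagonal; clip both so the result is again a valid similarity.
    W = np.maximum(W, 0.0)
    np.fill_diagonal(W, 0.0)
    return W


def mssc_step(
    views: list,
    state: CoTrainState,
    k: int,
    cfg: MSSCConfig,
    seed: int | None = None,
):
    """One snapshot of co-trained clustering.

    Returns ``(partition, new_state)``; ``new_state.alphas`` records the
    per-view temporal weights used.
    """
    if len(views) < 2:
        raise ValueError("co-training needs at least 2 views")
    node_ids = views[0].node_ids
    for v in views[1:]:
        if not np.array_equal(v.node_ids, node_ids):
            raise ValueError("views must share one node set")
    if seed is None:
        seed = cfg.seed
    s = len(views)
    k = int(k)

    st = align_history(state, node_ids)
    raw = [v.W for v in views]
    U = [_embed_matrix(W, node_ids, k) for W in raw]

    if st.is_empty:
        alphas = [1.0] * s
        prev_U = [None] * s
    else:
        if cfg.alpha_mode == "fixed":
            alphas = [cfg.alpha_fixed] * s
        else:
            alphas = [
                adaptive_alpha(
                    views[q],
                    SimilarityView(st.views[q], node_ids),
                    cfg.alpha_floor,
                )
                for q in range(s)
            ]
        if cfg.share_alpha:
            alphas = [float(np.mean(alphas))] * s
        prev_U = st.embeddings

    def projectors(current_U):
        out = []
        for q in range(s):
            if prev_U[q] is None or alphas[q] == 1.0:
                H = current_U[q] @ current_U[q].T
                out.append(TemporalProjector((H + H.T) / 2.0, alphas[q]))
            else:
                out.append(temporal_projector(current_U[q], prev_U[q], alphas[q]))
        return out

    S = list(raw)
    H = projectors(U)
    for _ in range(cfg.iterations):
        S = [
            _sanitize(
                cotrain_update(
                    SimilarityView(S[p], node_ids, views[p].kernel),
                    [H[q] for q in range(s) if q != p],
                ).W
            )
            for p in range(s)
        ]
        U = [_embed_matrix(W, node_ids, k) for W in S]
        H = projectors(U)

    if cfg.combine == "concat":
        V = np.hstack(U)
    else:
        V = U[cfg.informative_view]
    partition = cluster_embedding(Embedding(U=V, node_ids=node_ids), k, seed)
    new_state = CoTrainState(
        node_ids=node_ids.copy(),
        embeddings=[u.copy() for u in U],
        views=[W.copy() for W in raw],
        k=k,
        alphas=list(alphas),
    )
    return partition, new_state


def run_mssc(network: DynamicNetwork, k_list, cfg: MSSCConfig) -> list:
    """Fold :func:`mssc_step` over the snapshots of a dynamic network."""
    k_list = _k_per_snapshot(k_list, network.n_snapshots)
    state = CoTrainState.empty()
    partitions = []
    for snap, k in zip(network.snapshots, k_list):
        views = build_views(snap, cfg.kernels)
        partition, state = mssc_step(views, state, k, cfg, seed=cfg.seed + snap.t)
        partitions.append(partition)
    return partitions


class MultiSimilaritySpectralClustering(BaseEstimator):
    """Dynamic community detection by multi-view co-trained spectral
    clustering with temporal smoothing.

    Parameters mirror :class:`MSSCConfig`; ``n_clusters`` may be a
    scalar or one value per snapshot, and ``random_state`` seeds the
    k-means stage (snapshot t uses ``random_state + t``).

    Attributes
    ----------
    labels_ : list of ndarray
        Per-snapshot community labels.
    partitions_ : list of Partition
    alphas_ : list of list of float
        Per-snapshot, per-view temporal weights actually used.
    """

    def __init__(
        self,
        n_clusters=2,
        kernels=("gaussian", "linear"),
        iterations: int = 1,
        alpha_mode: str = "adaptive",
        alpha_fixed: float = 1.0,
        alpha_floor: float = 0.5,
        share_alpha: bool = False,
        combine: str = "concat",
        informative_view: int = 0,
        random_state: int = 0,
    ):
        self.n_clusters = n_clusters
        self.kernels = kernels
        self.iterations = iterations
        self.alpha_mode = alpha_mode
        self.alpha_fixed = alpha_fixed
        self.alpha_floor = alpha_floor
        self.share_alpha = share_alpha
        self.combine = combine
        self.informative_view = informative_view
        self.random_state = random_state

    def _config(self) -> MSSCConfig:
        kernels = tuple(
            k if isinstance(k, KernelSpec) else str(k) for k in self.kernels
        )
        return MSSCConfig(
            kernels=kernels,
            iterations=self.iterations,
            alpha_mode=self.alpha_mode,
            alpha_fixed=self.alpha_fixed,
            combine=self.combine,
            informative_view=self.informative_view,
            alpha_floor=self.alpha_floor,
            share_alpha=self.share_alpha,
            seed=self.random_state,
        )

    def fit(self, X, y=None):
        net = as_network(X)
        cfg = self._config()
        k_list = _k_per_snapshot(self.n_clusters, net.n_snapshots)
        state = CoTrainState.empty()
        self.partitions_, self.alphas_ = [], []
        for snap, k in zip(net.snapshots, k_list):
            views = build_views(snap, cfg.kernels)
            partition, state = mssc_step(
                views, state, k, cfg, seed=cfg.seed + snap.t
            )
            self.partitions_.append(partition)
            self.alphas_.append(list(state.alphas))
        self.labels_ = [p.labels.copy() for p in self.partitions_]
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_
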