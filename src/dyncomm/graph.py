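"""Core containers: snapshot graphs, dynamic networks and hard partitions.

A dynamic network is an ordered sequence of *snapshots*: undirected,
weighted graphs observed at discrete times t = 1..T.  Node sets may
differ between snapshots (nodes churn in and out).  Ground-truth
community structure, when known, is carried as one :class:`Partition`
per snapshot.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SnapshotGraph", "DynamicNetwork", "Partition"]


def _as_id_array(node_ids) -> np.ndarray:
    ids = np.asarray(node_ids)
    if ids.ndim != 1:
        raise ValueError("node_ids must be one-dimensional")
    if len(np.unique(ids)) != len(ids):
        raise ValueError("node_ids contains duplicates")
    return ids


@dataclass
class SnapshotGraph:
    """One time slice of a dynamic network.

    Parameters
    ----------
    node_ids : array-like of int
        Ordered node identifiers; defines the row/column order of
        ``adjacency``.
    adjacency : ndarray of shape (n, n)
        Symmetric, nonnegative edge-weight matrix with zero diagonal
        (no self-loops).
    t : int
        1-based snapshot index.
    """

    node_ids: np.ndarray
    adjacency: np.ndarray
    t: int = 1

    def __post_init__(self) -> None:
        self.node_ids = _as_id_array(self.node_ids)
        A = np.asarray(self.adjacency, dtype=float)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError(f"adjacency must be square, got shape {A.shape}")
        if A.shape[0] != len(self.node_ids):
            raise ValueError("adjacency size does not match node_ids")
        if not np.array_equal(A, A.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(A < 0):
            raise ValueError("adjacency must be nonnegative")
        if np.any(np.diagonal(A) != 0):
            raise ValueError("self-loops are not allowed")
        self.adjacency = A

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def index_of(self) -> dict:
        """Mapping node id -> row index."""
        return {int(v): i for i, v in enumerate(self.node_ids)}


@dataclass
class Partition:
    """Hard community assignment over an ordered node set.

    ``labels[i]`` is the community of ``node_ids[i]``.  Label values are
    arbitrary integers; only the induced grouping matters.
    """

    node_ids: np.ndarray
    labels: np.ndarray
    k: int | None = None

    def __post_init__(self) -> None:
        self.node_ids = _as_id_array(self.node_ids)
        self.labels = np.asarray(self.labels)
        if self.labels.shape != self.node_ids.shape:
            raise ValueError("labels and node_ids must have equal length")
        if self.k is None:
            self.k = int(len(np.unique(self.labels)))

    @classmethod
    def from_mapping(cls, mapping: dict, node_ids=None) -> "Partition":
        if node_ids is None:
            node_ids = sorted(mapping)
        node_ids = np.asarray(node_ids)
        labels = np.array([mapping[int(v)] for v in node_ids])
        return cls(node_ids, labels)

    def to_mapping(self) -> dict:
        return {int(v): int(c) for v, c in zip(self.node_ids, self.labels)}

    def to_indicator(self) -> np.ndarray:
        """Binary n x k indicator matrix with exactly one 1 per row.

        Columns are ordered by sorted distinct label value.
        """
        uniq, inverse = np.unique(self.labels, return_inverse=True)
        Z = np.zeros((len(self.labels), len(uniq)))
        Z[np.arange(len(self.labels)), inverse] = 1.0
        return Z

    @property
    def n_communities(self) -> int:
        return int(len(np.unique(self.labels)))


@dataclass
class DynamicNetwork:
    """An ordered sequence of snapshots with optional ground truth."""

    snapshots: list
    truth: list | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for i, snap in enumerate(self.snapshots, start=1):
            if snap.t != i:
                raise ValueError(
                    f"snapshot indices must be 1..T in order, got t={snap.t} at position {i}"
                )
        if self.truth is not None and len(self.truth) != len(self.snapshots):
            raise ValueError("truth must have one Partition per snapshot")

    @property
    def n_snapshots(self) -> int:
        return len(self.snapshots)

    def __iter__(self):
        return iter(self.snapshots)
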