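import numpy as np
import pytest

from dyncomm import DynamicNetwork, Partition, SnapshotGraph


def two_cliques_adjacency(size: int = 6, bridge: bool = True) -> np.ndarray:
    """Two cliques of `size` nodes, optionally joined by one edge."""
    n = 2 * size
    A = np.zeros((n, n))
    A[:size, :size] = 1.0
    A[size:, size:] = 1.0
    np.fill_diagonal(A, 0.0)
    if bridge:
        A[0, size] = A[size, 0] = 1.0
    return A


@pytest.fixture
def two_cliques() -> SnapshotGraph:
    return SnapshotGraph(np.arange(12), two_cliques_adjacency(), t=1)


@pytest.fixture
def two_cliques_truth() -> Partition:
    return Partition(np.arange(12), np.repeat([0, 1], 6))


@pytest.fixture
def stable_toy_network() -> DynamicNetwork:
    """Three identical snapshots of the bridged two-clique graph."""
    A = two_cliques_adjacency()
    snaps = [SnapshotGraph(np.arange(12), A, t=t) for t in (1, 2, 3)]
    truth = [Partition(np.arange(12), np.repeat([0, 1], 6)) for _ in range(3)]
    return DynamicNetwork(snapshots=snaps, truth=truth)


@pytest.fixture
def path3() -> SnapshotGraph:
    A = np.array([[0.0, 1, 0], [1, 0, 1], [0, 1, 0]])
    return SnapshotGraph(np.array([1, 2, 3]), A, t=1)
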