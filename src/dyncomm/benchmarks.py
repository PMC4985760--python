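"""Seeded generators for synthetic dynamic community benchmarks.

Three families:

* ``gn_dynamic`` — the classic four-community planted-partition
  benchmark (128 nodes, 4 communities of 32) made dynamic: at every
  snapshot after the first, Cn randomly chosen members of each
  community leave it and join one of the other communities uniformly;
  edges are redrawn independently per snapshot from the membership-
  conditional probabilities p_in, p_out.  z is the expected number of a
  node's edges ending in other communities, the total expected degree
  is held constant.
* ``syn_fix`` / ``syn_var`` — fixed- and variable-community-count
  variants: SYN-FIX is the 128-node benchmark with 3 switchers per
  community; SYN-VAR starts from 256 nodes in 4 communities of 64,
  births a 32-node community (8 nodes from each original community) at
  each t in 2..5, dissolves it 5 timestamps later, and additionally
  removes and adds 16 nodes per snapshot.
* ``event`` — a 1000-node, 10-snapshot configuration-model benchmark
  with community sizes in [20, 100], target mean degree 15 capped at
  50, mixing parameter mu, a 20% per-snapshot membership permutation,
  and exactly one embedded dynamic-community event (birth+death,
  expansion, contraction, merge+split, or switch).

All generators are deterministic functions of their seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .graph import DynamicNetwork, Partition, SnapshotGraph

__all__ = [
    "BenchmarkSpec",
    "EdgeProbabilities",
    "gn_probabilities",
    "gen_gn_dynamic",
    "gen_syn_fix",
    "gen_syn_var",
    "gen_event_network",
    "generate",
]

EVENT_KINDS = ("birth_death", "expand", "contract", "merge_split", "switch")


@dataclass(frozen=True)
class EdgeProbabilities:
    """Within- and between-community edge probabilities."""

    p_in: float
    p_out: float

    def __post_init__(self) -> None:
        for name, p in (("p_in", self.p_in), ("p_out", self.p_out)):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")


@dataclass
class BenchmarkSpec:
    """Serializable description of a benchmark draw (for manifests)."""

    family: str = "gn_dynamic"
    n: int = 128
    k0: int = 4
    z: float = 4.0
    avg_degree: float = 16.0
    cn: int = 1
    T: int = 10
    event: str = "birth_death"
    mu: float = 0.0
    mean_deg: float = 15.0
    max_deg: int = 50
    size_range: tuple = (20, 100)
    perm_frac: float = 0.2
    churn_total: bool = False
    seed: int | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        d["size_range"] = list(self.size_range)
        return d


def gn_probabilities(
    n: int, k0: int, z: float, avg_degree: float
) -> EdgeProbabilities:
    """Edge probabilities giving expected inter-degree z and total
    expected degree avg_degree, for k0 equal communities of n/k0 nodes.
    """
    if n % k0 != 0:
        raise ValueError("n must be divisible by k0 (equal community sizes)")
    if z >= avg_degree:
        raise ValueError("z must be smaller than the average degree")
    nc = n // k0
    p_out = z / (n - nc)
    p_in = (avg_degree - z) / (nc - 1)
    return EdgeProbabilities(p_in=p_in, p_out=p_out)


def _draw_edges(memberships: np.ndarray, P: np.ndarray, rng) -> np.ndarray:
    """Symmetric 0/1 adjacency from a per-pair probability matrix."""
    n = len(memberships)
    R = rng.random((n, n))
    upper = np.triu(R < P, 1)
    return (upper | upper.T).astype(float)


def _gn_adjacency(memberships, probs: EdgeProbabilities, rng) -> np.ndarray:
    same = memberships[:, None] == memberships[None, :]
    P = np.where(same, probs.p_in, probs.p_out)
    return _draw_edges(memberships, P, rng)


def gen_gn_dynamic(
    n: int = 128,
    k0: int = 4,
    z: float = 4.0,
    avg_degree: float = 16.0,
    cn: int = 1,
    T: int = 10,
    seed: int | None = None,
    churn_total: bool = False,
) -> DynamicNetwork:
    """Dynamic planted-partition benchmark with membership churn.

    ``cn`` switchers are drawn per community per snapshot; with
    ``churn_total=True`` they are drawn from the whole network instead.
    """
    rng = np.random.default_rng(seed)
    probs = gn_probabilities(n, k0, z, avg_degree)
    node_ids = np.arange(n)
    memberships = np.repeat(np.arange(k0), n // k0)

    snapshots, truths = [], []
    for t in range(1, T + 1):
        if t > 1:
            before = memberships.copy()
            if churn_total:
                movers = rng.choice(n, size=min(cn, n), replace=False)
            else:
                movers = np.concatenate(
                    [
                        rng.choice(
                            np.flatnonzero(before == c),
                            size=min(cn, int((before == c).sum())),
                            replace=False,
                        )
                        for c in range(k0)
                    ]
                )
            for i in movers:
                others = [c for c in range(k0) if c != before[i]]
                memberships[i] = rng.choice(others)
        A = _gn_adjacency(memberships, probs, rng)
        snapshots.append(SnapshotGraph(node_ids.copy(), A, t=t))
        truths.append(Partition(node_ids.copy(), memberships.copy(), k=k0))
    meta = {"family": "gn_dynamic", "n": n, "k0": k0, "z": z,
            "avg_degree": avg_degree, "cn": cn, "T": T, "seed": seed}
    return DynamicNetwork(snapshots=snapshots, truth=truths, meta=meta)


def gen_syn_fix(z: float, T: int = 10, seed: int | None = None) -> DynamicNetwork:
    """SYN-FIX: the 128-node benchmark, average degree 16, 3 switchers
    per community per snapshot."""
    net = gen_gn_dynamic(
        n=128, k0=4, z=z, avg_degree=16.0, cn=3, T=T, seed=seed
    )
    net.meta["family"] = "syn_fix"
    return net


def _varsize_adjacency(memberships, z, avg_degree, rng) -> np.ndarray:
    """Planted edges for unequal community sizes.

    Within community c: p = (avg_degree - z) / (|c| - 1).  Between, the
    two endpoint communities' z / (n - |c|) rates are averaged so each
    node keeps expected inter-degree ~ z.
    """
    n = len(memberships)
    uniq, inverse = np.unique(memberships, return_inverse=True)
    sizes = np.bincount(inverse)
    size_of = sizes[inverse].astype(float)
    p_in_node = np.minimum((avg_degree - z) / np.maximum(size_of - 1, 1), 1.0)
    p_out_node = z / np.maximum(n - size_of, 1)
    same = inverse[:, None] == inverse[None, :]
    P = np.where(
        same,
        p_in_node[:, None],
        (p_out_node[:, None] + p_out_node[None, :]) / 2.0,
    )
    return _draw_edges(memberships, P, rng)


def gen_syn_var(z: float, T: int = 10, seed: int | None = None) -> DynamicNetwork:
    """SYN-VAR: community births at t=2..5, each dissolving after 5
    timestamps, plus 16 node removals and 16 insertions per snapshot.

    Community-count trajectory over t=1..10 is 4,5,6,7,8,8,7,6,5,4.
    Only T=10 is supported (the birth/dissolution schedule is tied to
    it).
    """
    if T != 10:
        raise ValueError("the birth/dissolution schedule requires T=10")
    rng = np.random.default_rng(seed)
    n0, k0, size0, avg_degree = 256, 4, 64, 16.0

    membership = {v: v // size0 for v in range(n0)}  # current community
    origin = dict(membership)  # community to return to after an excursion
    excursion = {}  # node -> temp community id, while away
    next_node = n0
    next_comm = k0
    births = {}  # temp community id -> birth time

    snapshots, truths = [], []
    for t in range(1, T + 1):
        if t > 1:
            # dissolve temp communities born 5 timestamps ago
            for cid, born in list(births.items()):
                if t - born >= 5:
                    for v in [v for v, c in excursion.items() if c == cid]:
                        membership[v] = origin[v]
                        del excursion[v]
                    del births[cid]
            # birth of a new 32-node community from 8 nodes per original
            if 2 <= t <= 5:
                cid = next_comm
                next_comm += 1
                births[cid] = t
                for c in range(k0):
                    pool = [
                        v
                        for v, m in membership.items()
                        if m == c and v not in excursion
                    ]
                    for v in rng.choice(pool, size=8, replace=False):
                        v = int(v)
                        excursion[v] = cid
                        membership[v] = cid
            # node churn: 16 out, 16 in (excursion nodes are exempt from
            # deletion so every departed node can return to its origin)
            deletable = [v for v in membership if v not in excursion]
            for v in rng.choice(deletable, size=16, replace=False):
                v = int(v)
                del membership[v]
                del origin[v]
            survivors = list(membership)
            hosts = rng.choice(survivors, size=16, replace=True)
            for host in hosts:
                v = next_node
                next_node += 1
                membership[v] = membership[int(host)]
                origin[v] = origin[int(host)]
                if int(host) in excursion:
                    excursion[v] = excursion[int(host)]
        node_ids = np.array(sorted(membership))
        labels = np.array([membership[v] for v in node_ids])
        A = _varsize_adjacency(labels, z, avg_degree, rng)
        snapshots.append(SnapshotGraph(node_ids, A, t=t))
        truths.append(Partition(node_ids.copy(), labels))
    meta = {"family": "syn_var", "z": z, "T": T, "seed": seed}
    return DynamicNetwork(snapshots=snapshots, truth=truths, meta=meta)


def _initial_sizes(n: int, size_range, rng) -> list:
    """Community sizes in [lo, hi] summing exactly to n."""
    lo, hi = size_range
    if not lo <= hi or n < lo:
        raise ValueError("infeasible size constraints")
    sizes = []
    remaining = n
    while remaining > 0:
        if lo <= remaining <= hi:
            sizes.append(remaining)
            break
        # rejection keeps the tail completable: leave at least lo behind
        s = int(rng.integers(lo, hi + 1))
        if remaining - s < lo:
            continue
        sizes.append(s)
        remaining -= s
    return sizes


def _event_adjacency(labels, mu, mean_deg, max_deg, rng) -> np.ndarray:
    uniq, inverse = np.unique(labels, return_inverse=True)
    sizes = np.bincount(inverse)
    size_of = sizes[inverse].astype(float)
    n = len(labels)
    p_in = np.minimum((1.0 - mu) * mean_deg / np.maximum(size_of - 1, 1), 1.0)
    p_out = mu * mean_deg / np.maximum(n - size_of, 1)
    same = inverse[:, None] == inverse[None, :]
    P = np.where(same, p_in[:, None], (p_out[:, None] + p_out[None, :]) / 2.0)
    A = _draw_edges(labels, P, rng)
    # enforce the degree cap by removing random incident edges
    deg = A.sum(axis=1)
    for i in np.flatnonzero(deg > max_deg):
        while A[i].sum() > max_deg:
            nbrs = np.flatnonzero(A[i])
            j = int(rng.choice(nbrs))
            A[i, j] = A[j, i] = 0.0
    return A


def _move_nodes(labels, src, dst, count, rng) -> None:
    pool = np.flatnonzero(labels == src)
    for v in rng.choice(pool, size=count, replace=False):
        labels[v] = dst


def gen_event_network(
    event: str = "birth_death",
    n: int = 1000,
    T: int = 10,
    mu: float = 0.0,
    mean_deg: float = 15.0,
    max_deg: int = 50,
    size_range=(20, 100),
    perm_frac: float = 0.2,
    seed: int | None = None,
) -> DynamicNetwork:
    """Event-based benchmark with one embedded dynamic-community event.

    Community labels are persistent across snapshots, so the truth
    sequence exposes the event to a set-overlap matcher (a community id
    appearing/disappearing, growing/shrinking, merging or splitting).
    """
    if event not in EVENT_KINDS:
        raise ValueError(f"unknown event {event!r}; pick one of {EVENT_KINDS}")
    lo, hi = size_range
    rng = np.random.default_rng(seed)
    sizes = _initial_sizes(n, size_range, rng)
    labels = np.repeat(np.arange(len(sizes)), sizes)
    rng.shuffle(labels)
    next_comm = len(sizes)
    node_ids = np.arange(n)

    def comm_sizes():
        u, c = np.unique(labels, return_counts=True)
        return dict(zip(u.tolist(), c.tolist()))

    def donors(needed, exclude=()):
        """Yield (community, count) pairs that can spare nodes."""
        out = []
        for c, s in sorted(comm_sizes().items(), key=lambda kv: -kv[1]):
            if c in exclude or s <= lo:
                continue
            take = min(s - lo, needed)
            if take > 0:
                out.append((c, take))
                needed -= take
            if needed == 0:
                break
        if needed > 0:
            raise ValueError("infeasible size constraints for the event")
        return out

    snapshots, truths = [], []
    for t in range(1, T + 1):
        if t > 1 and perm_frac > 0:
            m = int(round(perm_frac * n))
            chosen = rng.choice(n, size=m, replace=False)
            labels[chosen] = labels[rng.permutation(chosen)]
        if event == "birth_death":
            if t == 4:  # birth: a new community assembled from donors
                newborn = next_comm
                next_comm += 1
                for c, take in donors(2 * lo):
                    _move_nodes(labels, c, newborn, take, rng)
            if t == 7:  # death: a community dissolves into the others
                sizes_now = comm_sizes()
                victim = min(
                    (c for c in sizes_now if c != next_comm - 1),
                    key=lambda c: sizes_now[c],
                )
                members = np.flatnonzero(labels == victim)
                hosts = [c for c, s in sizes_now.items()
                         if c != victim and s + 1 <= hi]
                for v in members:
                    sizes_now = comm_sizes()
                    open_hosts = [c for c in hosts if sizes_now.get(c, 0) < hi]
                    labels[v] = int(rng.choice(open_hosts))
        elif event == "expand" and t == 5:
            sizes_now = comm_sizes()
            target = min(sizes_now, key=lambda c: sizes_now[c])
            grow = min(hi - sizes_now[target], 30)
            for c, take in donors(grow, exclude=(target,)):
                _move_nodes(labels, c, target, take, rng)
        elif event == "contract" and t == 5:
            sizes_now = comm_sizes()
            target = max(sizes_now, key=lambda c: sizes_now[c])
            shed = min(sizes_now[target] - lo, 30)
            moved = 0
            for c, s in sizes_now.items():
                if c == target or moved >= shed:
                    continue
                take = min(hi - s, shed - moved)
                if take > 0:
                    _move_nodes(labels, target, c, take, rng)
                    moved += take
        elif event == "merge_split":
            if t == 4:  # merge the two smallest compatible communities
                sizes_now = comm_sizes()
                order = sorted(sizes_now, key=lambda c: sizes_now[c])
                a, b = order[0], order[1]
                if sizes_now[a] + sizes_now[b] <= hi:
                    labels[labels == b] = a
            if t == 7:  # split the largest community in two
                sizes_now = comm_sizes()
                big = max(sizes_now, key=lambda c: sizes_now[c])
                members = np.flatnonzero(labels == big)
                half = len(members) // 2
                if half >= lo and len(members) - half >= lo:
                    part = rng.choice(members, size=half, replace=False)
                    labels[part] = next_comm
                    next_comm += 1
        elif event == "switch" and t == 5:
            sizes_now = comm_sizes()
            order = sorted(sizes_now, key=lambda c: -sizes_now[c])
            a, b = order[0], order[1]
            swap = min(10, sizes_now[a] - lo, sizes_now[b] - lo)
            if swap > 0:
                pool_a = rng.choice(np.flatnonzero(labels == a), swap, replace=False)
                pool_b = rng.choice(np.flatnonzero(labels == b), swap, replace=False)
                labels[pool_a] = b
                labels[pool_b] = a
        A = _event_adjacency(labels, mu, mean_deg, max_deg, rng)
        snapshots.append(SnapshotGraph(node_ids.copy(), A, t=t))
        truths.append(Partition(node_ids.copy(), labels.copy()))
    meta = {"family": "event", "event": event, "n": n, "T": T, "mu": mu,
            "mean_deg": mean_deg, "max_deg": max_deg,
            "size_range": list(size_range), "perm_frac": perm_frac,
            "seed": seed}
    return DynamicNetwork(snapshots=snapshots, truth=truths, meta=meta)


def generate(spec: BenchmarkSpec) -> DynamicNetwork:
    """Dispatch a :class:`BenchmarkSpec` to the matching generator."""
    if spec.family == "gn_dynamic":
        return gen_gn_dynamic(
            n=spec.n, k0=spec.k0, z=spec.z, avg_degree=spec.avg_degree,
            cn=spec.cn, T=spec.T, seed=spec.seed, churn_total=spec.churn_total,
        )
    if spec.family == "syn_fix":
        return gen_syn_fix(z=spec.z, T=spec.T, seed=spec.seed)
    if spec.family == "syn_var":
        return gen_syn_var(z=spec.z, T=spec.T, seed=spec.seed)
    if spec.family == "event":
        return gen_event_network(
            event=spec.event, n=spec.n, T=spec.T, mu=spec.mu,
            mean_deg=spec.mean_deg, max_deg=spec.max_deg,
            size_range=tuple(spec.size_range), perm_frac=spec.perm_frac,
            seed=spec.seed,
        )
    raise ValueError(f"unknown benchmark family {spec.family!r}")
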