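"""On-disk formats and the experiment runner.

A dynamic network is stored as one directory with, per snapshot t,
``snap_%03d.tsv`` (lines ``u<TAB>v<TAB>weight``, integer 0-based node
ids, each undirected edge once with u < v) and optionally
``snap_%03d.labels.tsv`` (lines ``node<TAB>community``), plus a
``manifest.json`` recording snapshot count, node counts, the generator
spec and seed.  Snapshots are 1-based in filenames.

:func:`run_experiment` reproduces the synthetic-benchmark protocol:
repeat (generate network, cluster, evaluate) over seeded runs and
aggregate NMI/SSE first over snapshots, then over runs.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .baselines import EvolutionaryConfig, pcm, pcq
from .benchmarks import BenchmarkSpec, generate
from .graph import DynamicNetwork, Partition, SnapshotGraph
from .metrics import evaluate_run
from .mssc import MSSCConfig, run_mssc
from .spectral import static_spectral

__all__ = [
    "write_dynamic_network",
    "read_dynamic_network",
    "ExperimentConfig",
    "run_experiment",
]

logger = logging.getLogger(__name__)


def write_dynamic_network(net: DynamicNetwork, directory) -> dict:
    """Serialize a dynamic network; returns the manifest dict."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for snap in net.snapshots:
        lines = []
        idx = snap.node_ids
        A = snap.adjacency
        order = np.argsort(idx)
        for ai in order:
            for aj in order:
                u, v = int(idx[ai]), int(idx[aj])
                if u < v and A[ai, aj] != 0:
                    lines.append(f"{u}\t{v}\t{float(A[ai, aj])!r}")
        (directory / f"snap_{snap.t:03d}.tsv").write_text(
            "\n".join(lines) + ("\n" if lines else "")
        )
        if net.truth is not None:
            truth = net.truth[snap.t - 1]
            label_lines = [
                f"{int(v)}\t{int(c)}"
                for v, c in sorted(truth.to_mapping().items())
            ]
            (directory / f"snap_{snap.t:03d}.labels.tsv").write_text(
                "\n".join(label_lines) + "\n"
            )
    manifest = {
        "snapshots": net.n_snapshots,
        "node_counts": [snap.n_nodes for snap in net.snapshots],
        "spec": net.meta or None,
        "seed": (net.meta or {}).get("seed"),
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def _parse_edge_file(path: Path):
    edges = {}
    nodes = set()
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            raw = raw.rstrip("\n")
            if not raw:
                continue
            parts = raw.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{ln}: expected 'u<TAB>v<TAB>weight'")
            try:
                u, v, w = int(parts[0]), int(parts[1]), float(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: {exc}") from None
            if u >= v:
                raise ValueError(f"{path}:{ln}: edges must be written with u < v")
            if (u, v) in edges:
                raise ValueError(f"{path}:{ln}: duplicate edge ({u}, {v})")
            edges[(u, v)] = w
            nodes.update((u, v))
    return edges, nodes


def read_dynamic_network(directory) -> DynamicNetwork:
    """Load a dynamic network written by :func:`write_dynamic_network`.

    Tolerates a missing manifest (with a warning).  Node sets are the
    union of edge endpoints and any labeled nodes, so isolated nodes
    survive a round trip whenever truth labels are present.
    """
    directory = Path(directory)
    edge_files = sorted(directory.glob("snap_[0-9][0-9][0-9].tsv"))
    if not edge_files:
        raise ValueError(f"no snapshot files found in {directory}")
    indices = [int(p.stem.split("_")[1]) for p in edge_files]
    if indices != list(range(1, len(indices) + 1)):
        raise ValueError(f"snapshot indices not contiguous from 1: {indices}")
    manifest = None
    manifest_path = directory / "manifest.json"
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
    else:
        warnings.warn(f"{directory}: no manifest.json; loading leniently")

    snapshots, truths, any_truth = [], [], False
    for t, path in zip(indices, edge_files):
        edges, nodes = _parse_edge_file(path)
        labels_path = directory / f"snap_{t:03d}.labels.tsv"
        mapping = None
        if labels_path.exists():
            mapping = {}
            with open(labels_path) as fh:
                for ln, raw in enumerate(fh, start=1):
                    raw = raw.rstrip("\n")
                    if not raw:
                        continue
                    parts = raw.split("\t")
                    if len(parts) != 2:
                        raise ValueError(
                            f"{labels_path}:{ln}: expected 'node<TAB>community'"
                        )
                    mapping[int(parts[0])] = int(parts[1])
            nodes.update(mapping)
        node_ids = np.array(sorted(nodes))
        pos = {v: i for i, v in enumerate(node_ids)}
        A = np.zeros((len(node_ids), len(node_ids)))
        for (u, v), w in edges.items():
            A[pos[u], pos[v]] = A[pos[v], pos[u]] = w
        snapshots.append(SnapshotGraph(node_ids, A, t=t))
        if mapping is not None:
            any_truth = True
            labeled = np.array(sorted(mapping))
            truths.append(
                Partition(labeled, np.array([mapping[v] for v in labeled]))
            )
            if len(labeled) < len(node_ids):
                logger.info(
                    "%s: truth covers %d of %d nodes (partial)",
                    labels_path, len(labeled), len(node_ids),
                )
        else:
            truths.append(None)
    truth = truths if any_truth else None
    meta = (manifest or {}).get("spec") or {}
    return DynamicNetwork(snapshots=snapshots, truth=truth, meta=meta)


@dataclass
class ExperimentConfig:
    """One benchmark x method cell of the synthetic-experiment protocol."""

    benchmark: BenchmarkSpec
    method: str = "mssc"  # mssc | static | pcq | pcm
    method_params: dict = field(default_factory=dict)
    k: int | list = 4
    runs: int = 10
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.runs < 1:
            raise ValueError("runs must be >= 1")
        if self.method not in ("mssc", "static", "pcq", "pcm"):
            raise ValueError(f"unknown method {self.method!r}")


def _run_method(method: str, net: DynamicNetwork, k, params: dict, seed: int):
    if method == "mssc":
        cfg = MSSCConfig(seed=seed, **params)
        return run_mssc(net, k, cfg)
    if method == "static":
        if np.isscalar(k):
            k = [int(k)] * net.n_snapshots
        return [
            static_spectral(snap, kk, seed + snap.t)
            for snap, kk in zip(net.snapshots, k)
        ]
    cfg = EvolutionaryConfig(seed=seed, **params)
    runner = pcq if method == "pcq" else pcm
    return runner(net, k, cfg)


def run_experiment(cfg: ExperimentConfig) -> pd.DataFrame:
    """Run `runs` seeded repetitions of one benchmark/method cell.

    Returns per-snapshot rows plus one aggregate row (run == "all")
    whose nmi/sse are the mean over all run x snapshot values and whose
    *_std columns are the matching standard deviations.  Deterministic
    given ``cfg.seed``.  Writes ``results.csv`` under ``out_dir`` when
    set.
    """
    children = np.random.SeedSequence(cfg.seed).spawn(cfg.runs)
    rows = []
    for r, child in enumerate(children, start=1):
        gen_seed, method_seed = (
            int(s) for s in child.generate_state(2) % (2**31)
        )
        spec = BenchmarkSpec(**{**cfg.benchmark.to_dict(), "seed": gen_seed})
        net = generate(spec)
        partitions = _run_method(
            cfg.method, net, cfg.k, dict(cfg.method_params), method_seed
        )
        record = evaluate_run(partitions, net.truth)
        for t, (v_nmi, v_sse) in enumerate(
            zip(record.per_snapshot_nmi, record.per_snapshot_sse), start=1
        ):
            rows.append(
                {"run": str(r), "snapshot": t, "method": cfg.method,
                 "nmi": v_nmi, "sse": v_sse}
            )
        logger.info(
            "run %d: mean NMI %.4f, mean SSE %.2f",
            r, record.mean_nmi, record.mean_sse,
        )
    df = pd.DataFrame(rows)
    aggregate = {
        "run": "all", "snapshot": 0, "method": cfg.method,
        "nmi": df["nmi"].mean(), "sse": df["sse"].mean(),
        "nmi_std": df["nmi"].std(ddof=0), "sse_std": df["sse"].std(ddof=0),
    }
    df = pd.concat([df, pd.DataFrame([aggregate])], ignore_index=True)
    if cfg.out_dir is not None:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / "results.csv", index=False)
    return df
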