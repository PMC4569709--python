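"""Serialization of run results: CSV logs, edge lists, GraphML, JSON summaries."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .experiments import RunResult
from .networks import AcousticNetwork, ClanResult, build_network
from .similarity import SimilarityMatrix

__all__ = [
    "write_similarity",
    "write_edgelist",
    "write_graphml",
    "write_partition",
    "write_results",
]


def write_similarity(sim: SimilarityMatrix, path: str | Path) -> None:
    """Delimited similarity matrix with unit ids as header row and column."""
    pd.DataFrame(sim.values, index=sim.unit_ids, columns=sim.unit_ids).to_csv(path)


def write_edgelist(net: AcousticNetwork, path: str | Path) -> None:
    """Tab-delimited weighted edge list: node_a, node_b, weight."""
    with open(path, "w") as fh:
        fh.write("node_a\tnode_b\tweight\n")
        for a, b, w in net.edge_list():
            fh.write(f"{a}\t{b}\t{w:.10g}\n")


def read_edgelist(path: str | Path) -> AcousticNetwork:
    """Inverse of :func:`write_edgelist`."""
    df = pd.read_csv(path, sep="\t")
    nodes = sorted(set(df["node_a"]) | set(df["node_b"]))
    pos = {u: i for i, u in enumerate(nodes)}
    a = np.zeros((len(nodes), len(nodes)))
    for _, row in df.iterrows():
        i, j = pos[row["node_a"]], pos[row["node_b"]]
        a[i, j] = a[j, i] = row["weight"]
    return AcousticNetwork(node_ids=[int(u) for u in nodes], adjacency=a)


def write_graphml(net: AcousticNetwork, path: str | Path) -> None:
    net.to_igraph().write_graphml(str(path))


def write_partition(clans: ClanResult, path: str | Path) -> None:
    """CSV mapping unit_id -> clan label."""
    pd.DataFrame(
        {"unit_id": clans.node_ids, "clan": clans.membership}
    ).to_csv(path, index=False)


def write_results(result: RunResult, outdir: str | Path, version: str | None = None) -> dict:
    """Write all artifacts of a run; returns (and writes) the manifest.

    Creates the directory if needed; overwrites existing files (idempotent).
    """
    if version is None:
        from . import __version__ as version
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: list[str] = []

    result.population_log.to_csv(outdir / "population_log.csv", index=False)
    files.append("population_log.csv")

    if result.similarity is not None:
        write_similarity(result.similarity, outdir / "similarity_matrix.csv")
        files.append("similarity_matrix.csv")
        net = build_network(result.similarity)
        write_edgelist(net, outdir / "edges.tsv")
        write_graphml(net, outdir / "network.graphml")
        files.extend(["edges.tsv", "network.graphml"])
    if result.clans is not None:
        write_partition(result.clans, outdir / "partition.csv")
        files.append("partition.csv")

    summary = {
        "abm_id": result.scenario.abm_id,
        "mechanism": result.scenario.mechanism,
        "biases": sorted(result.scenario.biases),
        "level": result.scenario.level,
        "years": result.years,
        "extinct": result.extinct,
        "n_units": result.n_units,
        "mean_similarity": result.mean_similarity,
        "sd_similarity": result.sd_similarity,
        "q": None if result.clans is None else result.clans.q,
        "ci95": None if result.clans is None else list(result.clans.ci95),
        "significant": result.significant,
        "n_clans": None if result.clans is None else result.clans.n_clans,
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
    files.append("summary.json")

    manifest = {
        "seed": result.seed,
        "abm_id": result.scenario.abm_id,
        "years": result.years,
        "version": version,
        "files": files,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
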