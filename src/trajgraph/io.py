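"""Delimited-text I/O for data matrices, embedded graphs and labels.

Graphs travel as a pair of TSV files — ``<prefix>.nodes.tsv`` with columns
``node_id, coord_1..coord_m`` and ``<prefix>.edges.tsv`` with columns
``source_id, target_id`` (0-based integer ids) — plus an optional GraphML
export for interoperability with general graph tooling.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .graph import EmbeddedGraph, SegmentDecomposition


def read_data_matrix(path: str | Path) -> np.ndarray:
    """Read a points-x-features matrix from TSV/CSV (header optional) or .npy."""
    path = Path(path)
    if path.suffix == ".npy":
        return np.asarray(np.load(path), dtype=float)
    sep = "," if path.suffix == ".csv" else "\t"
    first = pd.read_csv(path, sep=sep, header=None, nrows=1)
    try:
        first.astype(float)
        header = None
    except (ValueError, TypeError):
        header = 0
    return pd.read_csv(path, sep=sep, header=header).to_numpy(dtype=float)


def write_data_matrix(data: np.ndarray, path: str | Path) -> None:
    pd.DataFrame(np.asarray(data)).to_csv(path, sep="\t", header=False, index=False)


def write_graph(graph: EmbeddedGraph, prefix: str | Path) -> tuple[Path, Path]:
    prefix = Path(prefix)
    nodes_path = prefix.with_suffix(".nodes.tsv")
    edges_path = prefix.with_suffix(".edges.tsv")
    ndf = pd.DataFrame(
        graph.node_coords,
        columns=[f"coord_{i + 1}" for i in range(graph.ndim)],
    )
    ndf.insert(0, "node_id", np.arange(graph.n_nodes))
    ndf.to_csv(nodes_path, sep="\t", index=False)
    pd.DataFrame(graph.edges, columns=["source_id", "target_id"]).to_csv(
        edges_path, sep="\t", index=False
    )
    return nodes_path, edges_path


def read_graph(prefix: str | Path) -> EmbeddedGraph:
    prefix = Path(prefix)
    nodes = pd.read_csv(prefix.with_suffix(".nodes.tsv"), sep="\t")
    edges = pd.read_csv(prefix.with_suffix(".edges.tsv"), sep="\t")
    order = np.argsort(nodes["node_id"].to_numpy())
    coords = nodes.drop(columns=["node_id"]).to_numpy(dtype=float)[order]
    return EmbeddedGraph(coords, edges.to_numpy(dtype=int))


def write_segments(decomposition: SegmentDecomposition, path: str | Path) -> None:
    """segments.tsv: segment_id + ordered comma-separated node ids."""
    rows = [
        {"segment_id": sid, "node_path": ",".join(map(str, seg.node_path))}
        for sid, seg in enumerate(decomposition.segments)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_labels(labels: np.ndarray, path: str | Path) -> None:
    df = pd.DataFrame(
        {"point_index": np.arange(len(labels)), "segment_id": np.asarray(labels)}
    )
    df.to_csv(path, sep="\t", index=False)


def read_labels(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    return df.sort_values("point_index")["segment_id"].to_numpy(dtype=int)


def export_graphml(graph: EmbeddedGraph, path: str | Path) -> None:
    import networkx as nx

    g = nx.Graph()
    for i, xy in enumerate(graph.node_coords):
        g.add_node(i, **{f"coord_{k + 1}": float(c) for k, c in enumerate(xy)})
    g.add_edges_from(map(tuple, graph.edges))
    nx.write_graphml(g, str(path))
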