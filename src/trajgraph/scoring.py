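"""Segment-induced clustering of a data cloud and its scoring.

The comparison device: decompose an approximating graph into non-branching
segments, label every data point by its nearest segment, and then reuse the
well-established clustering machinery — pair-counting / information-theoretic
agreement scores to compare two graphs through the clusterings they induce,
and internal quality indices (silhouette, Calinski–Harabasz, Davies–Bouldin)
to score a single graph against the data without ground truth.

Point-to-segment proximity follows the nearest-*node* rule: a point takes
the segment of its nearest graph node; when that node is a branching node
shared by several segments, the second-nearest node among those segments'
nodes decides (recursing to the third nearest if that one is shared too,
then falling back to the smallest segment index).  An alternative
``assignment="projection"`` mode labels each point by the segment owning the
closest point of the piecewise-linear graph itself; it is costlier and kept
for sensitivity checks.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist
from sklearn import metrics as _skm

from .graph import EmbeddedGraph, SegmentDecomposition, decompose_into_segments

COMPARISON_METRICS = {
    "adjusted_rand": _skm.adjusted_rand_score,
    "adjusted_mutual_information": _skm.adjusted_mutual_info_score,
    "fowlkes_mallows": _skm.fowlkes_mallows_score,
    "v_measure": _skm.v_measure_score,
}

QUALITY_METRICS = {
    "silhouette": _skm.silhouette_score,
    "calinski_harabasz": _skm.calinski_harabasz_score,
    "davies_bouldin": _skm.davies_bouldin_score,
}

DEFAULT_COMPARISON_METRIC = "adjusted_rand"


def _as_points(data: np.ndarray) -> np.ndarray:
    pts = np.asarray(data, dtype=float)
    if pts.ndim != 2:
        raise ValueError(f"data must be 2-D (n_points, m); got shape {pts.shape}")
    if pts.shape[0] < 1:
        raise ValueError("data cloud must contain at least one point")
    if not np.isfinite(pts).all():
        raise ValueError("data cloud contains non-finite values")
    return pts


def assign_nearest_node(
    data: np.ndarray, graph: EmbeddedGraph
) -> tuple[np.ndarray, np.ndarray]:
    """Exact nearest graph node for every data point.

    Returns ``(nearest_node, distance)``.  Ties are broken by the smallest
    node index (``argmin`` returns the first minimum).
    """
    pts = _as_points(data)
    if pts.shape[1] != graph.ndim:
        raise ValueError(
            f"dimension mismatch: data has {pts.shape[1]} columns, "
            f"graph coordinates have {graph.ndim}"
        )
    d = cdist(pts, graph.node_coords)
    nearest = d.argmin(axis=1)
    return nearest, d[np.arange(len(pts)), nearest]


def _resolve_shared_node(
    order: np.ndarray,
    candidates: tuple[int, ...],
    decomposition: SegmentDecomposition,
) -> int:
    """Label for a point whose nearest node sits on several segments.

    ``order`` ranks all graph nodes by distance; ``candidates`` are the
    segment indices sharing the nearest node.  Walk down the ranking over
    nodes belonging to the candidate segments; each time the best node is
    itself shared among several surviving candidates, restrict to those and
    continue.  If the ranking is exhausted (all remaining nodes shared),
    fall back to the smallest segment index.
    """
    segs = decomposition.segments
    surviving = set(candidates)
    cand_nodes = set().union(*(segs[s].nodes for s in surviving))
    cand_nodes.discard(int(order[0]))
    for node in order[1:]:
        node = int(node)
        if node not in cand_nodes:
            continue
        owners = [s for s in surviving if node in segs[s].nodes]
        if len(owners) == 1:
            return owners[0]
        surviving = set(owners)
        cand_nodes = set().union(*(segs[s].nodes for s in surviving))
        cand_nodes.discard(node)
    return min(surviving)


def cluster_by_segments(
    data: np.ndarray,
    graph: EmbeddedGraph,
    decomposition: SegmentDecomposition | None = None,
    *,
    assignment: str = "node",
) -> np.ndarray:
    """Label every data point by its nearest graph segment.

    ``assignment="node"`` (default) implements the nearest-node rule with
    the second-nearest-node disambiguation at branching nodes;
    ``assignment="projection"`` labels by the segment containing the closest
    point of the piecewise-linear graph (orthogonal projection onto edges).
    """
    pts = _as_points(data)
    if decomposition is None:
        decomposition = decompose_into_segments(graph)
    if decomposition.n_segments == 0:
        raise ValueError("empty segment decomposition")
    if assignment == "projection":
        return _cluster_by_projection(pts, graph, decomposition)
    if assignment != "node":
        raise ValueError(f"unknown assignment mode {assignment!r}")
    if pts.shape[1] != graph.ndim:
        raise ValueError("dimension mismatch between data and graph")

    d = cdist(pts, graph.node_coords)
    nearest = d.argmin(axis=1)
    labels = np.empty(len(pts), dtype=int)
    node_to = decomposition.node_to_segments
    n_owned = np.array([len(node_to[v]) for v in range(graph.n_nodes)])
    unique_owner = np.array(
        [node_to[v][0] if node_to[v] else -1 for v in range(graph.n_nodes)]
    )
    simple = n_owned[nearest] == 1
    labels[simple] = unique_owner[nearest[simple]]
    for i in np.flatnonzero(~simple):
        order = np.argsort(d[i], kind="stable")
        labels[i] = _resolve_shared_node(order, node_to[nearest[i]], decomposition)
    return labels


def _cluster_by_projection(
    pts: np.ndarray, graph: EmbeddedGraph, decomposition: SegmentDecomposition
) -> np.ndarray:
    seg_of_edge = decomposition.segment_of_edge()
    # Distance from every point to every edge segment (clamped projection).
    a = graph.node_coords[graph.edges[:, 0]]
    b = graph.node_coords[graph.edges[:, 1]]
    ab = b - a
    denom = (ab * ab).sum(axis=1)
    denom[denom == 0] = 1.0
    best_d = np.full(len(pts), np.inf)
    labels = np.empty(len(pts), dtype=int)
    if graph.n_edges == 0:
        # Only edgeless segments: fall back to nearest node.
        nearest, _ = assign_nearest_node(pts, graph)
        return np.array(
            [decomposition.node_to_segments[v][0] for v in nearest], dtype=int
        )
    for eid in range(graph.n_edges):
        t = np.clip((pts - a[eid]) @ ab[eid] / denom[eid], 0.0, 1.0)
        proj = a[eid] + t[:, None] * ab[eid]
        dist = np.linalg.norm(pts - proj, axis=1)
        sid = seg_of_edge[tuple(int(x) for x in np.sort(graph.edges[eid]))]
        better = dist < best_d
        best_d[better] = dist[better]
        labels[better] = sid
    # Isolated-node segments compete through their node.
    for sid, seg in enumerate(decomposition.segments):
        if len(seg.node_path) == 1:
            dist = np.linalg.norm(
                pts - graph.node_coords[seg.node_path[0]], axis=1
            )
            better = dist < best_d
            best_d[better] = dist[better]
            labels[better] = sid
    return labels


def compare_clusterings(
    labels_a: np.ndarray, labels_b: np.ndarray, metric: str = DEFAULT_COMPARISON_METRIC
) -> float:
    """Agreement between two label vectors (graph-vs-graph similarity).

    Supported metrics: adjusted_rand, adjusted_mutual_information,
    fowlkes_mallows, v_measure.  The adjusted scores have expectation near
    zero for independent random labelings, which is why they are the
    default family here.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError(f"label vectors differ in length: {a.shape} vs {b.shape}")
    try:
        fn = COMPARISON_METRICS[metric]
    except KeyError:
        raise ValueError(
            f"unknown comparison metric {metric!r}; "
            f"choose from {sorted(COMPARISON_METRICS)}"
        ) from None
    return float(fn(a, b))


def clustering_quality(
    data: np.ndarray, labels: np.ndarray, metric: str = "silhouette"
) -> float:
    """Internal quality of a clustering of ``data`` (graph-vs-data score).

    silhouette in [-1, 1] (higher better); calinski_harabasz > 0 (higher
    better); davies_bouldin >= 0 (lower better).  At least two distinct
    labels are required.
    """
    pts = _as_points(data)
    lab = np.asarray(labels)
    if len(lab) != len(pts):
        raise ValueError("labels and data differ in length")
    if np.unique(lab).size < 2:
        raise ValueError(
            f"{metric} is undefined for a single cluster; "
            "the graph induces only one segment"
        )
    try:
        fn = QUALITY_METRICS[metric]
    except KeyError:
        raise ValueError(
            f"unknown quality metric {metric!r}; choose from {sorted(QUALITY_METRICS)}"
        ) from None
    return float(fn(pts, lab))


def compare_graphs_on_data(
    data: np.ndarray,
    graph_a: EmbeddedGraph,
    graph_b: EmbeddedGraph,
    metric: str = DEFAULT_COMPARISON_METRIC,
    *,
    assignment: str = "node",
) -> float:
    """Similarity of two approximating graphs through their induced clusterings."""
    la = cluster_by_segments(data, graph_a, assignment=assignment)
    lb = cluster_by_segments(data, graph_b, assignment=assignment)
    return compare_clusterings(la, lb, metric)


def score_graph_on_data(
    data: np.ndarray,
    graph: EmbeddedGraph,
    metric: str = "silhouette",
    *,
    assignment: str = "node",
) -> float:
    """Unsupervised quality of one approximating graph for a dataset.

    Raises ``ValueError`` when the graph induces a single segment (the
    indices are undefined there); callers that scan many graphs may catch
    it and record a sentinel such as NaN.
    """
    labels = cluster_by_segments(data, graph, assignment=assignment)
    return clustering_quality(data, labels, metric)
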