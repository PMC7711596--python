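"""Embedded graphs and their decomposition into non-branching segments.

An *embedded graph* is an undirected graph whose nodes carry coordinates in
the ambient data space; its edges are straight line pieces between node
positions.  Such graphs are the skeletons produced by trajectory-inference
style approximators (minimum-spanning-tree pipelines, elastic principal
trees) and, in this package, also serve as ground-truth generative skeletons.

The central construction here is the unique partition of a graph's edge set
into maximal *non-branching segments*: paths that start and end at a
branching node (degree > 2) or a leaf (degree 1) and whose interior nodes
all have degree exactly 2.  Degenerate cases are handled explicitly — an
isolated cycle forms a single segment, and an isolated node forms a single
edgeless segment.  Segments are the device that turns graph comparison into
clustering comparison: each data point is later labelled by its nearest
segment (see :mod:`trajgraph.scoring`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np


class GraphValidationError(ValueError):
    """Raised when an embedded graph violates a structural invariant."""


def _canonical_edges(edges: np.ndarray) -> np.ndarray:
    """Sort each edge pair ascending, then sort rows lexicographically."""
    e = np.sort(edges, axis=1)
    order = np.lexsort((e[:, 1], e[:, 0]))
    return e[order]


@dataclass(eq=False)
class EmbeddedGraph:
    """Undirected graph with node coordinates in data space.

    Parameters
    ----------
    node_coords : (n_nodes, m) float array
        Position of each node in the ambient space.
    edges : (n_edges, 2) int array
        Unordered node-index pairs.  Stored canonically: each pair sorted
        ascending, rows sorted lexicographically.

    Invariants (enforced at construction): no self-loops, no duplicate
    edges, indices in range, all coordinates finite.  The arrays are marked
    read-only; derived quantities (degrees, adjacency) are computed on
    demand.
    """

    node_coords: np.ndarray
    edges: np.ndarray

    def __post_init__(self) -> None:
        coords = np.asarray(self.node_coords, dtype=float)
        if coords.ndim != 2:
            raise GraphValidationError(
                f"node_coords must be 2-D (n_nodes, m); got shape {coords.shape}"
            )
        bad = np.argwhere(~np.isfinite(coords))
        if bad.size:
            i, j = bad[0]
            raise GraphValidationError(
                f"non-finite coordinate at node {i}, dimension {j}"
            )
        edges = np.asarray(self.edges, dtype=int)
        if edges.size == 0:
            edges = edges.reshape(0, 2)
        if edges.ndim != 2 or edges.shape[1] != 2:
            raise GraphValidationError(
                f"edges must have shape (n_edges, 2); got {edges.shape}"
            )
        n = coords.shape[0]
        if edges.size:
            if edges.min() < 0 or edges.max() >= n:
                off = edges[(edges < 0) | (edges >= n)][0]
                raise GraphValidationError(
                    f"edge references out-of-range node index {off} "
                    f"(graph has {n} nodes)"
                )
            loops = edges[:, 0] == edges[:, 1]
            if loops.any():
                v = edges[loops][0, 0]
                raise GraphValidationError(f"self-loop at node {v}")
            edges = _canonical_edges(edges)
            dup = (np.diff(edges, axis=0) == 0).all(axis=1)
            if dup.any():
                u, v = edges[1:][dup][0]
                raise GraphValidationError(f"duplicate edge ({u}, {v})")
        coords = np.ascontiguousarray(coords)
        coords.setflags(write=False)
        edges.setflags(write=False)
        self.node_coords = coords
        self.edges = edges

    # -- basic queries -----------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self.node_coords.shape[0]

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]

    @property
    def ndim(self) -> int:
        return self.node_coords.shape[1]

    def degrees(self) -> np.ndarray:
        return np.bincount(self.edges.ravel(), minlength=self.n_nodes)

    def adjacency(self) -> list[list[tuple[int, int]]]:
        """Per-node list of ``(neighbor, edge_index)``, sorted by neighbor."""
        adj: list[list[tuple[int, int]]] = [[] for _ in range(self.n_nodes)]
        for eid, (u, v) in enumerate(self.edges):
            adj[u].append((int(v), eid))
            adj[v].append((int(u), eid))
        for lst in adj:
            lst.sort()
        return adj

    def branch_nodes(self) -> np.ndarray:
        """Indices of branching nodes (degree >= 3)."""
        return np.flatnonzero(self.degrees() >= 3)

    def leaf_nodes(self) -> np.ndarray:
        return np.flatnonzero(self.degrees() == 1)

    def edge_lengths(self) -> np.ndarray:
        if self.n_edges == 0:
            return np.zeros(0)
        d = self.node_coords[self.edges[:, 0]] - self.node_coords[self.edges[:, 1]]
        return np.linalg.norm(d, axis=1)

    def total_edge_length(self) -> float:
        return float(self.edge_lengths().sum())

    def with_coords(self, node_coords: np.ndarray) -> "EmbeddedGraph":
        """Same topology with new node positions."""
        return EmbeddedGraph(np.array(node_coords, dtype=float), self.edges.copy())

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        for i, xy in enumerate(self.node_coords):
            g.add_node(i, coords=tuple(float(c) for c in xy))
        g.add_edges_from(map(tuple, self.edges))
        return g


def validate_graph(
    graph: EmbeddedGraph | None = None,
    *,
    node_coords: np.ndarray | None = None,
    edges: Iterable[Sequence[int]] | None = None,
) -> EmbeddedGraph:
    """Validate a graph (or raw node/edge arrays) and return it.

    Raises :class:`GraphValidationError` naming the offending element for
    self-loops, duplicate edges, out-of-range indices or non-finite
    coordinates.  Duplicate edges are an error, never silently collapsed.
    """
    if graph is not None:
        return EmbeddedGraph(graph.node_coords, graph.edges)
    if node_coords is None:
        raise ValueError("provide either a graph or node_coords (+ edges)")
    edge_arr = np.asarray(list(edges) if edges is not None else [], dtype=int)
    return EmbeddedGraph(np.asarray(node_coords, dtype=float), edge_arr)


@dataclass(frozen=True)
class Segment:
    """A maximal non-branching path, stored as an ordered node sequence.

    ``node_path`` is oriented canonically (smaller-index endpoint first; for
    closed walks the smallest contained node first, then toward its smaller
    neighbor).  A cycle-segment repeats its first node at the end.  An
    isolated node yields a single-node, edgeless path.
    """

    node_path: tuple[int, ...]

    @property
    def is_cycle(self) -> bool:
        return len(self.node_path) > 1 and self.node_path[0] == self.node_path[-1]

    @property
    def nodes(self) -> frozenset[int]:
        return frozenset(self.node_path)

    @property
    def edge_set(self) -> frozenset[tuple[int, int]]:
        p = self.node_path
        return frozenset(
            (min(a, b), max(a, b)) for a, b in zip(p[:-1], p[1:])
        )

    def __len__(self) -> int:
        return len(self.node_path)


@dataclass(frozen=True)
class SegmentDecomposition:
    """Partition of a graph's edges into maximal non-branching segments."""

    segments: tuple[Segment, ...]
    node_to_segments: tuple[tuple[int, ...], ...] = field(repr=False)

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def segment_of_edge(self) -> dict[tuple[int, int], int]:
        """Map canonical edge pair -> index of its (unique) segment."""
        out: dict[tuple[int, int], int] = {}
        for sid, seg in enumerate(self.segments):
            for e in seg.edge_set:
                out[e] = sid
        return out


def _orient_path(path: list[int], anchored: bool = False) -> tuple[int, ...]:
    """Canonical orientation of an open or closed node path.

    Open paths run from their smaller-index endpoint.  Closed walks anchored
    at a terminal node (a cycle hanging off a branching point) keep that
    anchor first and only choose the direction; free cycles are rotated so
    the smallest node comes first.
    """
    if len(path) == 1:
        return (path[0],)
    if path[0] != path[-1]:
        if path[0] > path[-1]:
            path = path[::-1]
        return tuple(path)
    body = path[:-1]
    if not anchored:
        k = body.index(min(body))
        body = body[k:] + body[:k]
    if len(body) > 2 and body[1] > body[-1]:
        body = [body[0]] + body[1:][::-1]
    return tuple(body + [body[0]])


def decompose_into_segments(graph: EmbeddedGraph) -> SegmentDecomposition:
    """Partition a graph's edges into maximal non-branching segments.

    A modified depth-first walk that records visited *edges* (not only
    nodes): starting from every terminal node (leaf or branching node), walk
    along unvisited edges through degree-2 interiors until the next terminal
    is reached; each walk is one segment.  Components without any terminal
    are pure cycles and form one segment each; isolated nodes form edgeless
    segments.  Output ordering and path orientation are canonical, so the
    result is invariant under node relabeling and edge-list permutation
    (up to the relabeling itself).
    """
    deg = graph.degrees()
    adj = graph.adjacency()
    visited = np.zeros(graph.n_edges, dtype=bool)
    paths: list[list[int]] = []

    terminals = np.flatnonzero((deg == 1) | (deg >= 3))
    for v in terminals:
        for nb, eid in adj[v]:
            if visited[eid]:
                continue
            visited[eid] = True
            path = [int(v), nb]
            cur = nb
            prev_eid = eid
            while deg[cur] == 2:
                (n1, e1), (n2, e2) = adj[cur]
                nxt, neid = (n2, e2) if e1 == prev_eid else (n1, e1)
                if visited[neid]:
                    break  # closed back onto an already-walked edge
                visited[neid] = True
                path.append(nxt)
                cur, prev_eid = nxt, neid
            paths.append(path)

    # Components made only of degree-2 nodes: isolated cycles.
    for eid0 in range(graph.n_edges):
        if visited[eid0]:
            continue
        u, v = (int(x) for x in graph.edges[eid0])
        visited[eid0] = True
        path = [u, v]
        cur, prev_eid = v, eid0
        while cur != u:
            (n1, e1), (n2, e2) = adj[cur]
            nxt, neid = (n2, e2) if e1 == prev_eid else (n1, e1)
            visited[neid] = True
            path.append(nxt)
            cur, prev_eid = nxt, neid
        paths.append(path)

    # Isolated nodes are degenerate single-node segments.
    for v in np.flatnonzero(deg == 0):
        paths.append([int(v)])

    segs = [
        Segment(_orient_path(p, anchored=len(p) > 1 and p[0] == p[-1] and deg[p[0]] != 2))
        for p in paths
    ]
    segs.sort(key=lambda s: (min(s.node_path), s.node_path))

    node_to: list[set[int]] = [set() for _ in range(graph.n_nodes)]
    for sid, seg in enumerate(segs):
        for node in seg.nodes:
            node_to[node].add(sid)
    return SegmentDecomposition(
        segments=tuple(segs),
        node_to_segments=tuple(tuple(sorted(s)) for s in node_to),
    )


def count_branch_points(graph: EmbeddedGraph) -> int:
    """Number of branching nodes (degree >= 3)."""
    return int((graph.degrees() >= 3).sum())


def branch_point_displacement(
    graph: EmbeddedGraph, reference: EmbeddedGraph
) -> tuple[int, float]:
    """Match each reference branching point to its nearest one in ``graph``.

    For every branching node of ``reference`` the Euclidean-nearest branching
    node of ``graph`` is found; a single node of ``graph`` may serve as the
    match for several reference points, and surplus branching points of
    ``graph`` are ignored.  Returns ``(matched_count, mean_distance)`` where
    ``matched_count`` is the number of *distinct* nodes of ``graph`` used.
    If ``graph`` has no branching points the mean distance is ``inf``.

    Raises ``ValueError`` if the reference has no branching points.
    """
    ref_bp = reference.branch_nodes()
    if ref_bp.size == 0:
        raise ValueError("reference graph has no branching points")
    g_bp = graph.branch_nodes()
    if g_bp.size == 0:
        return 0, float("inf")
    ref_xy = reference.node_coords[ref_bp]
    g_xy = graph.node_coords[g_bp]
    d = np.linalg.norm(ref_xy[:, None, :] - g_xy[None, :, :], axis=2)
    nearest = d.argmin(axis=1)
    matched = int(np.unique(nearest).size)
    return matched, float(d[np.arange(len(ref_bp)), nearest].mean())
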