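"""Minimum-spanning-tree data approximation.

The simplest skeletonization pipeline used by many trajectory-inference
tools: split the data into K clusters with K-means, connect the cluster
centers by a k-nearest-neighbor graph weighted with Euclidean distances,
and keep its minimum spanning tree.  The number of nodes K is the main
hyperparameter; too few nodes cannot capture the branching structure, too
many make the tree "overbranch" into noise.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
from scipy.spatial.distance import cdist, pdist, squareform
from sklearn.cluster import KMeans

from .graph import EmbeddedGraph
from .model import GraphApproximationModel, GraphApproximationResults


@dataclass(frozen=True)
class MSTParams:
    """Hyperparameters of the K-means/kNN/MST approximator.

    ``n_nodes`` is K, the number of K-means clusters and hence graph nodes.
    ``k_neighbors`` is the kNN-graph degree; ``"all"`` (the default) keeps
    the complete graph, which the MST step then prunes — results do not
    depend on k once it is large enough.
    """

    n_nodes: int
    k_neighbors: int | str = "all"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 2:
            raise ValueError("n_nodes must be >= 2")
        if self.k_neighbors != "all" and int(self.k_neighbors) < 1:
            raise ValueError('k_neighbors must be >= 1 or "all"')


@dataclass
class WeightedGraph:
    """Weighted undirected graph over embedded nodes (pre-MST stage)."""

    node_coords: np.ndarray
    edges: np.ndarray  # (n_edges, 2) int, u < v
    weights: np.ndarray  # Euclidean distances between incident nodes

    @property
    def n_nodes(self) -> int:
        return self.node_coords.shape[0]


def kmeans_centers(data: np.ndarray, n_nodes: int, seed: int = 0) -> np.ndarray:
    """K-means centroids used as graph nodes.

    k-means++ initialization with 10 restarts, best inertia kept;
    deterministic for a given seed.  sklearn re-seats empty clusters at the
    worst-fit points, so exactly ``n_nodes`` centers always come back.
    """
    pts = np.asarray(data, dtype=float)
    if n_nodes > pts.shape[0]:
        raise ValueError(
            f"n_nodes={n_nodes} exceeds the number of data points {pts.shape[0]}"
        )
    km = KMeans(n_clusters=n_nodes, n_init=10, random_state=seed)
    km.fit(pts)
    return km.cluster_centers_


def knn_graph(nodes: np.ndarray, k_neighbors: int | str = "all") -> WeightedGraph:
    """Symmetrized k-nearest-neighbor graph over node coordinates.

    ``"all"`` yields the complete graph.  A finite k >= n_nodes is clamped
    to n_nodes - 1 with a warning.  Edge weights are Euclidean distances.
    """
    xy = np.asarray(nodes, dtype=float)
    n = xy.shape[0]
    if n < 2:
        raise ValueError("need at least 2 nodes")
    dmat = squareform(pdist(xy))
    if k_neighbors == "all":
        iu, ju = np.triu_indices(n, k=1)
        edges = np.column_stack([iu, ju])
        return WeightedGraph(xy, edges, dmat[iu, ju])
    k = int(k_neighbors)
    if k >= n:
        warnings.warn(
            f"k_neighbors={k} >= n_nodes={n}; clamping to {n - 1}", stacklevel=2
        )
        k = n - 1
    pairs: set[tuple[int, int]] = set()
    order = np.argsort(dmat, axis=1, kind="stable")
    for i in range(n):
        for j in order[i, 1 : k + 1]:  # order[i, 0] is i itself
            pairs.add((min(i, int(j)), max(i, int(j))))
    edges = np.array(sorted(pairs), dtype=int)
    return WeightedGraph(xy, edges, dmat[edges[:, 0], edges[:, 1]])


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def minimum_spanning_tree(
    g: WeightedGraph, *, forest: bool = False
) -> EmbeddedGraph:
    """Kruskal MST with a fully deterministic tie-break.

    Edges are taken in ``(weight, smaller endpoint, larger endpoint)``
    order, so equal-weight instances always yield the same tree.  A
    disconnected input raises an error naming the components unless
    ``forest=True``, in which case a minimum spanning forest is returned.
    """
    order = np.lexsort((g.edges[:, 1], g.edges[:, 0], g.weights))
    uf = _UnionFind(g.n_nodes)
    kept = []
    for idx in order:
        u, v = (int(x) for x in g.edges[idx])
        if uf.union(u, v):
            kept.append((u, v))
    if len(kept) < g.n_nodes - 1 and not forest:
        comps: dict[int, list[int]] = {}
        for node in range(g.n_nodes):
            comps.setdefault(uf.find(node), []).append(node)
        raise ValueError(
            f"input graph is disconnected; components: {sorted(comps.values())}"
        )
    return EmbeddedGraph(g.node_coords.copy(), np.array(sorted(kept), dtype=int))


def mst_approximate(data: np.ndarray, params: MSTParams) -> EmbeddedGraph:
    """K-means centers -> kNN graph -> minimum spanning tree."""
    centers = kmeans_centers(data, params.n_nodes, params.seed)
    g = knn_graph(centers, params.k_neighbors)
    return minimum_spanning_tree(g)


class MinimumSpanningTreeModel(GraphApproximationModel):
    """K-means/kNN/MST skeleton model for a point cloud.

    Examples
    --------
    >>> model = MinimumSpanningTreeModel(data, n_nodes=10, seed=0)
    >>> res = model.fit()
    >>> res.n_branch_points
    3
    """

    def __init__(
        self,
        data: np.ndarray,
        n_nodes: int,
        k_neighbors: int | str = "all",
        seed: int = 0,
    ) -> None:
        super().__init__(data)
        self.params = MSTParams(n_nodes=n_nodes, k_neighbors=k_neighbors, seed=seed)

    def fit(self) -> "MSTResults":
        centers = kmeans_centers(self.data, self.params.n_nodes, self.params.seed)
        graph = minimum_spanning_tree(knn_graph(centers, self.params.k_neighbors))
        inertia = float(
            (cdist(self.data, graph.node_coords).min(axis=1) ** 2).sum()
        )
        return MSTResults(self, graph, inertia=inertia)


class MSTResults(GraphApproximationResults):
    """Fitted MST skeleton with its diagnostics."""

    def __init__(
        self, model: MinimumSpanningTreeModel, graph: EmbeddedGraph, inertia: float
    ) -> None:
        super().__init__(model, graph)
        #: sum of squared point-to-nearest-node distances (k-means elbow quantity)
        self.inertia = inertia

    def _extra_summary_rows(self) -> list[tuple[str, str]]:
        return [("Inertia (sum sq. nearest-node dist)", f"{self.inertia:.4g}")]
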