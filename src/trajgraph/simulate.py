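"""Ground-truthed synthetic tree-shaped point clouds.

Datasets emulate the branching clouds that trajectory-inference methods are
benchmarked on: a tree skeleton is embedded in a (typically 20-dimensional)
ambient space by walking from the root and drawing a random unit direction
for every edge, points are sampled uniformly along each edge, and isotropic
Gaussian noise is added.  Every point carries the segment of its generating
edge as a ground-truth label, which closes the loop with the segment-induced
clustering: at zero noise, clustering the cloud by the ground-truth graph
reproduces the generator labels exactly.

Named skeletons
---------------
``binary_tree_7edges``
    Stem plus two levels of bifurcation: 8 nodes, 7 edges, 3 branch points.
``dumbbell``
    Bar joining two 3-spoke hubs (spokes half the bar length): 2 branch
    points; the hubs read as blobs once noise is added.
``binary_tree_15edges``
    One more bifurcation level: 16 nodes, 15 edges, 7 branch points.
``asymmetric_tree``
    A backbone path with side branches of unequal depth: 2 branch points.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterator

import numpy as np

from .graph import EmbeddedGraph, decompose_into_segments

# (edges, per-edge relative length); node 0 is the root of the walk
_SHAPES: dict[str, tuple[list[tuple[int, int]], list[float]]] = {
    "binary_tree_7edges": (
        [(0, 1), (1, 2), (1, 3), (2, 4), (2, 5), (3, 6), (3, 7)],
        [1.0] * 7,
    ),
    "dumbbell": (
        [(0, 1), (0, 2), (0, 3), (0, 4), (1, 5), (1, 6), (1, 7)],
        [1.0, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5],
    ),
    "binary_tree_15edges": (
        [(0, 1), (1, 2), (1, 3), (2, 4), (2, 5), (3, 6), (3, 7),
         (4, 8), (4, 9), (5, 10), (5, 11), (6, 12), (6, 13), (7, 14), (7, 15)],
        [1.0] * 15,
    ),
    "asymmetric_tree": (
        [(0, 1), (1, 2), (2, 3), (3, 4), (1, 5), (5, 6), (3, 7)],
        [1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 0.7],
    ),
}

MIN_BRANCH_ANGLE_DEG = 15.0


@dataclass(frozen=True)
class TreeDatasetSpec:
    """Generative parameters for a tree-shaped point cloud.

    ``skeleton`` is a named shape or an already-embedded tree.  Defaults
    describe the standard study conditions used throughout the package:
    20 ambient dimensions, edges of length 100 sampled with 100 points
    each, Gaussian noise of standard deviation 5 (i.e. 5% of an edge —
    a low-noise regime relative to the skeleton scale).
    """

    skeleton: str | EmbeddedGraph = "binary_tree_7edges"
    ambient_dim: int = 20
    noise_sd: float = 5.0
    points_per_edge: int = 100
    edge_length: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ambient_dim < 2:
            raise ValueError("ambient_dim must be >= 2")
        if self.points_per_edge < 1:
            raise ValueError("points_per_edge must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if isinstance(self.skeleton, str) and self.skeleton not in _SHAPES:
            raise ValueError(
                f"unknown shape {self.skeleton!r}; choose from {sorted(_SHAPES)}"
            )


@dataclass(frozen=True)
class TreeDataset:
    """A generated cloud, its generative skeleton and per-point labels."""

    data: np.ndarray
    ground_truth: EmbeddedGraph
    labels: np.ndarray

    def __iter__(self) -> Iterator:
        return iter((self.data, self.ground_truth, self.labels))


def _random_unit(rng: np.random.Generator, dim: int) -> np.ndarray:
    v = rng.standard_normal(dim)
    n = np.linalg.norm(v)
    while n < 1e-12:
        v = rng.standard_normal(dim)
        n = np.linalg.norm(v)
    return v / n


def _embed_skeleton(
    edges: list[tuple[int, int]],
    rel_lengths: list[float],
    dim: int,
    edge_length: float,
    rng: np.random.Generator,
) -> EmbeddedGraph:
    """Walk the tree from node 0, drawing a random direction per edge.

    Directions leaving a node are resampled until pairwise separated by at
    least ``MIN_BRANCH_ANGLE_DEG`` from every direction already present at
    that node (including the incoming edge), so branches never fold onto
    each other even in low ambient dimension.
    """
    n_nodes = max(max(e) for e in edges) + 1
    adj: list[list[tuple[int, int]]] = [[] for _ in range(n_nodes)]
    for eid, (u, v) in enumerate(edges):
        adj[u].append((v, eid))
        adj[v].append((u, eid))
    coords = np.zeros((n_nodes, dim))
    dirs_at: list[list[np.ndarray]] = [[] for _ in range(n_nodes)]
    cos_max = float(np.cos(np.deg2rad(MIN_BRANCH_ANGLE_DEG)))
    placed = {0}
    stack = [0]
    while stack:
        u = stack.pop()
        for v, eid in adj[u]:
            if v in placed:
                continue
            for _ in range(1000):
                d = _random_unit(rng, dim)
                if all(float(d @ prev) < cos_max for prev in dirs_at[u]):
                    break
            dirs_at[u].append(d)
            coords[v] = coords[u] + edge_length * rel_lengths[eid] * d
            dirs_at[v].append(-d)
            placed.add(v)
            stack.append(v)
    return EmbeddedGraph(coords, np.array(edges, dtype=int))


def generate_tree_dataset(spec: TreeDatasetSpec) -> TreeDataset:
    """Sample one tree-shaped cloud with ground-truth segment labels.

    Points are drawn uniformly along every skeleton edge and perturbed by
    isotropic Gaussian noise; each point is labelled by the segment of the
    ground-truth decomposition that contains its generating edge.  Fully
    reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    if isinstance(spec.skeleton, EmbeddedGraph):
        graph = spec.skeleton
        if graph.ndim != spec.ambient_dim:
            raise ValueError(
                "ambient_dim must match the embedded skeleton's dimension"
            )
    else:
        edges, rel = _SHAPES[spec.skeleton]
        graph = _embed_skeleton(
            edges, rel, spec.ambient_dim, spec.edge_length, rng
        )
    decomp = decompose_into_segments(graph)
    seg_of_edge = decomp.segment_of_edge()

    pts = []
    labels = []
    for u, v in graph.edges:
        t = rng.uniform(size=spec.points_per_edge)
        seg = graph.node_coords[u] + t[:, None] * (
            graph.node_coords[v] - graph.node_coords[u]
        )
        pts.append(seg)
        labels.append(
            np.full(spec.points_per_edge, seg_of_edge[(min(u, v), max(u, v))])
        )
    data = np.vstack(pts)
    if spec.noise_sd > 0:
        data = data + rng.normal(scale=spec.noise_sd, size=data.shape)
    return TreeDataset(data, graph, np.concatenate(labels))


def low_noise_spec(seed: int = 0) -> TreeDatasetSpec:
    """Standard low-noise study conditions: 7-edge binary tree, 20
    dimensions, noise sd 5 on edges of length 100 (5% relative noise)."""
    return TreeDatasetSpec(seed=seed)


def tuning_spec(seed: int = 0) -> TreeDatasetSpec:
    """Study conditions for the hyperparameter-tuning benchmark: same tree
    and noise sd 5, but on longer edges (length 185) so points are spread
    more thinly along each branch and finer skeletons keep paying off
    before overbranching sets in."""
    return TreeDatasetSpec(edge_length=185.0, seed=seed)


def replicate_ensemble(
    spec: TreeDatasetSpec, n_replicates: int, seed: int | None = None
) -> list[TreeDataset]:
    """Independent replicate datasets sharing one generative spec.

    Replicate ``i`` uses seed ``(base + i) mod 2**31`` where ``base`` is
    ``seed`` (or the spec's own seed when omitted), so a single replicate
    reproduces :func:`generate_tree_dataset` exactly and ensembles are
    bitwise-reproducible.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    base = spec.seed if seed is None else seed
    return [
        generate_tree_dataset(replace(spec, seed=(base + i) % 2**31))
        for i in range(n_replicates)
    ]
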