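"""Shared fixtures: small graphs and synthetic clouds, generated in-process."""

from __future__ import annotations

import numpy as np
import pytest

from trajgraph import (
    EmbeddedGraph,
    TreeDatasetSpec,
    generate_tree_dataset,
    validate_graph,
)

BINARY_TREE_EDGES = [(0, 1), (1, 2), (1, 3), (2, 4), (2, 5), (3, 6), (3, 7)]


def random_graph(rng: np.random.Generator, n_nodes: int, p: float = 0.3) -> EmbeddedGraph:
    """Erdos-Renyi style random embedded graph (any topology)."""
    coords = rng.normal(size=(n_nodes, 2))
    iu, ju = np.triu_indices(n_nodes, k=1)
    keep = rng.uniform(size=len(iu)) < p
    edges = np.column_stack([iu[keep], ju[keep]])
    return validate_graph(node_coords=coords, edges=edges)


@pytest.fixture
def path_graph() -> EmbeddedGraph:
    coords = np.column_stack([np.arange(5.0), np.zeros(5)])
    return validate_graph(node_coords=coords, edges=[(i, i + 1) for i in range(4)])


@pytest.fixture
def star_graph() -> EmbeddedGraph:
    coords = np.array([[0.0, 0], [1, 0], [0, 1], [-1, 0]])
    return validate_graph(node_coords=coords, edges=[(0, 1), (0, 2), (0, 3)])


@pytest.fixture
def binary_tree_skeleton() -> EmbeddedGraph:
    """7-edge symmetric binary tree embedded in the plane."""
    coords = np.array(
        [[0.0, 0], [0, 1], [-1, 2], [1, 2], [-1.5, 3], [-0.5, 3], [0.5, 3], [1.5, 3]]
    )
    return validate_graph(node_coords=coords, edges=BINARY_TREE_EDGES)


@pytest.fixture(scope="session")
def dumbbell_dataset():
    """Moderate-noise dumbbell cloud with ground truth (2 branch points)."""
    return generate_tree_dataset(
        TreeDatasetSpec(
            skeleton="dumbbell",
            ambient_dim=2,
            noise_sd=4.0,
            points_per_edge=60,
            edge_length=100.0,
            seed=42,
        )
    )


@pytest.fixture(scope="session")
def binary_tree_dataset():
    """Low-noise 20-D binary-tree cloud (the standard study conditions)."""
    return generate_tree_dataset(TreeDatasetSpec(seed=7))
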