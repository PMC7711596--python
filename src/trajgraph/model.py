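"""Model/Results base classes shared by the graph approximators.

Both approximators follow the same convention: a model object is built from
a data matrix plus hyperparameters, ``fit()`` returns a results object that
carries the fitted embedded graph together with the segment decomposition,
diagnostics, a ``summary()`` table, and scoring/plotting helpers.
"""

from __future__ import annotations

import numpy as np

from .graph import (
    EmbeddedGraph,
    SegmentDecomposition,
    count_branch_points,
    decompose_into_segments,
)


class GraphApproximationModel:
    """Base class: holds the data cloud an approximator is fitted to."""

    def __init__(self, data: np.ndarray) -> None:
        data = np.asarray(data, dtype=float)
        if data.ndim != 2 or data.shape[0] < 1:
            raise ValueError("data must be a non-empty 2-D matrix (points x features)")
        if not np.isfinite(data).all():
            raise ValueError("data contains non-finite values")
        self.data = data

    @classmethod
    def from_dataframe(cls, frame, **kwargs) -> "GraphApproximationModel":
        """Build the model from a pandas DataFrame of numeric columns."""
        return cls(np.asarray(frame, dtype=float), **kwargs)

    def fit(self) -> "GraphApproximationResults":  # pragma: no cover - abstract
        raise NotImplementedError


class GraphApproximationResults:
    """Fitted graph approximation: the embedded graph plus derived views."""

    def __init__(self, model: GraphApproximationModel, graph: EmbeddedGraph) -> None:
        self.model = model
        self.graph = graph
        self._decomposition: SegmentDecomposition | None = None
        self._labels: np.ndarray | None = None

    # -- derived structure -------------------------------------------------

    @property
    def decomposition(self) -> SegmentDecomposition:
        if self._decomposition is None:
            self._decomposition = decompose_into_segments(self.graph)
        return self._decomposition

    @property
    def n_segments(self) -> int:
        return self.decomposition.n_segments

    @property
    def n_branch_points(self) -> int:
        return count_branch_points(self.graph)

    def segment_labels(self) -> np.ndarray:
        """Nearest-segment label of every point of the model's data."""
        from .scoring import cluster_by_segments

        if self._labels is None:
            self._labels = cluster_by_segments(
                self.model.data, self.graph, self.decomposition
            )
        return self._labels

    # -- scoring -----------------------------------------------------------

    def score(self, metric: str = "silhouette") -> float:
        """Unsupervised clustering-quality score of the induced partition."""
        from .scoring import clustering_quality

        return clustering_quality(self.model.data, self.segment_labels(), metric)

    def compare_to(self, other, metric: str = "adjusted_rand") -> float:
        """Agreement with another fitted graph, a graph, or a label vector."""
        from .scoring import cluster_by_segments, compare_clusterings

        if isinstance(other, GraphApproximationResults):
            other_labels = cluster_by_segments(self.model.data, other.graph)
        elif isinstance(other, EmbeddedGraph):
            other_labels = cluster_by_segments(self.model.data, other)
        else:
            other_labels = np.asarray(other)
        return compare_clusterings(self.segment_labels(), other_labels, metric)

    # -- presentation ------------------------------------------------------

    def _extra_summary_rows(self) -> list[tuple[str, str]]:
        return []

    def summary(self) -> str:
        rows = [
            ("Method", type(self.model).__name__),
            ("No. points", str(self.model.data.shape[0])),
            ("Ambient dim.", str(self.model.data.shape[1])),
            ("No. nodes", str(self.graph.n_nodes)),
            ("No. edges", str(self.graph.n_edges)),
            ("Branch points", str(self.n_branch_points)),
            ("Segments", str(self.n_segments)),
            ("Total edge length", f"{self.graph.total_edge_length():.4g}"),
        ]
        rows += self._extra_summary_rows()
        width = max(len(k) for k, _ in rows) + 2
        title = "Graph Approximation Results"
        lines = [title, "=" * (width + 16)]
        lines += [f"{k:<{width}}{v}" for k, v in rows]
        return "\n".join(lines)

    def plot(self, ax=None, show_data: bool = True):
        """2-D view (PCA projection if the ambient space has more dims)."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        data = self.model.data
        coords = self.graph.node_coords
        if data.shape[1] > 2:
            centered = data - data.mean(axis=0)
            _, _, vt = np.linalg.svd(centered, full_matrices=False)
            basis = vt[:2].T
            data2 = centered @ basis
            coords2 = (coords - self.model.data.mean(axis=0)) @ basis
        else:
            data2, coords2 = data, coords
        if show_data:
            labels = self.segment_labels()
            ax.scatter(data2[:, 0], data2[:, 1], c=labels, s=6, cmap="tab20", alpha=0.5)
        for u, v in self.graph.edges:
            ax.plot(coords2[[u, v], 0], coords2[[u, v], 1], "k-", lw=1.5)
        ax.scatter(coords2[:, 0], coords2[:, 1], c="k", s=18, zorder=3)
        ax.set_xlabel("PC1" if data.shape[1] > 2 else "x")
        ax.set_ylabel("PC2" if data.shape[1] > 2 else "y")
        return ax
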