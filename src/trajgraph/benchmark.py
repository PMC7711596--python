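"""Benchmark orchestration: node-number scans and stability reports.

A scan fits an approximator over a grid of node numbers on every replicate
of a synthetic ensemble and records, per replicate and grid value, the
supervised scores against ground truth (adjusted Rand of the induced
clustering, branch-point count, branch-point displacement), the k-means
elbow quantity (inertia of the fitted node set) and the unsupervised
clustering-quality indices.  Mean curves over replicates are what the
method-comparison figures are built from; the stability report condenses
two scans into the width of each method's near-optimal node-number
interval, which is the quantitative form of "one method is flatter in its
main parameter than the other".
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.decomposition import PCA

from .elastic import ElasticParams, FitConfig, grow_tree
from .graph import EmbeddedGraph, branch_point_displacement, count_branch_points
from .mst import MSTParams, mst_approximate
from .scoring import cluster_by_segments, compare_clusterings, clustering_quality
from .simulate import TreeDataset

SCAN_METHODS = ("mst", "elpitree", "mst_then_elpitree")

_UNSUPERVISED = ("silhouette", "calinski_harabasz", "davies_bouldin")


def pca_reduce(data: np.ndarray, n_components: int) -> np.ndarray:
    """Project onto the top principal components, deterministically.

    Standard preprocessing for expression matrices before skeleton fitting
    (50 components is the conventional choice for single-cell data).  The
    sign of each component is fixed by making its largest-magnitude loading
    positive, so repeated runs agree exactly.
    """
    pts = np.asarray(data, dtype=float)
    if n_components > min(pts.shape):
        raise ValueError(
            f"n_components={n_components} exceeds min(n, m)={min(pts.shape)}"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    out = pca.fit_transform(pts)
    comps = pca.components_
    flip = np.sign(comps[np.arange(len(comps)), np.abs(comps).argmax(axis=1)])
    flip[flip == 0] = 1.0
    return out * flip


def sqrt_heuristic(n_points: int) -> int:
    """Rule-of-thumb node number: round(sqrt(n_points))."""
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    return int(round(math.sqrt(n_points)))


@dataclass
class ScanResult:
    """Scores of one method over a node-number grid on an ensemble.

    ``scores[metric]`` is a (n_replicates, n_grid) matrix; NaN marks a fit
    or score that was unavailable (e.g. silhouette of a single-segment
    graph, or grid values below an MST initialization's size).
    """

    method: str
    node_grid: np.ndarray
    scores: dict[str, np.ndarray] = field(repr=False)
    truth_branch_count: np.ndarray | None = None

    def __post_init__(self) -> None:
        g = np.asarray(self.node_grid)
        if len(g) and (np.diff(g) <= 0).any():
            raise ValueError("node_grid must be strictly increasing")

    @property
    def n_replicates(self) -> int:
        return next(iter(self.scores.values())).shape[0]

    def mean(self, metric: str) -> np.ndarray:
        """Column mean (over replicates, ignoring missing) of one metric."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.scores[metric], axis=0)

    def to_frame(self):
        """Mean curves as a tidy DataFrame (one row per grid value)."""
        import pandas as pd

        cols = {"n_nodes": self.node_grid}
        for m in self.scores:
            cols[m] = self.mean(m)
        return pd.DataFrame(cols)


def _score_one(
    data: np.ndarray,
    graph: EmbeddedGraph,
    truth: TreeDataset | None,
) -> dict[str, float]:
    out: dict[str, float] = {}
    out["branch_count"] = float(count_branch_points(graph))
    out["inertia"] = float((cdist(data, graph.node_coords).min(axis=1) ** 2).sum())
    try:
        labels = cluster_by_segments(data, graph)
    except ValueError:
        labels = None
    for m in _UNSUPERVISED:
        try:
            out[m] = clustering_quality(data, labels, m) if labels is not None else np.nan
        except ValueError:
            out[m] = np.nan
    if truth is not None:
        out["adjusted_rand"] = (
            compare_clusterings(labels, truth.labels) if labels is not None else np.nan
        )
        try:
            _, disp = branch_point_displacement(graph, truth.ground_truth)
            out["branch_displacement"] = disp
        except ValueError:
            out["branch_displacement"] = np.nan
    return out


def node_number_scan(
    ensemble: list[TreeDataset],
    method: str,
    grid: list[int] | np.ndarray,
    method_params: dict | None = None,
    truth_available: bool = True,
    seed: int = 0,
) -> ScanResult:
    """Fit one approximator over a node-number grid on every replicate.

    ``method`` is ``"mst"``, ``"elpitree"`` or ``"mst_then_elpitree"``.
    ``method_params`` may carry ``k_neighbors`` (MST), elastic moduli
    (``lambda_``, ``mu``, ``alpha``, ``r0``) and, for the combined method,
    ``mst_nodes`` — the size of the MST used to initialize the elastic
    growth (grid values below it are recorded as missing).  Elastic scans
    grow each replicate's tree once to the largest grid value and snapshot
    the intermediate sizes, so the scan costs one growth per replicate.
    Failed fits are recorded as NaN, never silently dropped.
    """
    if method not in SCAN_METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {SCAN_METHODS}")
    mp = dict(method_params or {})
    grid = np.asarray(sorted(int(g) for g in grid))
    metrics = ["branch_count", "inertia", *_UNSUPERVISED]
    if truth_available:
        metrics += ["adjusted_rand", "branch_displacement"]
    R, G = len(ensemble), len(grid)
    scores = {m: np.full((R, G), np.nan) for m in metrics}
    truth_bp = np.zeros(R)

    elastic = ElasticParams(
        lambda_=mp.get("lambda_", 0.01),
        mu=mp.get("mu", 0.1),
        alpha=mp.get("alpha", 0.01),
        r0=mp.get("r0", math.inf),
    )
    for r, ds in enumerate(ensemble):
        rep_seed = (seed + r) % 2**31
        truth_bp[r] = count_branch_points(ds.ground_truth)
        truth = ds if truth_available else None
        graphs: dict[int, EmbeddedGraph] = {}
        try:
            if method == "mst":
                for k in grid:
                    graphs[int(k)] = mst_approximate(
                        ds.data,
                        MSTParams(int(k), mp.get("k_neighbors", "all"), rep_seed),
                    )
            else:
                if method == "mst_then_elpitree":
                    k0 = int(mp["mst_nodes"])
                    init = mst_approximate(
                        ds.data, MSTParams(k0, mp.get("k_neighbors", "all"), rep_seed)
                    )
                else:
                    init, k0 = None, 2
                snap = tuple(int(k) for k in grid if k >= k0)
                if not snap:
                    continue
                config = FitConfig(n_nodes_target=max(snap))
                _, _, graphs = grow_tree(
                    ds.data, elastic, config, init, snapshot_at=snap
                )
        except (ValueError, np.linalg.LinAlgError) as exc:
            warnings.warn(f"replicate {r}: fit failed ({exc}); recorded as missing")
            continue
        for gi, k in enumerate(grid):
            if int(k) not in graphs:
                continue
            row = _score_one(ds.data, graphs[int(k)], truth)
            for m, val in row.items():
                scores[m][r, gi] = val
    return ScanResult(
        method=method,
        node_grid=grid,
        scores=scores,
        truth_branch_count=truth_bp if truth_available else None,
    )


@dataclass(frozen=True)
class MethodStability:
    """Flatness of one scan's mean score curve around its peak."""

    method: str
    peak_value: float
    peak_nodes: int
    near_optimal_nodes: tuple[int, ...]
    interval_width: int
    mean_spurious_branches: float


@dataclass(frozen=True)
class StabilityReport:
    """Side-by-side flatness comparison of two scans on one ensemble."""

    a: MethodStability
    b: MethodStability
    level: float

    @property
    def wider_method(self) -> str:
        """Method whose near-optimal node-number interval is wider."""
        if self.a.interval_width == self.b.interval_width:
            return "tie"
        return (
            self.a.method
            if self.a.interval_width > self.b.interval_width
            else self.b.method
        )


def _stability_of(scan: ScanResult, level: float, metric: str) -> MethodStability:
    mean = scan.mean(metric)
    peak_i = int(np.nanargmax(mean))
    peak = float(mean[peak_i])
    mask = mean >= level * peak
    nodes = tuple(int(k) for k in scan.node_grid[mask])
    spurious = np.nan
    if scan.truth_branch_count is not None:
        excess = scan.scores["branch_count"] - scan.truth_branch_count[:, None]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            spurious = float(np.nanmean(excess))
    return MethodStability(
        method=scan.method,
        peak_value=peak,
        peak_nodes=int(scan.node_grid[peak_i]),
        near_optimal_nodes=nodes,
        interval_width=(max(nodes) - min(nodes)) if nodes else 0,
        mean_spurious_branches=spurious,
    )


def stability_report(
    scan_a: ScanResult,
    scan_b: ScanResult,
    level: float = 0.95,
    metric: str = "adjusted_rand",
) -> StabilityReport:
    """Compare the parameter-stability of two scans on the same grid.

    For each scan, the near-optimal interval is the span of grid values
    whose mean score reaches ``level`` (default 95%) of that scan's peak;
    a wider interval means the method tolerates a rougher guess of its
    node-number parameter.  Mean spurious branch count (branch points in
    excess of ground truth, averaged over the whole scan) is reported
    alongside.
    """
    if not np.array_equal(scan_a.node_grid, scan_b.node_grid):
        raise ValueError("scans were run on different node grids")
    return StabilityReport(
        a=_stability_of(scan_a, level, metric),
        b=_stability_of(scan_b, level, metric),
        level=level,
    )
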