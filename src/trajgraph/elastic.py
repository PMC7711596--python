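"""Elastic principal trees.

A principal tree is an embedded graph whose node positions minimize an
elastic energy: the mean squared (optionally trimmed) distance from the
data to their nearest nodes, plus an edge-stretching penalty proportional
to squared edge lengths, plus a star-bending penalty that pulls every node
of degree >= 2 toward the mean of its neighbors.  Edges touching nodes of
degree above two pay a topological-complexity surcharge.

For a fixed topology the energy is minimized by a splitting-type algorithm:
alternate (i) assigning each point to its nearest node and (ii) solving the
resulting quadratic problem for all node positions at once (a linear system,
since the functional is quadratic given the assignment).  Both half-steps
decrease the energy, so convergence is monotone.

The topology itself is grown by a two-rule graph grammar — "add a node to a
node" and "bisect an edge".  At every growth step all candidate topologies
are fitted to the data and the one with minimal energy is kept, a greedy
descent in the discrete space of trees.  Growth can start from the default
two-node seed along the first principal component or from any tree (for
example a minimum spanning tree), which is how MST-initialized runs are
expressed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .graph import EmbeddedGraph
from .model import GraphApproximationModel, GraphApproximationResults


@dataclass(frozen=True)
class ElasticParams:
    """Elastic moduli of the principal-tree energy.

    lambda_ : edge-stretching modulus (regularizes total edge length).
    mu : star-bending modulus (pulls star centers toward harmonicity).
    alpha : topological-complexity penalty added to lambda for every unit
        of endpoint degree above two.
    r0 : trimming radius; points farther than ``r0`` from every node are
        capped at ``r0**2`` in the data term and exert no pull.  Default
        values follow common practice for principal trees.
    """

    lambda_: float = 0.01
    mu: float = 0.1
    alpha: float = 0.01
    r0: float = math.inf

    def __post_init__(self) -> None:
        if self.lambda_ < 0 or self.mu < 0 or self.alpha < 0:
            raise ValueError("lambda_, mu and alpha must be non-negative")
        if not self.r0 > 0:
            raise ValueError("r0 must be positive (possibly infinite)")


@dataclass(frozen=True)
class EnergyBreakdown:
    """Elastic energy split into its three terms (total = msd + ue + ur)."""

    msd: float
    ue: float
    ur: float

    @property
    def total(self) -> float:
        return self.msd + self.ue + self.ur


@dataclass(frozen=True)
class FitConfig:
    """Convergence control for position fitting and topology growth."""

    n_nodes_target: int = 2
    max_iterations: int = 100
    relative_tolerance: float = 1e-5

    def __post_init__(self) -> None:
        if self.n_nodes_target < 2:
            raise ValueError("n_nodes_target must be >= 2")
        if not self.relative_tolerance > 0:
            raise ValueError("relative_tolerance must be positive")


def penalized_lambda(
    edge: tuple[int, int], graph: EmbeddedGraph, params: ElasticParams
) -> float:
    """Stretching modulus of one edge including the complexity surcharge.

    lambda + alpha * (max(2, deg(u), deg(v)) - 2): edges not touching any
    branching node pay plain lambda; each extra unit of endpoint degree
    above two adds alpha.
    """
    deg = graph.degrees()
    u, v = edge
    return params.lambda_ + params.alpha * (max(2, int(deg[u]), int(deg[v])) - 2)


def _penalized_lambdas(edges: np.ndarray, deg: np.ndarray, params: ElasticParams):
    m = np.maximum(2, np.maximum(deg[edges[:, 0]], deg[edges[:, 1]]))
    return params.lambda_ + params.alpha * (m - 2)


def energy(
    data: np.ndarray, graph: EmbeddedGraph, params: ElasticParams
) -> EnergyBreakdown:
    """Elastic energy of a graph embedding for a data cloud."""
    pts = np.asarray(data, dtype=float)
    if graph.n_nodes == 0:
        raise ValueError("empty graph")
    d2 = cdist(pts, graph.node_coords, "sqeuclidean").min(axis=1)
    if math.isfinite(params.r0):
        d2 = np.minimum(d2, params.r0**2)
    msd = float(d2.mean())

    deg = graph.degrees()
    ue = 0.0
    if graph.n_edges:
        lam = _penalized_lambdas(graph.edges, deg, params)
        ue = float((lam * graph.edge_lengths() ** 2).sum())

    ur = 0.0
    if params.mu > 0:
        adj = graph.adjacency()
        for c in np.flatnonzero(deg >= 2):
            nbrs = [n for n, _ in adj[c]]
            diff = graph.node_coords[c] - graph.node_coords[nbrs].mean(axis=0)
            ur += float(diff @ diff)
        ur *= params.mu
    return EnergyBreakdown(msd=msd, ue=ue, ur=ur)


class _FixedTopologyFitter:
    """Alternating minimization for one topology; everything that depends
    only on the edge structure (penalized stretching Laplacian, star
    operator) is precomputed once."""

    def __init__(
        self, pts: np.ndarray, n_nodes: int, edges: np.ndarray, params: ElasticParams
    ):
        self.pts = pts
        self.edges = edges
        self.params = params
        self.n_pts, self.dim = pts.shape
        n = self.n = n_nodes
        self.r0sq = params.r0**2 if math.isfinite(params.r0) else None

        A = np.zeros((n, n))
        self.star_op = np.zeros((0, n))
        if edges.size:
            deg = np.bincount(edges.ravel(), minlength=n)
            self.lam = _penalized_lambdas(edges, deg, params)
            u, v = edges[:, 0], edges[:, 1]
            np.add.at(A, (u, u), self.lam)
            np.add.at(A, (v, v), self.lam)
            np.add.at(A, (u, v), -self.lam)
            np.add.at(A, (v, u), -self.lam)
            centers = np.flatnonzero(deg >= 2)
            if params.mu > 0 and centers.size:
                S = np.zeros((centers.size, n))
                S[np.arange(centers.size), centers] = 1.0
                inv_k = 1.0 / deg[centers]
                row_of = {int(c): i for i, c in enumerate(centers)}
                for a, b in edges:
                    a, b = int(a), int(b)
                    if a in row_of:
                        S[row_of[a], b] -= inv_k[row_of[a]]
                    if b in row_of:
                        S[row_of[b], a] -= inv_k[row_of[b]]
                self.star_op = S
                A += params.mu * (S.T @ S)
        else:
            self.lam = np.zeros(0)
        self.A_elastic = A

    def energy_terms(self, coords: np.ndarray, d2: np.ndarray) -> EnergyBreakdown:
        dmin = d2.min(axis=1)
        if self.r0sq is not None:
            dmin = np.minimum(dmin, self.r0sq)
        msd = float(dmin.mean())
        ue = 0.0
        if self.edges.size:
            diff = coords[self.edges[:, 0]] - coords[self.edges[:, 1]]
            ue = float((self.lam * (diff * diff).sum(axis=1)).sum())
        ur = 0.0
        if self.star_op.shape[0]:
            sv = self.star_op @ coords
            ur = float(self.params.mu * (sv * sv).sum())
        return EnergyBreakdown(msd=msd, ue=ue, ur=ur)

    def step(self, d2: np.ndarray) -> np.ndarray:
        """One exact position solve given the assignment implied by d2."""
        assign = d2.argmin(axis=1)
        if self.r0sq is not None:
            active = d2[np.arange(self.n_pts), assign] <= self.r0sq
            a_idx, a_pts = assign[active], self.pts[active]
        else:
            a_idx, a_pts = assign, self.pts
        counts = np.bincount(a_idx, minlength=self.n)
        A = self.A_elastic.copy()
        A[np.diag_indices(self.n)] += counts / self.n_pts
        B = np.empty((self.n, self.dim))
        for j in range(self.dim):
            B[:, j] = np.bincount(a_idx, weights=a_pts[:, j], minlength=self.n)
        B /= self.n_pts
        try:
            return np.linalg.solve(A, B)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "singular position-update system: a node has no assigned "
                "points and no elastic coupling (check lambda > 0 and "
                "connectivity)"
            ) from exc

    def run(self, coords: np.ndarray, config: FitConfig):
        history: list[EnergyBreakdown] = []
        d2 = cdist(self.pts, coords, "sqeuclidean")
        history.append(self.energy_terms(coords, d2))
        for _ in range(config.max_iterations):
            coords = self.step(d2)
            d2 = cdist(self.pts, coords, "sqeuclidean")
            cur = self.energy_terms(coords, d2)
            history.append(cur)
            prev = history[-2]
            denom = max(abs(prev.total), 1e-300)
            if (prev.total - cur.total) / denom < config.relative_tolerance:
                break
        return coords, history


def fit_node_positions(
    data: np.ndarray,
    graph: EmbeddedGraph,
    params: ElasticParams,
    config: FitConfig | None = None,
    *,
    return_history: bool = False,
):
    """Fit node positions of a fixed topology by alternating minimization.

    Alternates nearest-node assignment with an exact solve of the quadratic
    position problem until the relative total-energy decrease drops below
    the tolerance or ``max_iterations`` is reached.  The recorded energy
    sequence is monotone non-increasing (both half-steps lower the energy).

    Returns the refitted graph, or ``(graph, history)`` with the per-
    iteration :class:`EnergyBreakdown` when ``return_history`` is set.
    """
    if config is None:
        config = FitConfig(n_nodes_target=max(2, graph.n_nodes))
    pts = np.asarray(data, dtype=float)
    if pts.shape[1] != graph.ndim:
        raise ValueError("dimension mismatch between data and graph")
    fitter = _FixedTopologyFitter(pts, graph.n_nodes, graph.edges, params)
    coords, history = fitter.run(np.array(graph.node_coords, dtype=float), config)
    fitted = graph.with_coords(coords)
    if return_history:
        return fitted, history
    return fitted


# -- topology grammar -------------------------------------------------------


def _add_node_candidate(graph: EmbeddedGraph, node: int) -> EmbeddedGraph:
    """Attach a new leaf to ``node``, placed at the mirror of the neighbor
    mean through the node (a small deterministic offset when degenerate)."""
    coords = graph.node_coords
    adj = graph.adjacency()
    nbrs = [n for n, _ in adj[node]]
    scale = float(graph.edge_lengths().mean()) if graph.n_edges else 1.0
    if nbrs:
        disp = coords[node] - coords[nbrs].mean(axis=0)
    else:
        disp = np.zeros(graph.ndim)
    if np.linalg.norm(disp) < 1e-9 * max(scale, 1e-9):
        disp = np.zeros(graph.ndim)
        disp[0] = 0.01 * scale
    new_xy = coords[node] + disp
    new_coords = np.vstack([coords, new_xy])
    new_edges = np.vstack([graph.edges, [[node, graph.n_nodes]]])
    return EmbeddedGraph(new_coords, new_edges)


def _bisect_edge_candidate(graph: EmbeddedGraph, edge_index: int) -> EmbeddedGraph:
    u, v = (int(x) for x in graph.edges[edge_index])
    mid = 0.5 * (graph.node_coords[u] + graph.node_coords[v])
    new_coords = np.vstack([graph.node_coords, mid])
    w = graph.n_nodes
    keep = np.delete(graph.edges, edge_index, axis=0)
    new_edges = np.vstack([keep, [[u, w]], [[v, w]]])
    return EmbeddedGraph(new_coords, new_edges)


def grammar_candidates(graph: EmbeddedGraph) -> list[EmbeddedGraph]:
    """All one-step grammar successors of a tree.

    One candidate per node ("add a node to a node": new leaf attached to
    it) and one per edge ("bisect an edge": midpoint node splitting it).
    Every candidate is again a tree.  Order is deterministic: node
    candidates by node index, then edge candidates by edge index.
    """
    cands = [_add_node_candidate(graph, v) for v in range(graph.n_nodes)]
    cands += [_bisect_edge_candidate(graph, e) for e in range(graph.n_edges)]
    return cands


def default_init(data: np.ndarray) -> EmbeddedGraph:
    """Two-node seed along the first principal component, at mean +/- one
    standard deviation of the projections.  Sign fixed by making the
    largest-magnitude loading positive, so the seed is deterministic."""
    pts = np.asarray(data, dtype=float)
    center = pts.mean(axis=0)
    centered = pts - center
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    pc1 = vt[0]
    if pc1[np.abs(pc1).argmax()] < 0:
        pc1 = -pc1
    sd = float((centered @ pc1).std())
    sd = sd if sd > 0 else 1.0
    coords = np.vstack([center - sd * pc1, center + sd * pc1])
    return EmbeddedGraph(coords, np.array([[0, 1]]))


@dataclass(frozen=True)
class GrowthStep:
    """One accepted grammar application during tree growth."""

    n_nodes: int
    operation: str  # "init", "add_node", "bisect_edge"
    energy: EnergyBreakdown


def grow_tree(
    data: np.ndarray,
    params: ElasticParams,
    config: FitConfig,
    init: EmbeddedGraph | None = None,
    *,
    snapshot_at: tuple[int, ...] | None = None,
):
    """Grow an elastic principal tree to ``config.n_nodes_target`` nodes.

    Greedy grammar descent: starting from ``init`` (or the principal-
    component seed), repeatedly fit every grammar candidate with
    :func:`fit_node_positions` and keep the minimal-energy topology until
    the node budget is reached.  ``snapshot_at`` records the fitted graph
    at the listed node counts (useful for node-number scans, since a single
    growth passes through every intermediate size).

    Returns ``(graph, steps, snapshots)``.
    """
    pts = np.asarray(data, dtype=float)
    graph = default_init(pts) if init is None else init
    if graph.n_nodes > config.n_nodes_target:
        raise ValueError(
            f"init has {graph.n_nodes} nodes, above the target "
            f"{config.n_nodes_target}"
        )
    graph = fit_node_positions(pts, graph, params, config)
    steps = [GrowthStep(graph.n_nodes, "init", energy(pts, graph, params))]
    want = set(snapshot_at or ())
    snapshots: dict[int, EmbeddedGraph] = {}
    if graph.n_nodes in want:
        snapshots[graph.n_nodes] = graph

    while graph.n_nodes < config.n_nodes_target:
        n_node_cands = graph.n_nodes
        cands = grammar_candidates(graph)
        fitted = [fit_node_positions(pts, c, params, config) for c in cands]
        energies = [energy(pts, f, params) for f in fitted]
        best = int(np.argmin([e.total for e in energies]))
        graph = fitted[best]
        op = "add_node" if best < n_node_cands else "bisect_edge"
        steps.append(GrowthStep(graph.n_nodes, op, energies[best]))
        if graph.n_nodes in want:
            snapshots[graph.n_nodes] = graph
    return graph, steps, snapshots


@dataclass(frozen=True)
class GraphProjection:
    """Closest point of the piecewise-linear tree to a query point.

    ``kind`` is "node" when the projection lands on a node (offset 0 or 1
    clamps included), otherwise "edge" with ``offset`` in (0, 1) measured
    from the smaller-index endpoint of the edge.
    """

    kind: str
    index: int
    offset: float
    distance: float
    coords: np.ndarray


def project_point(graph: EmbeddedGraph, x: np.ndarray) -> GraphProjection:
    """Orthogonal projection of ``x`` onto the graph's nodes and edges.

    Global minimum over all edges (clamped to endpoints); ties broken by
    the smallest edge index.  Edge-free graphs project onto nodes.
    """
    x = np.asarray(x, dtype=float)
    if graph.n_edges == 0:
        d = np.linalg.norm(graph.node_coords - x, axis=1)
        i = int(d.argmin())
        return GraphProjection("node", i, 0.0, float(d[i]), graph.node_coords[i])
    a = graph.node_coords[graph.edges[:, 0]]
    b = graph.node_coords[graph.edges[:, 1]]
    ab = b - a
    denom = (ab * ab).sum(axis=1)
    safe = np.where(denom == 0, 1.0, denom)
    t = np.clip(((x - a) * ab).sum(axis=1) / safe, 0.0, 1.0)
    proj = a + t[:, None] * ab
    dist = np.linalg.norm(proj - x, axis=1)
    e = int(dist.argmin())
    te = float(t[e])
    if te <= 0.0 or te >= 1.0:
        node = int(graph.edges[e, 0] if te <= 0.0 else graph.edges[e, 1])
        return GraphProjection(
            "node", node, float(round(te)), float(dist[e]), graph.node_coords[node]
        )
    return GraphProjection("edge", e, te, float(dist[e]), proj[e])


# -- model interface --------------------------------------------------------


class ElasticPrincipalTree(GraphApproximationModel):
    """Elastic principal tree model for a point cloud.

    Parameters mirror :class:`ElasticParams` plus the node budget and an
    optional initial tree (e.g. an MST skeleton) whose topology and
    positions seed the growth.

    Examples
    --------
    >>> model = ElasticPrincipalTree(data, n_nodes=20)
    >>> res = model.fit()
    >>> print(res.summary())
    """

    def __init__(
        self,
        data: np.ndarray,
        n_nodes: int,
        lambda_: float = 0.01,
        mu: float = 0.1,
        alpha: float = 0.01,
        r0: float = math.inf,
        init: EmbeddedGraph | None = None,
        max_iterations: int = 100,
        tol: float = 1e-5,
    ) -> None:
        super().__init__(data)
        self.params = ElasticParams(lambda_=lambda_, mu=mu, alpha=alpha, r0=r0)
        self.config = FitConfig(
            n_nodes_target=n_nodes,
            max_iterations=max_iterations,
            relative_tolerance=tol,
        )
        self.init = init

    def fit(self, snapshot_at: tuple[int, ...] | None = None) -> "ElasticTreeResults":
        graph, steps, snapshots = grow_tree(
            self.data, self.params, self.config, self.init, snapshot_at=snapshot_at
        )
        return ElasticTreeResults(self, graph, steps, snapshots)


class ElasticTreeResults(GraphApproximationResults):
    """Fitted elastic principal tree with its energy diagnostics."""

    def __init__(self, model, graph, steps, snapshots) -> None:
        super().__init__(model, graph)
        #: accepted grammar applications, in order
        self.growth_path = steps
        #: graphs recorded at requested node counts during growth
        self.snapshots_ = snapshots
        #: final energy breakdown
        self.energy = steps[-1].energy

    def project(self, x: np.ndarray) -> GraphProjection:
        """Project an arbitrary point onto the fitted tree."""
        return project_point(self.graph, x)

    def _extra_summary_rows(self) -> list[tuple[str, str]]:
        e = self.energy
        return [
            ("Energy (total)", f"{e.total:.6g}"),
            ("  data term (MSD)", f"{e.msd:.6g}"),
            ("  stretching (UE)", f"{e.ue:.6g}"),
            ("  bending (UR)", f"{e.ur:.6g}"),
        ]
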