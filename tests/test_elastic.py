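"""Elastic principal tree: energy terms, position optimizer, grammar, projection."""

from __future__ import annotations

import math

import numpy as np
import pytest

from trajgraph import (
    ElasticParams,
    ElasticPrincipalTree,
    FitConfig,
    count_branch_points,
    energy,
    fit_node_positions,
    grammar_candidates,
    grow_tree,
    mst_approximate,
    MSTParams,
    penalized_lambda,
    project_point,
    validate_graph,
)


def total_energy_fn(data, graph, params):
    """Energy as a plain function of flattened coordinates (for numeric grads)."""

    def f(flat):
        g = graph.with_coords(flat.reshape(graph.node_coords.shape))
        return energy(data, g, params).total

    return f


class TestPenalizedLambda:
    def test_plain_lambda_below_degree_three(self, path_graph):
        p = ElasticParams(lambda_=0.7, alpha=0.2)
        assert penalized_lambda((0, 1), path_graph, p) == pytest.approx(0.7)
        assert penalized_lambda((1, 2), path_graph, p) == pytest.approx(0.7)

    def test_surcharge_at_star_center(self, star_graph):
        p = ElasticParams(lambda_=0.01, alpha=0.01)
        assert penalized_lambda((0, 1), star_graph, p) == pytest.approx(0.02)

    def test_degree_four_endpoint(self):
        g = validate_graph(
            node_coords=np.random.default_rng(0).normal(size=(5, 2)),
            edges=[(0, 1), (0, 2), (0, 3), (0, 4)],
        )
        p = ElasticParams(lambda_=0.01, alpha=0.01)
        assert penalized_lambda((0, 1), g, p) == pytest.approx(0.03)


class TestEnergy:
    def test_data_on_nodes_gives_zero_msd(self, path_graph):
        e = energy(path_graph.node_coords, path_graph, ElasticParams())
        assert e.msd == 0.0
        assert e.total == pytest.approx(e.ue + e.ur)

    def test_harmonic_star_has_zero_bending(self):
        # center exactly at the mean of its three leaves
        leaves = np.array([[1.0, 0], [-0.5, 0.8], [-0.5, -0.8]])
        coords = np.vstack([leaves.mean(axis=0), leaves])
        g = validate_graph(node_coords=coords, edges=[(0, 1), (0, 2), (0, 3)])
        e = energy(np.zeros((1, 2)), g, ElasticParams(mu=5.0))
        assert e.ur == pytest.approx(0.0)

    def test_two_node_edge_and_trimmed_points(self):
        d = 3.0
        g = validate_graph(
            node_coords=np.array([[0.0, 0], [d, 0]]), edges=[(0, 1)]
        )
        params = ElasticParams(lambda_=1.0, alpha=0.5, mu=0.0, r0=1.0)
        data = np.array([[100.0, 100], [-50, 20]])  # far outside trimming radius
        e = energy(data, g, params)
        assert e.ue == pytest.approx(d**2)
        assert e.msd == pytest.approx(params.r0**2)

    def test_trimming_limits(self, dumbbell_dataset):
        data, g = dumbbell_dataset.data, dumbbell_dataset.ground_truth
        from scipy.spatial.distance import cdist

        plain = (cdist(data, g.node_coords).min(axis=1) ** 2).mean()
        e_inf = energy(data, g, ElasticParams(r0=math.inf))
        assert e_inf.msd == pytest.approx(plain)
        tiny = 1e-6
        e_zero = energy(data, g, ElasticParams(r0=tiny))
        assert e_zero.msd == pytest.approx(tiny**2)


class TestFitNodePositions:
    def test_single_free_node_moves_to_data_mean(self):
        # with mu=lambda=0 a 2-node graph decouples into per-cluster means
        rng = np.random.default_rng(0)
        data = np.vstack([rng.normal(0, 0.3, (40, 2)), rng.normal(5, 0.3, (40, 2))])
        g = validate_graph(
            node_coords=np.array([[0.5, 0.5], [4.5, 4.5]]), edges=[(0, 1)]
        )
        fitted = fit_node_positions(data, g, ElasticParams(lambda_=0, mu=0, alpha=0))
        assign = np.linalg.norm(
            data[:, None] - fitted.node_coords[None], axis=2
        ).argmin(axis=1)
        for j in (0, 1):
            assert fitted.node_coords[j] == pytest.approx(
                data[assign == j].mean(axis=0)
            )

    def test_symmetric_data_gives_mirror_positions(self):
        rng = np.random.default_rng(1)
        half = rng.normal(loc=[2, 0], scale=0.5, size=(200, 2))
        data = np.vstack([half, -half])
        g = validate_graph(node_coords=np.array([[-1.0, 0], [1, 0]]), edges=[(0, 1)])
        fitted = fit_node_positions(data, g, ElasticParams())
        assert fitted.node_coords[0] == pytest.approx(-fitted.node_coords[1], abs=1e-8)

    @pytest.mark.parametrize("trial", range(20))
    def test_energy_monotone_on_random_fixtures(self, trial):
        rng = np.random.default_rng(200 + trial)
        data = rng.normal(size=(60, 3))
        n = int(rng.integers(3, 9))
        edges = [(i, i + 1) for i in range(n - 1)]
        g = validate_graph(node_coords=rng.normal(size=(n, 3)), edges=edges)
        params = ElasticParams(r0=(math.inf if trial % 2 else 2.0))
        _, hist = fit_node_positions(data, g, params, return_history=True)
        totals = [h.total for h in hist]
        assert all(a >= b - 1e-9 for a, b in zip(totals, totals[1:]))

    def test_stationary_point_by_finite_differences(self, star_graph):
        rng = np.random.default_rng(4)
        data = rng.normal(scale=1.5, size=(150, 2))
        params = ElasticParams(lambda_=0.05, mu=0.2, alpha=0.02)
        fitted = fit_node_positions(
            data, star_graph, params,
            FitConfig(n_nodes_target=4, relative_tolerance=1e-12,
                      max_iterations=500),
        )
        f = total_energy_fn(data, fitted, params)
        x0 = fitted.node_coords.ravel().copy()
        h = 1e-6
        grad = np.zeros_like(x0)
        for i in range(len(x0)):
            xp, xm = x0.copy(), x0.copy()
            xp[i] += h
            xm[i] -= h
            grad[i] = (f(xp) - f(xm)) / (2 * h)
        assert np.abs(grad).max() < 1e-4

    def test_huge_mu_forces_harmonic_star(self, star_graph):
        rng = np.random.default_rng(5)
        data = rng.normal(size=(100, 2))
        fitted = fit_node_positions(
            data, star_graph, ElasticParams(mu=1e6),
            FitConfig(n_nodes_target=4, max_iterations=300),
        )
        center = fitted.node_coords[0]
        leaves_mean = fitted.node_coords[1:].mean(axis=0)
        assert center == pytest.approx(leaves_mean, abs=1e-3)


class TestGrammar:
    @pytest.mark.parametrize(
        "edges,n_expected",
        [
            ([(0, 1), (1, 2)], 5),       # 3-node path: 3 add + 2 bisect
            ([(0, 1)], 3),               # single edge: 2 add + 1 bisect
            ([(0, 1), (0, 2), (0, 3)], 7),  # star: 4 add + 3 bisect
        ],
    )
    def test_candidate_counts(self, edges, n_expected):
        n = max(max(e) for e in edges) + 1
        g = validate_graph(
            node_coords=np.random.default_rng(0).normal(size=(n, 2)), edges=edges
        )
        cands = grammar_candidates(g)
        assert len(cands) == n_expected
        import networkx as nx

        for c in cands:
            assert c.n_nodes == g.n_nodes + 1
            assert nx.is_tree(c.to_networkx())


class TestGrowTree:
    def test_two_node_target_is_single_segment(self, dumbbell_dataset):
        g, steps, _ = grow_tree(
            dumbbell_dataset.data, ElasticParams(), FitConfig(n_nodes_target=2)
        )
        assert g.n_nodes == 2 and count_branch_points(g) == 0

    def test_accepted_energy_decreases_along_growth(self, binary_tree_dataset):
        _, steps, _ = grow_tree(
            binary_tree_dataset.data, ElasticParams(), FitConfig(n_nodes_target=12)
        )
        totals = [s.energy.total for s in steps]
        assert all(a >= b for a, b in zip(totals, totals[1:]))

    def test_branch_count_stable_over_node_budget(self, binary_tree_dataset):
        """Correct 3-branch topology persists across a wide node range."""
        res = ElasticPrincipalTree(binary_tree_dataset.data, n_nodes=28).fit(
            snapshot_at=(12, 20, 28)
        )
        for k, g in res.snapshots_.items():
            assert count_branch_points(g) == 3, f"{k} nodes"

    def test_mst_init_accepted_and_snapshots_recorded(self, binary_tree_dataset):
        mst = mst_approximate(binary_tree_dataset.data, MSTParams(8, "all", 0))
        g, steps, snaps = grow_tree(
            binary_tree_dataset.data,
            ElasticParams(),
            FitConfig(n_nodes_target=12),
            init=mst,
            snapshot_at=(8, 10, 12),
        )
        assert g.n_nodes == 12
        assert sorted(snaps) == [8, 10, 12]
        assert steps[0].operation == "init" and steps[0].n_nodes == 8

    def test_init_above_target_rejected(self, binary_tree_dataset):
        mst = mst_approximate(binary_tree_dataset.data, MSTParams(10, "all", 0))
        with pytest.raises(ValueError, match="above the target"):
            grow_tree(
                binary_tree_dataset.data, ElasticParams(),
                FitConfig(n_nodes_target=5), init=mst,
            )


class TestProjection:
    @pytest.fixture
    def vee(self):
        return validate_graph(
            node_coords=np.array([[0.0, 0], [1, 0], [1, 1]]),
            edges=[(0, 1), (1, 2)],
        )

    def test_node_hit(self, vee):
        p = project_point(vee, np.array([1.0, 0.0]))
        assert p.kind == "node" and p.index == 1 and p.distance == 0.0

    def test_midpoint_offset(self, vee):
        p = project_point(vee, np.array([0.5, -2.0]))
        assert p.kind == "edge" and p.index == 0
        assert p.offset == pytest.approx(0.5)
        assert p.distance == pytest.approx(2.0)

    def test_matches_dense_sampling_oracle(self, vee):
        rng = np.random.default_rng(7)
        ts = np.linspace(0, 1, 10_000)
        polyline = np.vstack(
            [
                vee.node_coords[u] + ts[:, None] * (vee.node_coords[v] - vee.node_coords[u])
                for u, v in vee.edges
            ]
        )
        for x in rng.normal(scale=2, size=(50, 2)):
            p = project_point(vee, x)
            dense = np.linalg.norm(polyline - x, axis=1).min()
            assert p.distance == pytest.approx(dense, abs=1e-3)

    def test_results_object_projection(self, binary_tree_dataset):
        res = ElasticPrincipalTree(binary_tree_dataset.data, n_nodes=10).fit()
        p = res.project(binary_tree_dataset.data[0])
        assert p.kind in ("node", "edge")
        assert p.distance >= 0
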