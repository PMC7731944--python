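"""Dual projected-gradient solver: objectives, step size, convergence,
analytic limits, and the independent dense-ADMM primal oracle."""

import numpy as np
import pytest
from oracles import admm_primal_minimizer, dense_blocks

from cococlust import (SolverConfig, WeightConfig, build_weights, dual_objective,
                       find_gamma_max, primal_objective, project_to_ball,
                       solution_path, solve, vectorize)
from cococlust.dual_solver import auto_step_size, operators_from_graph
from cococlust.mode_graphs import ModeGraph


def random_sparse_graph(shape, rng, p=0.7):
    """Random connected-ish graph with random positive weights per mode."""
    edges, weights = [], []
    for nd in shape:
        E = [(i, i + 1) for i in range(nd - 1)]  # chain guarantees connectivity
        for i in range(nd):
            for j in range(i + 2, nd):
                if rng.random() < p:
                    E.append((i, j))
        edges.append(np.array(E))
        weights.append(rng.uniform(0.2, 1.0, size=len(E)))
    return ModeGraph(tuple(shape), edges, weights)


class TestProjectToBall:
    def test_inside_unchanged(self):
        z = np.array([0.3, 0.4])
        assert np.array_equal(project_to_ball(z, 1.0), z)

    def test_radial_scaling(self):
        assert np.allclose(project_to_ball(np.array([3.0, 4.0]), 1.0), [0.6, 0.8])

    def test_zero_radius(self):
        assert np.array_equal(project_to_ball(np.array([1.0, -2.0]), 0.0), [0.0, 0.0])


class TestObjectives:
    def test_primal_at_data(self, rng):
        X = rng.standard_normal((3, 3, 2))
        g = random_sparse_graph(X.shape, rng)
        ops = operators_from_graph(g)
        pen = sum(
            float(np.dot(w, np.linalg.norm(op.apply(vectorize(X)), axis=1)))
            for op, w in zip(ops, g.weights)
        )
        assert primal_objective(vectorize(X), X, g, 2.0) == pytest.approx(2.0 * pen)
        assert primal_objective(vectorize(X), X, g, 0.0) == pytest.approx(0.0)

    def test_primal_matches_naive_evaluation(self, rng):
        X = rng.standard_normal((3, 3, 2))
        g = random_sparse_graph(X.shape, rng)
        u = rng.standard_normal(X.size)
        blocks, w = dense_blocks(g)
        naive = 0.5 * np.sum((vectorize(X) - u) ** 2) + 1.3 * sum(
            wb * np.linalg.norm(B @ u) for B, wb in zip(blocks, w)
        )
        assert primal_objective(u, X, g, 1.3) == pytest.approx(naive)

    def test_dual_zero_and_weak_duality(self, rng):
        X = rng.standard_normal((3, 2, 2))
        g = random_sparse_graph(X.shape, rng)
        zero = [np.zeros((len(E), X.size // X.shape[d])) for d, E in enumerate(g.edges)]
        assert dual_objective(zero, X, g, 0.5) == pytest.approx(0.0)
        # random feasible lambda never exceeds the primal at its own u
        for _ in range(5):
            lam = []
            for d, (E, w) in enumerate(zip(g.edges, g.weights)):
                L = rng.standard_normal((len(E), X.size // X.shape[d]))
                radii = 0.5 * w
                L *= (radii / np.maximum(np.linalg.norm(L, axis=1), 1e-12))[:, None]
                L *= rng.uniform(0, 1, size=(len(E), 1))
                lam.append(L)
            G = dual_objective(lam, X, g, 0.5)
            ops = operators_from_graph(g)
            u = vectorize(X) - sum(
                op.apply_transpose(L) for op, L in zip(ops, lam) if op.n_edges
            )
            assert G <= primal_objective(u, X, g, 0.5) + 1e-10

    def test_infeasible_dual_is_minus_inf(self, rng):
        X = rng.standard_normal((3, 2, 2))
        g = random_sparse_graph(X.shape, rng)
        lam = [
            np.full((len(E), X.size // X.shape[d]), 10.0)
            for d, E in enumerate(g.edges)
        ]
        assert dual_objective(lam, X, g, 1e-6) == -np.inf


class TestAutoStepSize:
    def test_single_edge_single_mode(self):
        g = ModeGraph((2, 2), [np.array([[0, 1]])], [np.array([1.0])])
        g.edges.append(np.zeros((0, 2), dtype=int))
        g.weights.append(np.zeros(0))
        eta = auto_step_size(g)
        # Delta = e1 - e2 has squared spectral norm 2, so eta = 1/2
        assert eta == pytest.approx(0.5, rel=0.02)

    def test_within_one_percent_of_dense_eigenvalue(self, rng):
        X_shape = (3, 3, 2)
        g = random_sparse_graph(X_shape, rng)
        eta = auto_step_size(g)
        A = np.vstack(dense_blocks(g)[0])
        L_true = np.linalg.eigvalsh(A @ A.T).max()
        assert 1.0 / eta == pytest.approx(L_true, rel=0.015)
        assert eta > 0


class TestSolve:
    def test_gamma_zero_returns_data_exactly(self, rng):
        X = rng.standard_normal((3, 3, 2))
        g = random_sparse_graph(X.shape, rng)
        fit = solve(X, g, 0.0)
        assert np.array_equal(fit.u, vectorize(X))
        assert fit.converged

    def test_large_gamma_gives_grand_mean(self, rng):
        X = rng.standard_normal((3, 3, 2))
        g = random_sparse_graph(X.shape, rng)
        gmax = find_gamma_max(X, g)
        fit = solve(X, g, gmax)
        xbar = float(np.mean(X))
        assert np.linalg.norm(fit.u - xbar) <= 1e-6 * np.linalg.norm(vectorize(X))

    def test_matches_independent_primal_oracle(self, rng):
        for _ in range(3):
            shape = tuple(rng.integers(2, 5, size=3))
            X = rng.standard_normal(shape)
            g = random_sparse_graph(shape, rng)
            for gamma in (0.01, 0.1, 1.0):
                fit = solve(X, g, gamma, config=SolverConfig(tol=1e-10))
                oracle = admm_primal_minimizer(X, g, gamma)
                rel = np.linalg.norm(fit.u - oracle) / max(np.linalg.norm(oracle), 1e-12)
                assert rel <= 1e-4

    def test_plain_pg_monotone_dual_ascent(self, rng):
        X = rng.standard_normal((3, 3, 2))
        g = random_sparse_graph(X.shape, rng)
        cfg = SolverConfig(accelerate=False, max_iter=200, check_every=1, tol=1e-14)
        # instrument: track dual objective over iterations via repeated solves
        values = []
        for iters in (10, 50, 100, 200):
            fit = solve(X, g, 0.5, config=SolverConfig(
                accelerate=False, max_iter=iters, check_every=iters, tol=1e-16))
            values.append(dual_objective(fit.dual, X, g, 0.5))
        assert all(values[i + 1] >= values[i] - 1e-12 for i in range(len(values) - 1))

    def test_dual_feasible_at_solution(self, rng):
        X = rng.standard_normal((3, 3, 2))
        g = random_sparse_graph(X.shape, rng)
        fit = solve(X, g, 0.7)
        for L, w in zip(fit.dual, g.weights):
            assert np.all(np.linalg.norm(L, axis=1) <= 0.7 * w * (1 + 1e-10))
        assert fit.gap >= 0.0

    def test_nonexpansiveness(self, rng):
        shape = (3, 3, 2)
        g = random_sparse_graph(shape, rng)
        cfg = SolverConfig(tol=1e-10)
        for _ in range(5):
            X = rng.standard_normal(shape)
            Xt = X + 0.3 * rng.standard_normal(shape)
            uA = solve(X, g, 0.5, config=cfg).u
            uB = solve(Xt, g, 0.5, config=cfg).u
            assert np.linalg.norm(uA - uB) <= np.linalg.norm(
                vectorize(X) - vectorize(Xt)
            ) + 1e-6

    def test_permutation_equivariance(self, rng):
        X = rng.standard_normal((5, 4, 3))
        cfg = WeightConfig(k=2, tucker_ranks="off")
        g = build_weights(X, cfg)
        perm = rng.permutation(5)
        Xp = X[perm]
        gp = build_weights(Xp, cfg)
        scfg = SolverConfig(tol=1e-11)
        u = solve(X, g, 0.3, config=scfg).tensor
        up = solve(Xp, gp, 0.3, config=scfg).tensor
        assert np.allclose(up, u[perm], atol=1e-5)

    def test_continuity_in_gamma(self, rng):
        X = rng.standard_normal((3, 3, 2))
        g = random_sparse_graph(X.shape, rng)
        cfg = SolverConfig(tol=1e-11)
        base = solve(X, g, 0.5, config=cfg).u
        diffs = []
        for delta in (0.1, 0.01, 0.001):
            diffs.append(np.linalg.norm(solve(X, g, 0.5 + delta, config=cfg).u - base))
        assert diffs[0] > diffs[1] > diffs[2]
        assert diffs[2] <= 1e-2

    def test_negative_gamma_rejected(self, rng):
        X = rng.standard_normal((2, 2))
        g = random_sparse_graph(X.shape, rng)
        with pytest.raises(ValueError):
            solve(X, g, -1.0)


class TestSolutionPath:
    def test_single_zero_grid(self, rng):
        X = rng.standard_normal((3, 2, 2))
        g = random_sparse_graph(X.shape, rng)
        fits = solution_path(X, g, [0.0])
        assert len(fits) == 1 and np.array_equal(fits[0].u, vectorize(X))

    def test_rss_nondecreasing(self, rng):
        X = rng.standard_normal((4, 3, 3))
        g = random_sparse_graph(X.shape, rng)
        fits = solution_path(X, g, np.geomspace(0.01, 20.0, 12))
        rss = [float(np.sum((vectorize(X) - f.u) ** 2)) for f in fits]
        # slack of order the solver's relative gap tolerance
        assert all(
            rss[i + 1] >= rss[i] - 1e-5 * max(1.0, rss[i])
            for i in range(len(rss) - 1)
        )

    def test_warm_equals_cold(self, rng):
        X = rng.standard_normal((3, 3, 3))
        g = random_sparse_graph(X.shape, rng)
        cfg = SolverConfig(tol=1e-10)
        grid = np.geomspace(0.05, 5.0, 8)
        warm = solution_path(X, g, grid, config=cfg)
        for fit in warm:
            cold = solve(X, g, fit.gamma, config=cfg)
            rel = np.linalg.norm(fit.u - cold.u) / max(np.linalg.norm(cold.u), 1e-12)
            assert rel <= 1e-5

    def test_unsorted_grid_rejected(self, rng):
        X = rng.standard_normal((2, 2))
        g = random_sparse_graph(X.shape, rng)
        with pytest.raises(ValueError):
            solution_path(X, g, [1.0, 0.5])
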