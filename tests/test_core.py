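"""Penalized least-squares objective, multiplicative updates, and restarts."""

import numpy as np
import pytest

from conftest import naive_objective, naive_update_step, random_weight_matrix
from plsmc import (
    OptimizerConfig,
    compute_weights,
    estimate,
    fit_restarts,
    gradient,
    objective,
    random_init,
    update_step,
)

TWO_NODE_S = np.array([[0.0, 1.0], [1.0, 0.0]])


class TestObjective:
    def test_two_node_hand_values(self):
        theta = np.array([[1.0], [1.0]])
        # diagonal residuals (1-0)^2/2 each; off-diagonal residuals vanish
        assert objective(theta, TWO_NODE_S, 0.0) == pytest.approx(1.0)
        assert objective(theta, TWO_NODE_S, 1.0) == pytest.approx(3.0)

    def test_zero_theta(self):
        rng = np.random.default_rng(7)
        S = random_weight_matrix(rng, 6)
        theta = np.zeros((6, 2))
        assert objective(theta, S, 0.5) == pytest.approx(0.5 * np.sum(S**2))

    def test_matches_naive_loops(self):
        rng = np.random.default_rng(11)
        S = random_weight_matrix(rng, 7)
        theta = rng.random((7, 3))
        assert objective(theta, S, 0.3) == pytest.approx(
            naive_objective(theta, S, 0.3), rel=1e-12
        )

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            objective(np.ones((3, 2)), TWO_NODE_S, 1.0)


class TestUpdateStep:
    def test_two_node_hand_value(self):
        theta = np.array([[1.0], [1.0]])
        out = update_step(theta, TWO_NODE_S, 0.0)
        assert out == pytest.approx(np.array([[0.75], [0.75]]))

    def test_zero_is_fixed_point(self):
        theta = np.zeros((4, 2))
        S = random_weight_matrix(np.random.default_rng(0), 4)
        assert np.array_equal(update_step(theta, S, 0.5), theta)

    def test_zero_entries_stay_zero_and_nonnegative(self):
        rng = np.random.default_rng(3)
        S = random_weight_matrix(rng, 8)
        theta = rng.random((8, 3))
        theta[theta < 0.4] = 0.0
        out = update_step(theta, S, 0.2)
        assert np.all(out >= 0)
        assert np.all(out[theta == 0] == 0)

    def test_negative_input_rejected(self):
        theta = np.array([[-0.1], [1.0]])
        with pytest.raises(ValueError):
            update_step(theta, TWO_NODE_S, 0.0)

    @pytest.mark.parametrize("lam", [0.0, 0.1, 1.0])
    def test_matches_naive_loops(self, lam):
        rng = np.random.default_rng(int(lam * 10) + 1)
        S = random_weight_matrix(rng, 9)
        theta = rng.random((9, 3))
        assert np.allclose(
            update_step(theta, S, lam), naive_update_step(theta, S, lam), atol=1e-12
        )

    def test_objective_never_increases(self):
        rng = np.random.default_rng(42)
        S = random_weight_matrix(rng, 10)
        theta = rng.random((10, 3))
        for _ in range(50):
            new = update_step(theta, S, 0.1)
            assert objective(new, S, 0.1) <= objective(theta, S, 0.1) + 1e-12
            theta = new


class TestGradient:
    def test_against_central_finite_differences(self):
        rng = np.random.default_rng(5)
        S = random_weight_matrix(rng, 6)
        theta = rng.random((6, 3))
        lam = 0.25
        g = gradient(theta, S, lam)
        h = 1e-6
        for i in range(6):
            for k in range(3):
                e = np.zeros_like(theta)
                e[i, k] = h
                fd = (objective(theta + e, S, lam) - objective(theta - e, S, lam)) / (2 * h)
                assert g[i, k] == pytest.approx(fd, rel=1e-5, abs=1e-8)


class TestEstimate:
    def _instance(self, seed=0, n=12, k=3):
        rng = np.random.default_rng(seed)
        S = random_weight_matrix(rng, n)
        init = random_init(S, k, rng)
        return S, init

    def test_trajectory_monotone_and_consistent(self):
        S, init = self._instance()
        cfg = OptimizerConfig(k=3, lam=0.1, restarts=1)
        res = estimate(S, cfg, init)
        traj = np.array(res.trajectory)
        assert np.all(np.diff(traj) <= 1e-9 * (1 + traj[0]))
        assert res.objective == traj[-1]
        assert res.iterations == len(traj) - 1

    def test_converged_flag_and_determinism(self):
        S, init = self._instance(seed=1)
        cfg = OptimizerConfig(k=3, lam=0.1, restarts=1, rel_tol=1e-8, max_iter=5000)
        a = estimate(S, cfg, init)
        b = estimate(S, cfg, init)
        assert a.converged
        assert a.iterations < cfg.max_iter
        assert np.array_equal(a.theta, b.theta)
        assert a.trajectory == b.trajectory

    def test_max_iter_cap_marks_unconverged(self):
        S, init = self._instance(seed=2)
        cfg = OptimizerConfig(k=3, lam=0.1, restarts=1, rel_tol=1e-16, max_iter=5)
        res = estimate(S, cfg, init)
        assert not res.converged
        assert res.iterations == 5

    def test_negative_init_rejected(self):
        S, init = self._instance()
        with pytest.raises(ValueError):
            estimate(S, OptimizerConfig(k=3, restarts=1), -init)

    def test_recovers_two_planted_triangles(self):
        # Two disjoint triangles under geometric weights: S is block
        # all-ones off-diagonal.  Because the objective sums ordered pairs
        # including i=j (with S_ii = 0), the optimal rank-1 fit of a size-m
        # all-ones block is theta_i = sqrt((m-1)/m), giving off-diagonal
        # reconstruction (m-1)/m = 2/3 for triangles (plus an O(lam) shift).
        from plsmc import PPINetwork, PostprocessConfig, threshold_complexes

        net = PPINetwork(
            [("a", "b"), ("b", "c"), ("a", "c"), ("x", "y"), ("y", "z"), ("x", "z")]
        )
        S = compute_weights(net, variant="geometric")
        cfg = OptimizerConfig(k=2, lam=0.01, restarts=20, seed=0, rel_tol=1e-10,
                              max_iter=5000)
        res = fit_restarts(S, cfg)
        recon = res.theta @ res.theta.T
        within = (S.values == 1.0)
        across = (S.values == 0.0) & ~np.eye(6, dtype=bool)
        assert np.allclose(recon[within], 2 / 3, atol=0.02)
        assert np.max(recon[across]) < 0.01
        cs = threshold_complexes(res, net.nodes, PostprocessConfig(tau=0.2))
        assert sorted(sorted(c) for c in cs) == [["a", "b", "c"], ["x", "y", "z"]]


class TestFitRestarts:
    def test_single_restart_equals_estimate_with_derived_init(self):
        rng = np.random.default_rng(9)
        S = random_weight_matrix(rng, 10)
        cfg = OptimizerConfig(k=3, lam=0.2, restarts=1, seed=123)
        init = random_init(S, 3, np.random.default_rng([123, 0]))
        direct = estimate(S, cfg, init)
        best = fit_restarts(S, cfg)
        assert np.array_equal(best.theta, direct.theta)

    def test_returns_minimum_over_restarts(self):
        rng = np.random.default_rng(10)
        S = random_weight_matrix(rng, 10)
        cfg = OptimizerConfig(k=3, lam=0.2, restarts=8, seed=7, max_iter=100)
        best = fit_restarts(S, cfg)
        for r in range(cfg.restarts):
            init = random_init(S, 3, np.random.default_rng([7, r]))
            res = estimate(S, cfg, init)
            assert best.objective <= res.objective + 1e-12

    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(12)
        S = random_weight_matrix(rng, 10)
        cfg = OptimizerConfig(k=3, lam=0.2, restarts=5, seed=99, max_iter=200)
        a, b = fit_restarts(S, cfg), fit_restarts(S, cfg)
        assert np.array_equal(a.theta, b.theta)
        assert a.seed_used == b.seed_used

    def test_penalty_shrinks_propensities(self):
        # total squared propensity at convergence is non-increasing in lambda
        rng = np.random.default_rng(13)
        S = random_weight_matrix(rng, 12)
        norms = []
        for lam in [0.01, 0.1, 0.5, 1.0, 2.0]:
            cfg = OptimizerConfig(k=3, lam=lam, restarts=1, seed=5, max_iter=3000,
                                  rel_tol=1e-10)
            res = fit_restarts(S, cfg)
            norms.append(np.sum(res.theta**2))
        assert all(a >= b - 1e-8 for a, b in zip(norms, norms[1:]))


class TestOptimizerConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"k": 0},
            {"lam": -0.1},
            {"max_iter": 0},
            {"rel_tol": 0.0},
            {"restarts": 0},
            {"eps": 0.0},
        ],
    )
    def test_invalid_settings_rejected(self, kwargs):
        with pytest.raises(ValueError):
            OptimizerConfig(**kwargs)
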