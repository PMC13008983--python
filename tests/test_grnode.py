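"""Graph-regularized neural ODE: adjacency, solver, losses, training, CV."""

import numpy as np
import pytest

from krtecon import grnode
from krtecon.panel import DynamicsSpec, PanelConfig, generate_panel


def _small_config(**kw):
    defaults = dict(hidden=(8, 8), n_steps=4, epochs=50, lambda_graph=0.1,
                    lambda_curv=0.01, weight_decay=0.0, n_ensemble=1, seed=0)
    defaults.update(kw)
    return grnode.GRNODEConfig(**defaults)


class TestAdjacency:
    def test_identical_features_unit_weight(self):
        z = np.array([[1.0, 2.0], [1.0, 2.0], [0.0, 0.0]])
        adj = grnode.build_adjacency(z, sigma=0.5)
        assert adj.A[0, 1] == pytest.approx(1.0)

    def test_kernel_value_at_bandwidth_distance(self):
        # squared distance exactly sigma^2 -> weight exp(-1)
        sigma = 0.5
        z = np.array([[0.0], [sigma]])
        adj = grnode.build_adjacency(z, sigma=sigma)
        assert adj.A[0, 1] == pytest.approx(np.exp(-1.0), abs=1e-12)

    def test_symmetry_unit_diagonal_and_range(self):
        rng = np.random.default_rng(0)
        z = rng.normal(size=(14, 3))
        adj = grnode.build_adjacency(z, sigma=0.5)
        np.testing.assert_allclose(adj.A, adj.A.T)
        np.testing.assert_allclose(np.diag(adj.A), 1.0)
        assert ((adj.A > 0) & (adj.A <= 1)).all()

    def test_monotone_decreasing_in_distance(self):
        z = np.array([[0.0], [1.0], [2.0]])
        adj = grnode.build_adjacency(z, sigma=1.0)
        assert adj.A[0, 1] > adj.A[0, 2]

    def test_pair_count_for_14_countries(self):
        z = np.zeros((14, 3))
        assert grnode.build_adjacency(z, 0.5).n_pairs == 91

    def test_bad_inputs_rejected(self):
        with pytest.raises(ValueError):
            grnode.build_adjacency(np.zeros((3, 2)), sigma=0.0)
        with pytest.raises(ValueError):
            grnode.build_adjacency(np.zeros(3), sigma=0.5)


class TestCountParameters:
    def test_stated_architecture(self):
        # (5*32+32) + (32*32+32) + (32*1+32) = 192 + 1056 + 64
        assert grnode.count_parameters(5, 1) == 1312

    def test_unit_width_analogue_matches_hand_count(self):
        # (1*1+1) + (1*1+1) + (1*1+1)
        assert grnode.count_parameters(1, 1, widths=(1, 1)) == 6

    def test_doubling_widths_quadruples_middle_weights(self):
        def middle(w):
            return w * w  # weight count of the hidden-to-hidden block
        assert middle(64) == 4 * middle(32)
        diff_64 = grnode.count_parameters(5, 1, (64, 64))
        diff_32 = grnode.count_parameters(5, 1, (32, 32))
        # consistency of the full formula with the algebra above
        assert diff_64 - diff_32 == (5 * 32 + 32) + (64 * 64 - 32 * 32 + 32) + (
            32 * 1 + 32
        )


class TestDynamics:
    def test_zero_parameters_zero_derivative(self):
        params = {k: np.zeros_like(v)
                  for k, v in grnode.init_params(5, (32, 32), 0).items()}
        out = grnode.dynamics(np.ones(5), 0.3, params)
        np.testing.assert_allclose(out, 0.0)

    @pytest.mark.parametrize("n", range(2, 9))
    def test_output_dimension_matches_state(self, n):
        params = grnode.init_params(n, (16, 16), seed=1)
        x = np.random.default_rng(n).normal(size=(4, n))
        assert grnode.dynamics(x, 0.5, params).shape == (4, n)

    def test_nonfinite_state_rejected(self):
        params = grnode.init_params(3, (8, 8), 0)
        with pytest.raises(ValueError):
            grnode.dynamics(np.array([np.nan, 0.0, 1.0]), 0.0, params)

    def test_gradient_matches_finite_differences(self):
        # hand-derived reverse-mode gradients of the full composite loss
        # against central finite differences
        rng = np.random.default_rng(0)
        N, n = 5, 4
        cfg = _small_config(lambda_graph=0.3, lambda_curv=0.02)
        z = rng.normal(size=(N, 3))
        A = grnode.build_adjacency(z, 0.7).A
        x0 = rng.normal(size=(1, N, n))
        obs = np.stack([x0[0, :, 0], x0[0, :, 0] + 0.3], axis=1)
        mask = np.ones((1, N), dtype=bool)
        params = grnode._stack_params([grnode.init_params(n, cfg.hidden, 1)])

        def total(p):
            tl, _ = grnode._integrate_cached(x0, p, (0, 1), cfg.n_steps)
            traj = np.stack(tl)
            ld, _ = grnode._data_loss_and_cotangent(traj, obs, cfg, mask)
            lg, _ = grnode._graph_loss_and_cotangent(traj, A)
            lc, _ = grnode._curv_loss_and_cotangent(traj)
            return ld + cfg.lambda_graph * lg + cfg.lambda_curv * lc

        tl, caches = grnode._integrate_cached(x0, params, (0, 1), cfg.n_steps)
        traj = np.stack(tl)
        ld, cd = grnode._data_loss_and_cotangent(traj, obs, cfg, mask)
        lg, cg = grnode._graph_loss_and_cotangent(traj, A)
        lc, cc = grnode._curv_loss_and_cotangent(traj)
        cot = cd + cfg.lambda_graph * cg + cfg.lambda_curv * cc
        grads = grnode._backward(list(cot), caches, params)
        for key, g in grads.items():
            flat = params[key].ravel()
            gflat = g.ravel()
            for idx in rng.choice(flat.size, size=min(5, flat.size), replace=False):
                orig = flat[idx]
                eps = 1e-6
                flat[idx] = orig + eps
                up = total(params)
                flat[idx] = orig - eps
                down = total(params)
                flat[idx] = orig
                fd = (up - down) / (2 * eps)
                assert gflat[idx] == pytest.approx(fd, rel=1e-4, abs=1e-8)


class TestIntegrate:
    def test_zero_dynamics_constant_trajectory(self):
        params = {k: np.zeros_like(v)
                  for k, v in grnode.init_params(3, (8, 8), 0).items()}
        x0 = np.array([[1.0, -2.0, 0.5]])
        traj = grnode.integrate(x0, params, n_steps=8)
        for state in traj:
            np.testing.assert_allclose(state, x0)

    def test_constant_field_exact(self):
        c = np.array([0.3, -0.7])
        traj = grnode.integrate(np.zeros((1, 2)), lambda x, t: np.broadcast_to(c, x.shape),
                                n_steps=5)
        np.testing.assert_allclose(traj[-1], c[None, :], atol=1e-14)

    @pytest.mark.parametrize("a", [-1.0, -0.3, 0.5, 1.0])
    def test_exponential_growth_closed_form(self, a):
        traj = grnode.integrate(np.ones((1, 1)), lambda x, t: a * x, n_steps=16)
        assert traj[-1][0, 0] == pytest.approx(np.exp(a), abs=1e-6)

    def test_nonfinite_initial_state_rejected(self):
        params = grnode.init_params(2, (8, 8), 0)
        with pytest.raises(ValueError):
            grnode.integrate(np.array([[np.inf, 0.0]]), params)


class TestLossComponents:
    def _setup(self):
        rng = np.random.default_rng(3)
        traj = rng.normal(size=(5, 4, 3))
        obs = rng.normal(size=(4, 2))
        A = grnode.build_adjacency(rng.normal(size=(4, 2)), 1.0).A
        return traj, obs, A

    def test_identical_trajectories_zero_graph_penalty(self):
        traj, obs, A = self._setup()
        traj = np.repeat(traj[:, :1, :], 4, axis=1)  # all countries identical
        _, lg, _, _ = grnode.loss_components(traj, obs, A, _small_config())
        assert lg == pytest.approx(0.0, abs=1e-12)

    def test_straight_line_trajectories_zero_curvature(self):
        traj, obs, A = self._setup()
        t = np.linspace(0, 1, 5)[:, None, None]
        linear = traj[0][None] * (1 - t) + traj[-1][None] * t
        _, _, lc, _ = grnode.loss_components(linear, obs, A, _small_config())
        assert lc == pytest.approx(0.0, abs=1e-16)

    def test_perfect_predictions_zero_data_loss(self):
        traj, obs, A = self._setup()
        obs = np.stack([traj[0, :, 0], traj[-1, :, 0]], axis=1)
        cfg = _small_config(lambda_graph=0.7, lambda_curv=0.3)
        ld, lg, lc, lt = grnode.loss_components(traj, obs, A, cfg)
        assert ld == pytest.approx(0.0, abs=1e-20)
        assert lt == pytest.approx(0.7 * lg + 0.3 * lc)

    def test_composition_identity(self):
        traj, obs, A = self._setup()
        cfg = _small_config(lambda_graph=0.37, lambda_curv=0.013)
        ld, lg, lc, lt = grnode.loss_components(traj, obs, A, cfg)
        assert lt == pytest.approx(ld + 0.37 * lg + 0.013 * lc, rel=1e-14)


class TestTrain:
    @staticmethod
    def _easy_panel(seed=0):
        # noise-free panel with pure drift dynamics: the break-even ratio is
        # unchanged between years, a recoverable (zero-dynamics) signal
        cfg = PanelConfig(
            seed=seed,
            dynamics_spec=DynamicsSpec(amplitude=0.0, noise_scale=0.0, drift=0.05),
        )
        return generate_panel(cfg)

    def test_recoverable_signal_low_data_loss(self):
        panel = self._easy_panel()
        cfg = grnode.GRNODEConfig(hidden=(32, 32), epochs=400, n_steps=4,
                                  lambda_graph=0.001, weight_decay=0.0, seed=0)
        fit = grnode.train(panel, cfg)
        assert fit.loss_trace["L_data"].iloc[-1] < 1e-3

    def test_seeded_determinism(self):
        panel = self._easy_panel(1)
        cfg = _small_config(epochs=30)
        t1 = grnode.train(panel, cfg).loss_trace
        t2 = grnode.train(panel, cfg).loss_trace
        np.testing.assert_array_equal(t1.to_numpy(), t2.to_numpy())

    def test_loss_trace_composition_invariant(self):
        panel = self._easy_panel(2)
        cfg = _small_config(epochs=40, lambda_graph=0.2, lambda_curv=0.05)
        trace = grnode.train(panel, cfg).loss_trace
        np.testing.assert_allclose(
            trace["L_total"],
            trace["L_data"] + 0.2 * trace["L_graph"] + 0.05 * trace["L_curv"],
            rtol=1e-12,
        )

    def test_graph_penalty_shrinks_along_regularization_path(self):
        panel = generate_panel(PanelConfig(seed=4))
        finals = []
        for lam in (0.01, 0.1, 1.0, 10.0):
            cfg = _small_config(epochs=150, lambda_graph=lam)
            finals.append(grnode.train(panel, cfg).loss_trace["L_graph"].iloc[-1])
        assert all(a > b for a, b in zip(finals, finals[1:]))

    def test_single_country_rejected(self, default_panel):
        single = default_panel[default_panel["country_id"] == "C01"]
        with pytest.raises(ValueError):
            grnode.train(single, _small_config())


class TestLocoCV:
    def test_fourteen_held_out_predictions(self, default_panel):
        cfg = _small_config(epochs=30)
        res = grnode.loco_cv(default_panel, cfg)
        assert len(res.predictions) == 14
        assert res.predictions.index.tolist() == res.observed.index.tolist()

    def test_r_squared_of_perfect_and_mean_predictors(self):
        obs = np.array([1.0, 2.0, 3.0, 4.0])
        assert grnode.r_squared(obs, obs) == pytest.approx(1.0)
        assert grnode.r_squared(obs, np.full(4, obs.mean())) == pytest.approx(0.0)

    def test_too_few_countries_rejected(self, default_panel):
        two = default_panel[default_panel["country_id"].isin(["C01", "C02"])]
        with pytest.raises(ValueError):
            grnode.loco_cv(two, _small_config())


class TestBootstrap:
    def test_interval_brackets_point_for_stable_panels(self, default_panel):
        cfg = _small_config(epochs=40)
        res = grnode.bootstrap_ci(default_panel, cfg, B=100, seed=0, chunk=50)
        assert res.lower <= res.upper
        assert len(res.samples) == 100

    def test_near_noiseless_panel_narrow_interval(self):
        cfg_panel = PanelConfig(
            seed=0, dynamics_spec=DynamicsSpec(amplitude=0.0, noise_scale=0.0)
        )
        panel = generate_panel(cfg_panel)
        cfg = grnode.GRNODEConfig(hidden=(16, 16), epochs=200, n_steps=4,
                                  lambda_graph=0.001, weight_decay=0.0, seed=0)
        res = grnode.bootstrap_ci(panel, cfg, B=100, seed=1, chunk=50)
        # zero-dynamics panel: every replicate fits almost exactly
        assert res.upper - res.lower < 0.05
        assert res.upper < 0.05

    def test_small_b_rejected(self, default_panel):
        with pytest.raises(ValueError):
            grnode.bootstrap_ci(default_panel, _small_config(), B=10)
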