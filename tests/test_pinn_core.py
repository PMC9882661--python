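"""Network forward/gradients, Taylor polynomial, residuals, losses."""

import numpy as np
import pytest

import pulsepinn as pp
from pulsepinn.errors import ConfigError, InsufficientSequenceError, NoLabelsError
from pulsepinn.pinn_core import ModelConfig, init_params, loss_and_param_grads

from conftest import make_tiny_dataset

ACTIVE = 100.0  # large hidden bias keeps ReLU units in their linear region


def linear_u_params(cfg, w=(2.0, -1.0, 0.0), bias=0.0):
    """A network that computes exactly y = w·u + bias, ignoring x.

    One always-active hidden unit per feature; all convolution weights are
    zero so the waveform path contributes nothing.
    """
    params = init_params(cfg, 0)
    for k in params.values:
        params.values[k] = np.zeros_like(params.values[k])
    F = cfg.flat_len
    for k, wk in enumerate(w):
        params.values["W1"][k, F + k] = wk
        params.values["b1"][k] = ACTIVE
        params.values["w2"][k] = 1.0
    params.values["b2"] = np.asarray(bias - len(w) * ACTIVE)
    return params


class TestForward:
    def test_zero_weights_collapse_to_bias(self, tiny_cfg):
        params = init_params(tiny_cfg, 0)
        for k in params.values:
            params.values[k] = np.zeros_like(params.values[k])
        params.values["b2"] = np.asarray(3.5)
        rng = np.random.default_rng(0)
        for _ in range(3):
            y = pp.forward(params, rng.normal(size=20), rng.normal(size=3))
            assert y == 3.5

    def test_deterministic_and_batch_consistent(self, tiny_params):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(6, 20))
        U = rng.normal(size=(6, 3))
        y1 = pp.forward(tiny_params, X, U)
        y2 = pp.forward(tiny_params, X, U)
        np.testing.assert_array_equal(y1, y2)
        singles = np.array([pp.forward(tiny_params, X[i], U[i]) for i in range(6)])
        np.testing.assert_allclose(y1, singles, atol=1e-6)

    def test_permutation_equivariance(self, tiny_params):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(8, 20))
        U = rng.normal(size=(8, 3))
        perm = rng.permutation(8)
        np.testing.assert_allclose(
            pp.forward(tiny_params, X[perm], U[perm]),
            pp.forward(tiny_params, X, U)[perm],
            atol=1e-12,
        )

    def test_shape_mismatch_rejected(self, tiny_params):
        with pytest.raises(ConfigError):
            pp.forward(tiny_params, np.zeros(21), np.zeros(3))
        with pytest.raises(ConfigError):
            pp.forward(tiny_params, np.zeros(20), np.zeros(4))


class TestFeatureGradients:
    def test_linear_readout_gradient_is_exact(self, tiny_cfg):
        w = (2.0, -1.0, 0.5)
        params = linear_u_params(tiny_cfg, w=w)
        rng = np.random.default_rng(4)
        g = pp.feature_gradients(params, rng.normal(size=20), rng.normal(size=3))
        np.testing.assert_array_equal(g, w)

    def test_matches_central_finite_differences(self, tiny_cfg):
        rng = np.random.default_rng(5)
        for trial in range(5):
            params = init_params(tiny_cfg, trial)
            x, u = rng.normal(size=20), rng.normal(size=3)
            g = pp.feature_gradients(params, x, u)
            fd = np.empty(3)
            for k in range(3):
                e = np.zeros(3)
                e[k] = 1e-4
                fd[k] = (
                    pp.forward(params, x, u + e) - pp.forward(params, x, u - e)
                ) / 2e-4
            np.testing.assert_allclose(g, fd, rtol=1e-4, atol=1e-7)

    def test_zero_network_zero_gradient(self, tiny_cfg):
        params = init_params(tiny_cfg, 0)
        for k in params.values:
            params.values[k] = np.zeros_like(params.values[k])
        g = pp.feature_gradients(params, np.ones(20), np.ones(3))
        np.testing.assert_array_equal(g, np.zeros(3))

    def test_nan_weights_rejected(self, tiny_params):
        tiny_params.values["w2"][0] = np.nan
        with pytest.raises(ConfigError):
            pp.feature_gradients(tiny_params, np.zeros(20), np.zeros(3))


class TestTaylorEvaluate:
    def test_printed_formula_arithmetic(self, tiny_cfg):
        # f(anchor) = 5, gradients (2, -1, 0), displacement (1, 1, 7) -> P = 6
        anchor_u = np.zeros(3)
        params = linear_u_params(tiny_cfg, w=(2.0, -1.0, 0.0), bias=5.0)
        x = np.zeros(20)
        assert pp.forward(params, x, anchor_u) == pytest.approx(5.0)
        P = pp.taylor_evaluate(params, x, anchor_u, anchor_u + [1.0, 1.0, 7.0])
        assert P == pytest.approx(6.0)

    def test_zero_displacement_returns_anchor_value(self, tiny_params):
        rng = np.random.default_rng(6)
        x, u = rng.normal(size=20), rng.normal(size=3)
        assert pp.taylor_evaluate(tiny_params, x, u, u) == pytest.approx(
            pp.forward(tiny_params, x, u), abs=1e-12
        )

    def test_exact_for_network_linear_in_u(self, tiny_cfg):
        params = linear_u_params(tiny_cfg, w=(1.5, -0.7, 0.3), bias=2.0)
        rng = np.random.default_rng(7)
        anchor_x, anchor_u = rng.normal(size=20), rng.normal(size=3)
        for _ in range(5):
            target = rng.normal(scale=5.0, size=3)
            P = pp.taylor_evaluate(params, anchor_x, anchor_u, target)
            y = pp.forward(params, rng.normal(size=20), target)
            assert P == pytest.approx(y, abs=1e-10)


class TestResiduals:
    def test_identical_beats_give_zero(self, tiny_cfg, tiny_params):
        ds = make_tiny_dataset()
        ds.waveforms[:] = ds.waveforms[0]
        ds.features[:] = ds.features[0]
        h = pp.residuals(ds, tiny_params)
        np.testing.assert_allclose(h, 0.0, atol=1e-14)

    def test_linear_in_u_network_has_zero_residuals(self, tiny_cfg):
        params = linear_u_params(tiny_cfg, w=(1.0, 2.0, -0.5))
        h = pp.residuals(make_tiny_dataset(seed=3), params)
        np.testing.assert_allclose(h, 0.0, atol=1e-10)

    def test_brute_force_oracle(self, tiny_params):
        ds = make_tiny_dataset(seed=4)
        h = pp.residuals(ds, tiny_params)
        expected = []
        for sid, run in ds.session_runs():
            for i, j in zip(run[:-1], run[1:]):
                P = pp.taylor_evaluate(
                    tiny_params, ds.waveforms[i], ds.features[i], ds.features[j]
                )
                expected.append(
                    pp.forward(tiny_params, ds.waveforms[j], ds.features[j]) - P
                )
        np.testing.assert_allclose(h, expected, atol=1e-6)

    def test_session_boundaries_excluded(self, tiny_params):
        ds = make_tiny_dataset(n_beats=9, sessions=["a"] * 5 + ["b"] * 4)
        assert pp.residuals(ds, tiny_params).shape == (7,)  # 4 + 3 pairs

    def test_single_beat_rejected(self, tiny_params):
        ds = make_tiny_dataset(n_beats=1, sessions=["a"])
        with pytest.raises(InsufficientSequenceError):
            pp.residuals(ds, tiny_params)

    def test_vanishes_as_consecutive_segments_coincide(self, tiny_cfg):
        params = init_params(tiny_cfg, 2)
        rng = np.random.default_rng(8)
        x0, u0 = rng.normal(size=20), rng.normal(size=3)
        dx, du = rng.normal(size=20), rng.normal(size=3)

        def h_at(delta):
            ds = make_tiny_dataset(n_beats=2, sessions=["a", "a"])
            ds.waveforms = np.stack([x0, x0 + delta * dx])
            ds.features = np.stack([u0, u0 + delta * du])
            return abs(pp.residuals(ds, params)[0])

        h0 = h_at(1e-3)
        for delta in (1e-4, 1e-5, 1e-6):
            assert h_at(delta) <= 2.0 * h0 * (delta / 1e-3) + 1e-12


class TestLosses:
    def test_physics_loss_is_mean_squared_residual(self, tiny_params):
        ds = make_tiny_dataset(seed=5)
        h = pp.residuals(ds, tiny_params)
        assert pp.physics_loss(ds, tiny_params) == pytest.approx(np.mean(h**2))

    def test_physics_loss_ignores_labels(self, tiny_params):
        ds = make_tiny_dataset(seed=6)
        L1 = pp.physics_loss(ds, tiny_params)
        ds.labels = None
        assert pp.physics_loss(ds, tiny_params) == L1

    def test_supervised_loss_examples(self, tiny_cfg):
        params = linear_u_params(tiny_cfg, w=(0.0, 0.0, 0.0))  # y == 0
        ds = make_tiny_dataset(n_beats=2, sessions=["a", "a"])
        ds.labels = np.array([1.0, -1.0])
        assert pp.supervised_loss(ds, [0, 1], params) == pytest.approx(1.0)
        ds.labels = np.array([0.0, 0.0])
        assert pp.supervised_loss(ds, [0, 1], params) == pytest.approx(0.0)

    def test_supervised_loss_requires_labels(self, tiny_params):
        ds = make_tiny_dataset()
        with pytest.raises(NoLabelsError):
            pp.supervised_loss(ds, [], tiny_params)
        ds.labels = None
        with pytest.raises(NoLabelsError):
            pp.supervised_loss(ds, [0], tiny_params)

    def test_total_loss_sum_and_lambda_zero(self, tiny_params):
        ds = make_tiny_dataset(seed=7)
        b = pp.total_loss(ds, [0, 2, 5], tiny_params, lambda_phys=1.0)
        assert b.L_total == pytest.approx(b.L_conv + b.L_phys)
        b0 = pp.total_loss(ds, [0, 2, 5], tiny_params, lambda_phys=0.0)
        assert b0.L_total == b0.L_conv

    def test_bundle_invariant_random_draws(self, tiny_cfg):
        for seed in range(20):
            params = init_params(tiny_cfg, seed)
            ds = make_tiny_dataset(seed=seed)
            lam = (seed % 5) / 2.0
            b = pp.total_loss(ds, [0, 3], params, lambda_phys=lam)
            assert b.L_conv >= 0 and b.L_phys >= 0
            assert b.L_total == pytest.approx(b.L_conv + lam * b.L_phys, rel=1e-12)


class TestParamGradients:
    @pytest.mark.parametrize("lam", [0.0, 0.7])
    def test_fused_gradients_match_finite_differences(self, tiny_cfg, lam):
        params = init_params(tiny_cfg, 1)
        ds = make_tiny_dataset(seed=4)
        idx = np.array([0, 2, 6])
        _, grads = loss_and_param_grads(ds, idx, params, lam)
        flat = params.ravel()
        gflat = np.concatenate([grads[k].ravel() for k in params.KEYS])

        def loss_at(v):
            return pp.total_loss(ds, idx, params.with_ravel(v), lam).L_total

        sel = np.random.default_rng(9).choice(flat.size, 50, replace=False)
        for q in sel:
            e = np.zeros_like(flat)
            e[q] = 1e-6
            fd = (loss_at(flat + e) - loss_at(flat - e)) / 2e-6
            assert gflat[q] == pytest.approx(fd, abs=2e-7)
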