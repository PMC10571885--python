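"""LSTM recurrence, network contracts, Cox fit, training behaviour."""

import math

import numpy as np
import pytest

from ndeepsurv import (LSTMParams, LSTMState, ModelSpec, OptimizerConfig,
                       SimulationConfig, fit_cox_ph, lstm_cell_forward,
                       simulate_cohort, to_sequences, train_model)
from ndeepsurv.losses import NoEventsError
from ndeepsurv.models import (CoxConvergenceError, DeepHitNet, MTLNDeepNet,
                              NDeepNet, build_model, _breslow_ll_grad_hess)
from ndeepsurv.nn import LSTMLayer, seq_to_tensors
from ndeepsurv.autodiff import Tensor


def scalar_lstm_step(wf, uf, bf, wi, ui, bi, wo, uo, bo, wc, uc, bc, x, h, c):
    """Independent h=d=1 reference written with math-module scalars."""
    sig = lambda z: 1.0 / (1.0 + math.exp(-z))
    f = sig(wf * x + uf * h + bf)
    i = sig(wi * x + ui * h + bi)
    o = sig(wo * x + uo * h + bo)
    ct = f * c + i * math.tanh(wc * x + uc * h + bc)
    return o * math.tanh(ct), ct


class TestLSTMCell:
    def test_zero_weights_give_zero_state(self):
        p = LSTMParams.zeros(3, 2)
        s = lstm_cell_forward(p, np.array([5.0, -2.0]), LSTMState.initial(3))
        assert np.array_equal(s.h_t, np.zeros(3))
        assert np.array_equal(s.c_t, np.zeros(3))

    def test_matches_scalar_reference(self):
        rng = np.random.default_rng(20)
        for _ in range(200):
            w = rng.uniform(-2, 2, size=12)
            x, h, c = rng.uniform(-2, 2, size=3)
            p = LSTMParams(*[np.array([[v]]) for v in w[:8]],
                           *[np.array([v]) for v in w[8:]])
            s = lstm_cell_forward(p, np.array([x]), LSTMState(np.array([h]),
                                                              np.array([c])))
            h_ref, c_ref = scalar_lstm_step(
                w[0], w[4], w[8], w[1], w[5], w[9], w[2], w[6], w[10],
                w[3], w[7], w[11], x, h, c)
            assert s.h_t[0] == pytest.approx(h_ref, abs=1e-12)
            assert s.c_t[0] == pytest.approx(c_ref, abs=1e-12)

    def test_gate_output_ranges(self):
        rng = np.random.default_rng(21)
        p = LSTMParams.random(4, 3, rng)
        s = LSTMState.initial(4)
        for _ in range(5):
            s = lstm_cell_forward(p, rng.uniform(-3, 3, 3), s)
            assert np.all(np.abs(s.h_t) < 1.0)

    def test_shape_mismatch_rejected(self):
        p = LSTMParams.zeros(2, 3)
        with pytest.raises(ValueError):
            lstm_cell_forward(p, np.zeros(5), LSTMState.initial(2))

    def test_recurrent_matrix_must_be_square(self):
        kw = {f"{m}_{g}": np.zeros((2, 3)) if m == "W" else
              (np.zeros((2, 2)) if m == "U" else np.zeros(2))
              for g in "fioc" for m in "WUb"}
        kw["U_f"] = np.zeros((2, 3))  # the h x d shape that cannot multiply h
        with pytest.raises(ValueError):
            LSTMParams(**kw)

    def test_layer_matches_reference_cell(self):
        # the trainable layer and the reference cell implement one recurrence
        rng = np.random.default_rng(22)
        layer = LSTMLayer(3, 4, rng)
        p = layer.to_params()
        xs = rng.standard_normal((1, 2, 3))
        out = layer(seq_to_tensors(xs))
        s = LSTMState.initial(4)
        for t in range(2):
            s = lstm_cell_forward(p, xs[0, t], s)
        assert np.allclose(out[-1].data[0], s.h_t, atol=1e-12)


class TestNetworkContracts:
    def _batch(self, n=5, d=3, steps=4, seed=30):
        rng = np.random.default_rng(seed)
        return rng.standard_normal((n, steps, d))

    def test_zero_initialized_ndeep_outputs_constant(self):
        rng = np.random.default_rng(31)
        net = NDeepNet(3, ModelSpec(kind="ndeep", lstm_hidden=4), rng)
        for p in net.parameters():
            p.data[...] = 0.0
        out = net(seq_to_tensors(self._batch()))
        assert np.allclose(out.data, out.data[0])

    def test_ndeep_permutation_equivariance_and_shape(self):
        rng = np.random.default_rng(32)
        net = NDeepNet(3, ModelSpec(kind="ndeep", lstm_hidden=4), rng)
        xs = self._batch()
        out = net(seq_to_tensors(xs)).data
        assert out.shape == (5,)
        assert np.isfinite(out).all()
        perm = np.array([2, 0, 4, 1, 3])
        out_p = net(seq_to_tensors(xs[perm])).data
        assert np.allclose(out_p, out[perm])

    def test_deepsurv_deterministic_in_eval_mode(self):
        rng = np.random.default_rng(33)
        spec = ModelSpec(kind="deepsurv", hidden=[8], dropout=0.5)
        net = build_model(spec, 3, 1, rng)
        net.eval()
        X = Tensor(np.random.default_rng(0).standard_normal((6, 3)))
        assert np.array_equal(net(X).data, net(X).data)

    def test_deepsurv_single_linear_layer_is_linear_predictor(self):
        rng = np.random.default_rng(34)
        net = build_model(ModelSpec(kind="deepsurv", hidden=[]), 3, 1, rng)
        X = np.random.default_rng(1).standard_normal((10, 3))
        out = net(Tensor(X)).data
        beta = net.head.W.data[:, 0]
        assert np.allclose(out, X @ beta + net.head.b.data[0])

    def test_deephit_shape_and_residual_ablation(self):
        rng = np.random.default_rng(35)
        X = np.random.default_rng(2).standard_normal((7, 3))
        with_res = DeepHitNet(3, 2, ModelSpec(kind="deephit", residual="concat",
                                              shared_hidden=[4], hidden=[4]),
                              np.random.default_rng(35))
        no_res = DeepHitNet(3, 2, ModelSpec(kind="deephit", residual="none",
                                            shared_hidden=[4], hidden=[4]),
                            np.random.default_rng(35))
        assert with_res(Tensor(X)).data.shape == (7, 2)
        # ablating the residual changes the function (different head widths)
        assert (with_res.heads[0].layers[0].W.shape
                != no_res.heads[0].layers[0].W.shape)

    def test_mtl_ndeep_shape_and_residual_gradient_flow(self):
        rng = np.random.default_rng(36)
        spec = ModelSpec(kind="mtl_ndeep", lstm_hidden=4, n_lstm_layers=1,
                         shared_hidden=[4])
        net = MTLNDeepNet(3, 2, spec, rng)
        # zero the shared block: the residual path must still carry signal
        for layer in net.shared.layers:
            for p in layer.parameters() if hasattr(layer, "parameters") else []:
                p.data[...] = 0.0
        xs = seq_to_tensors(self._batch(steps=2))
        out = net(xs)
        assert out.data.shape == (5, 2)
        out.sum().backward()
        first_lstm = net.blocks[0][0]
        assert np.any(first_lstm.Wf.grad != 0)


class TestCoxFit:
    def test_constant_covariate_gives_zero_beta(self):
        X = np.ones((20, 1))
        T = np.arange(20, dtype=float)
        E = (np.arange(20) % 2).astype(int)
        m = fit_cox_ph(None, X=X, T=T, E=E)
        assert m.beta[0] == 0.0
        assert m.converged

    def test_gradient_of_implementation_matches_finite_differences(self):
        rng = np.random.default_rng(40)
        X = rng.standard_normal((50, 3))
        T = rng.integers(1, 10, 50).astype(float)
        E = (rng.random(50) < 0.5).astype(int)
        E[0] = 1
        beta = rng.standard_normal(3) * 0.3
        _, grad, _ = _breslow_ll_grad_hess(beta, X, T, E)
        eps = 1e-6
        for k in range(3):
            bp, bm = beta.copy(), beta.copy()
            bp[k] += eps
            bm[k] -= eps
            fd = (_breslow_ll_grad_hess(bp, X, T, E)[0]
                  - _breslow_ll_grad_hess(bm, X, T, E)[0]) / (2 * eps)
            assert grad[k] == pytest.approx(fd, rel=1e-6, abs=1e-7)

    def test_parameter_recovery_on_continuous_time_data(self):
        cfg = SimulationConfig(n=2000, d=2, beta=np.array([[1.0], [-1.0]]),
                               baseline_rate=0.12, followup_years=10,
                               round_to_years=False, seed=41)
        ds, _ = simulate_cohort(cfg)
        m = fit_cox_ph(ds)
        assert np.all(np.abs(m.beta - [1.0, -1.0]) < 0.15)

    def test_separation_is_reported(self):
        # a covariate that perfectly orders event times diverges
        T = np.arange(1, 31, dtype=float)
        X = (-T).reshape(-1, 1)
        E = np.ones(30, int)
        with pytest.raises(CoxConvergenceError, match="separation|converge"):
            fit_cox_ph(None, X=X, T=T, E=E)

    def test_requires_events(self):
        with pytest.raises(NoEventsError):
            fit_cox_ph(None, X=np.ones((5, 1)), T=np.arange(5.0),
                       E=np.zeros(5, int))


class TestTraining:
    def _cohort(self, seed=50):
        beta = np.array([[1.2], [-1.2], [0.0]])
        cfg = SimulationConfig(n=600, d=3, beta=beta, baseline_rate=0.05,
                               followup_years=10, seed=seed)
        return simulate_cohort(cfg)[0]

    def test_same_seed_identical_weights(self):
        ds = self._cohort()
        spec = ModelSpec(kind="deepsurv", hidden=[8])
        opt = OptimizerConfig(epochs=3)
        m1 = train_model(spec, ds, seed=7, opt_cfg=opt)
        m2 = train_model(spec, ds, seed=7, opt_cfg=opt)
        for p1, p2 in zip(m1.net.parameters(), m2.net.parameters()):
            assert np.array_equal(p1.data, p2.data)

    def test_zero_learning_rate_leaves_weights_unchanged(self):
        ds = self._cohort()
        spec = ModelSpec(kind="ndeep", lstm_hidden=4, n_lstm_layers=1)
        rng = np.random.default_rng(7)
        ref = build_model(spec, ds.d, 1, rng)
        init = [p.data.copy() for p in ref.parameters()]
        m = train_model(spec, ds, seed=7,
                        opt_cfg=OptimizerConfig(lr=0.0, epochs=2))
        for p, p0 in zip(m.net.parameters(), init):
            assert np.array_equal(p.data, p0)

    def test_loss_trend_decreases_on_strong_signal(self):
        ds = self._cohort()
        m = train_model(ModelSpec(kind="ndeep", lstm_hidden=8), ds, seed=1,
                        opt_cfg=OptimizerConfig(epochs=12))
        hist = np.array(m.loss_history)
        assert np.isfinite(hist).all()
        assert hist[-3:].mean() < hist[:3].mean()

    def test_early_stopping_restores_best_weights(self):
        ds = self._cohort()
        from ndeepsurv import split_train_test
        tr, va = split_train_test(ds, seed=3)
        m = train_model(ModelSpec(kind="deepsurv", hidden=[8]), tr, seed=3,
                        opt_cfg=OptimizerConfig(epochs=40, patience=3),
                        valid_ds=va)
        assert len(m.valid_history) <= 40
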