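"""The 5-5-2 sigmoid network: initialization, forward pass, full-batch
backpropagation, scaling, and the repeated-trials protocol."""

import numpy as np
import pandas as pd
import pytest

import physioaffect as pa
from physioaffect.errors import ModelError
from physioaffect.mlp import _train_batch, sigmoid


def _flatten(w):
    parts = [w.W_hi.ravel(), w.W_oh.ravel()]
    if w.b_h is not None:
        parts += [w.b_h.ravel(), w.b_o.ravel()]
    return np.concatenate(parts)


def _unflatten(theta, config):
    H, I, O = config.n_hidden, config.n_in, config.n_out
    k = 0
    W_hi = theta[k:k + H * I].reshape(H, I); k += H * I
    W_oh = theta[k:k + O * H].reshape(O, H); k += O * H
    b_h = b_o = None
    if config.use_bias:
        b_h = theta[k:k + H]; k += H
        b_o = theta[k:k + O]; k += O
    return pa.MLPWeights(W_hi=W_hi, W_oh=W_oh, b_h=b_h, b_o=b_o)


def _batch_loss(theta, config, X, T):
    """Summed per-pattern loss E = sum_p 1/2 ||o_p - t_p||^2, the quantity
    whose gradient the accumulated backprop deltas must equal."""
    w = _unflatten(theta, config)
    o = pa.forward(w, X, config.input_sigmoid)
    return 0.5 * np.sum((o - T) ** 2)


class TestInit:
    def test_degenerate_range_gives_zero_weights(self, rng):
        cfg = pa.MLPConfig(init_low=0.0, init_high=0.0)
        w = pa.init_weights(cfg, rng)
        assert not _flatten(w).any()

    def test_uniform_moments(self):
        rng = np.random.default_rng(3)
        cfg = pa.MLPConfig()
        samples = np.concatenate([_flatten(pa.init_weights(cfg, rng)) for _ in range(300)])
        assert len(samples) >= 10_000
        assert abs(samples.mean() - 0.025) < 0.002
        assert samples.min() >= 0.0 and samples.max() < 0.05

    def test_same_seed_same_weights(self):
        cfg = pa.MLPConfig()
        w1 = pa.init_weights(cfg, np.random.default_rng(42))
        w2 = pa.init_weights(cfg, np.random.default_rng(42))
        np.testing.assert_array_equal(_flatten(w1), _flatten(w2))


class TestForward:
    def test_zero_network_outputs_scale_midpoint(self, rng):
        w = pa.MLPWeights(W_hi=np.zeros((5, 5)), W_oh=np.zeros((2, 5)),
                          b_h=np.zeros(5), b_o=np.zeros(2))
        o = pa.forward(w, rng.uniform(0, 1, 5))
        np.testing.assert_allclose(o, 0.5)
        np.testing.assert_allclose(pa.unit_to_rating(o), 5.0)

    def test_hand_computed_single_path(self):
        """One active hidden unit, no input squashing: o = sigmoid(2*sigmoid(0))."""
        W_hi = np.zeros((5, 5)); W_hi[0, 0] = 1.0
        W_oh = np.zeros((1, 5)); W_oh[0, 0] = 2.0
        w = pa.MLPWeights(W_hi=W_hi, W_oh=W_oh)
        o = pa.forward(w, np.zeros(5), input_sigmoid=False)
        assert o[0] == pytest.approx(sigmoid(2 * sigmoid(0.0)))
        assert o[0] == pytest.approx(0.7311, abs=1e-4)

    def test_monotone_in_positive_path_weight(self, rng):
        w = pa.MLPWeights(W_hi=rng.uniform(0, 1, (5, 5)), W_oh=rng.uniform(0, 1, (2, 5)))
        x = rng.uniform(0, 1, 5)
        o1 = pa.forward(w, x)
        w.W_oh[0, 0] += 0.5
        o2 = pa.forward(w, x)
        assert o2[0] >= o1[0]

    def test_out_of_range_input_warns_but_passes(self):
        w = pa.MLPWeights(W_hi=np.zeros((5, 5)), W_oh=np.zeros((2, 5)))
        with pytest.warns(UserWarning, match="outside"):
            pa.forward(w, np.array([1.5, 0, 0, 0, 0]))

    def test_shape_mismatch_is_an_error(self):
        w = pa.MLPWeights(W_hi=np.zeros((5, 5)), W_oh=np.zeros((2, 5)))
        with pytest.raises(ModelError, match="components"):
            pa.forward(w, np.zeros(4))


class TestScaling:
    def test_rating_map_round_trip(self):
        r = np.linspace(1, 9, 33)
        np.testing.assert_allclose(pa.unit_to_rating(pa.rating_to_unit(r)), r, atol=1e-12)

    def test_feature_scaling_uses_training_extremes(self, rng):
        X = rng.standard_normal((8, 5))
        sp = pa.ScalingParams.fit(X)
        Xs = sp.transform(X)
        np.testing.assert_allclose(Xs.min(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(Xs.max(axis=0), 1.0, atol=1e-12)
        # out-of-range test data is deliberately not clipped
        assert sp.transform(X.max(axis=0, keepdims=True) + 1.0).max() > 1.0

    def test_degenerate_feature_range_rejected(self):
        with pytest.raises(ModelError, match="degenerate"):
            pa.ScalingParams.fit(np.ones((8, 5)))


class TestGradients:
    @pytest.mark.parametrize("input_sigmoid,use_bias", [
        (True, True), (True, False), (False, True), (False, False)])
    def test_backprop_matches_central_finite_differences(self, input_sigmoid, use_bias):
        """>= 50 random configurations in total across the four variants; max
        absolute component difference below 1e-6 at epsilon 1e-6."""
        cfg = pa.MLPConfig(input_sigmoid=input_sigmoid, use_bias=use_bias,
                           learning_rate=1.0, max_epochs=1, trace_every=1)
        rng = np.random.default_rng(hash((input_sigmoid, use_bias)) % 2 ** 31)
        for _ in range(13):
            X = rng.uniform(0, 1, (4, 5))
            T = rng.uniform(0, 1, (4, 2))
            w0 = pa.MLPWeights(
                W_hi=rng.uniform(-1, 1, (5, 5)), W_oh=rng.uniform(-1, 1, (2, 5)),
                b_h=rng.uniform(-1, 1, 5) if use_bias else None,
                b_o=rng.uniform(-1, 1, 2) if use_bias else None)
            theta0 = _flatten(w0)
            # one epoch with lr=1: accumulated update == -grad of summed loss
            w1, _ = _train_batch(X, T, cfg, [pa.MLPWeights(
                W_hi=w0.W_hi.copy(), W_oh=w0.W_oh.copy(),
                b_h=None if w0.b_h is None else w0.b_h.copy(),
                b_o=None if w0.b_o is None else w0.b_o.copy())],
                np.random.default_rng(0))
            grad_bp = theta0 - _flatten(w1[0])
            eps = 1e-6
            grad_fd = np.empty_like(theta0)
            for i in range(len(theta0)):
                tp = theta0.copy(); tp[i] += eps
                tm = theta0.copy(); tm[i] -= eps
                grad_fd[i] = (_batch_loss(tp, cfg, X, T) - _batch_loss(tm, cfg, X, T)) / (2 * eps)
            assert np.max(np.abs(grad_bp - grad_fd)) < 1e-6


class TestTrain:
    def test_already_optimal_single_pair(self):
        """Zero-init network outputs (0.5, 0.5); with that exact target the
        loss starts at zero and training never moves."""
        cfg = pa.MLPConfig(init_low=0.0, init_high=0.0, max_epochs=50, trace_every=1)
        X = np.array([[0.2, 0.4, 0.6, 0.8, 1.0]])
        T = np.array([[0.5, 0.5]])
        w, trace = pa.train(X, T, cfg)
        assert trace.mse[0] == pytest.approx(0.0, abs=1e-30)
        assert trace.final_mse == pytest.approx(0.0, abs=1e-30)

    def test_trace_records_epoch_zero_and_final(self, rng):
        cfg = pa.MLPConfig(max_epochs=250, trace_every=100)
        X = rng.uniform(0, 1, (8, 5))
        T = rng.uniform(0.2, 0.8, (8, 2))
        _, trace = pa.train(X, T, cfg, rng)
        assert trace.epochs[0] == 0
        assert trace.epochs[-1] == 250
        assert trace.final_epoch == 250

    def test_loss_never_increases_from_start_to_end(self, rng):
        for seed in range(5):
            cfg = pa.MLPConfig(max_epochs=2000, seed=seed)
            X = np.random.default_rng(seed).uniform(0, 1, (8, 5))
            T = np.random.default_rng(seed + 100).uniform(0.1, 0.9, (8, 2))
            _, trace = pa.train(X, T, cfg)
            assert trace.final_mse <= trace.mse[0]


class TestRunTrials:
    def _features(self, rng):
        fm = pd.DataFrame(rng.uniform(-1, 1, (12, 5)), columns=list(pa.FEATURES),
                          index=[f"M{i}" for i in range(1, 13)])
        fm["mean_valence"] = rng.uniform(2, 8, 12)
        fm["mean_arousal"] = rng.uniform(2, 8, 12)
        return fm

    def test_overlapping_split_is_an_error(self, rng):
        with pytest.raises(ModelError, match="overlap"):
            pa.run_trials(self._features(rng), pa.MLPConfig(max_epochs=1),
                          train_excerpts=("M1", "M2"), test_excerpts=("M2", "M3"))

    def test_single_trial_matches_direct_train_call(self, rng):
        """The ensemble of one reproduces a plain train() with the same
        initial weights (presentation order cannot matter)."""
        fm = self._features(rng)
        cfg = pa.MLPConfig(n_trials=1, max_epochs=500, seed=9)
        ens = pa.run_trials(fm, cfg)
        init_rng = np.random.default_rng(np.random.SeedSequence(9).spawn(1)[0])
        Xtr = fm.loc[list(pa.DEFAULT_TRAIN_EXCERPTS), list(pa.FEATURES)].to_numpy()
        sp = pa.ScalingParams.fit(Xtr)
        Ttr = pa.rating_to_unit(fm.loc[list(pa.DEFAULT_TRAIN_EXCERPTS),
                                       ["mean_valence", "mean_arousal"]].to_numpy())
        w, _ = pa.train(sp.transform(Xtr), Ttr, cfg, init_rng)
        np.testing.assert_allclose(_flatten(w), _flatten(ens.weights[0]), atol=1e-12)

    def test_identical_initial_weights_give_zero_ensemble_spread(self, rng):
        fm = self._features(rng)
        cfg = pa.MLPConfig(max_epochs=300, n_trials=4)
        Xtr = fm.loc[list(pa.DEFAULT_TRAIN_EXCERPTS), list(pa.FEATURES)].to_numpy()
        sp = pa.ScalingParams.fit(Xtr)
        Ttr = pa.rating_to_unit(fm.loc[list(pa.DEFAULT_TRAIN_EXCERPTS),
                                       ["mean_valence", "mean_arousal"]].to_numpy())
        w0 = pa.init_weights(cfg, np.random.default_rng(5))
        clones = [pa.MLPWeights(W_hi=w0.W_hi.copy(), W_oh=w0.W_oh.copy(),
                                b_h=w0.b_h.copy(), b_o=w0.b_o.copy()) for _ in range(4)]
        weights, traces = _train_batch(sp.transform(Xtr), Ttr, cfg, clones,
                                       np.random.default_rng(0))
        for w in weights[1:]:
            np.testing.assert_array_equal(_flatten(w), _flatten(weights[0]))

    def test_predictions_live_strictly_inside_the_scale(self, trained_ensemble):
        p = trained_ensemble.predictions
        assert np.all(p > 1.0) and np.all(p < 9.0)

    def test_ensemble_is_seed_deterministic(self, rng):
        fm = self._features(rng)
        cfg = pa.MLPConfig(n_trials=3, max_epochs=200, seed=21)
        e1 = pa.run_trials(fm, cfg)
        e2 = pa.run_trials(fm, cfg)
        np.testing.assert_array_equal(e1.predictions, e2.predictions)
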