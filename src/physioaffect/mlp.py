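"""A small feedforward sigmoid network trained by full-batch backpropagation.

Architecture and protocol follow the study design exactly: 5 input units
(the physiological features, min-max scaled to [0, 1] and passed through a
logistic squashing function), one hidden layer of 5 logistic units (kept
equal to the input count as an overfitting guard), and 2 logistic outputs
(valence, arousal on a (0, 1) scale mapped back to 1-9).  Weights start
i.i.d. uniform on [0, 0.05); each epoch presents the 8 training patterns in
a randomized order, accumulates per-pattern backpropagation deltas of the
squared-error loss, and applies the summed update once at epoch end with a
learning rate of 0.1.  Training runs a fixed 80,000 epochs aiming for a
mean squared error below 0.02; the whole procedure is repeated for an
ensemble of 20 independently re-initialized networks.

The trainer is vectorized over ensemble trials (leading trial axis); a
single network is the one-trial case, so there is exactly one numerical
path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ModelError
from .features import FEATURES

RATING_RANGE = 8.0  # the 1-9 scale spans 8 units

DEFAULT_TRAIN_EXCERPTS = ("M1", "M2", "M4", "M5", "M7", "M8", "M10", "M11")
DEFAULT_TEST_EXCERPTS = ("M3", "M6", "M9", "M12")


def sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def rating_to_unit(r):
    """Map a 1-9 rating onto the network's (0, 1) output scale."""
    return (np.asarray(r, dtype=float) - 1.0) / RATING_RANGE


def unit_to_rating(o):
    """Inverse of :func:`rating_to_unit`."""
    return 8.0 * np.asarray(o, dtype=float) + 1.0


@dataclass(frozen=True)
class MLPConfig:
    n_in: int = 5
    n_hidden: int = 5
    n_out: int = 2
    learning_rate: float = 0.1
    max_epochs: int = 80_000
    mse_target: float = 0.02
    init_low: float = 0.0
    init_high: float = 0.05
    input_sigmoid: bool = True
    use_bias: bool = True
    n_trials: int = 20
    seed: int = 0
    trace_every: int = 100

    def __post_init__(self) -> None:
        if self.n_hidden != self.n_in:
            raise ModelError("n_hidden must equal n_in (overfitting guard)")
        if self.learning_rate <= 0:
            raise ModelError("learning_rate must be positive")
        if not self.init_high >= self.init_low >= 0:
            raise ModelError("need init_high >= init_low >= 0")


@dataclass
class MLPWeights:
    """Input-to-hidden (W_hi) and hidden-to-output (W_oh) weights."""

    W_hi: np.ndarray           # (n_hidden, n_in)
    W_oh: np.ndarray           # (n_out, n_hidden)
    b_h: np.ndarray | None = None
    b_o: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name, w in (("W_hi", self.W_hi), ("W_oh", self.W_oh),
                        ("b_h", self.b_h), ("b_o", self.b_o)):
            if w is not None and not np.all(np.isfinite(w)):
                raise ModelError(f"non-finite values in {name}")


@dataclass(frozen=True)
class ScalingParams:
    """Per-feature min/max over the training excerpts, for [0, 1] scaling."""

    feature_min: np.ndarray
    feature_max: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "ScalingParams":
        lo = X.min(axis=0)
        hi = X.max(axis=0)
        if np.any(hi <= lo):
            raise ModelError("degenerate feature range: max <= min")
        return cls(feature_min=lo, feature_max=hi)

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Scale with the training min/max; values outside the training range
        map outside [0, 1] and are deliberately not clipped."""
        return (np.asarray(X, dtype=float) - self.feature_min) / (
            self.feature_max - self.feature_min)


@dataclass
class TrainingTrace:
    epochs: np.ndarray
    mse: np.ndarray
    final_epoch: int
    converged: bool

    @property
    def final_mse(self) -> float:
        return float(self.mse[-1])


@dataclass
class EnsembleResult:
    """Outcome of the repeated-trials protocol."""

    weights: list[MLPWeights]
    traces: list[TrainingTrace]
    predictions: np.ndarray          # (n_trials, n_test, 2) on the 1-9 scale
    mean_predictions: np.ndarray     # (n_test, 2)
    test_excerpts: list[str]
    scaling: ScalingParams


def init_weights(config: MLPConfig, rng: np.random.Generator) -> MLPWeights:
    """Uniform [init_low, init_high) initialization of all weights/biases."""
    lo, hi = config.init_low, config.init_high
    w = MLPWeights(
        W_hi=rng.uniform(lo, hi, (config.n_hidden, config.n_in)),
        W_oh=rng.uniform(lo, hi, (config.n_out, config.n_hidden)),
    )
    if config.use_bias:
        w.b_h = rng.uniform(lo, hi, config.n_hidden)
        w.b_o = rng.uniform(lo, hi, config.n_out)
    return w


def forward(weights: MLPWeights, x: np.ndarray, input_sigmoid: bool = True) -> np.ndarray:
    """Deterministic forward pass; accepts a single pattern or an (n, n_in)
    batch and returns outputs in (0, 1)."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    if X.shape[1] != weights.W_hi.shape[1]:
        raise ModelError(
            f"input has {X.shape[1]} components, expected {weights.W_hi.shape[1]}")
    if np.any((X < 0) | (X > 1)):
        warnings.warn("input components outside [0, 1] (training-range shift); "
                      "not clipped", stacklevel=2)
    a = sigmoid(X) if input_sigmoid else X
    bh = weights.b_h if weights.b_h is not None else 0.0
    bo = weights.b_o if weights.b_o is not None else 0.0
    h = sigmoid(a @ weights.W_hi.T + bh)
    o = sigmoid(h @ weights.W_oh.T + bo)
    return o[0] if single else o


def _train_batch(X: np.ndarray, T: np.ndarray, config: MLPConfig,
                 weight_sets: list[MLPWeights], rng: np.random.Generator
                 ) -> tuple[list[MLPWeights], list[TrainingTrace]]:
    """Full-batch gradient descent on squared error for a stack of networks.

    Per epoch: present all patterns (randomized order), accumulate the
    per-pattern deltas of E_p = 1/2 ||o - t||^2, apply the summed update once.
    Reported MSE is the mean of (o - t)^2 over patterns and outputs.
    """
    n_trials = len(weight_sets)
    N = X.shape[0]
    lr = config.learning_rate
    use_bias = config.use_bias

    Whi = np.stack([w.W_hi for w in weight_sets])            # (T, H, I)
    Woh = np.stack([w.W_oh for w in weight_sets])            # (T, O, H)
    bh = (np.stack([w.b_h for w in weight_sets]) if use_bias
          else np.zeros((n_trials, config.n_hidden)))
    bo = (np.stack([w.b_o for w in weight_sets]) if use_bias
          else np.zeros((n_trials, config.n_out)))

    A = sigmoid(X) if config.input_sigmoid else np.asarray(X, dtype=float)
    rec_epochs: list[int] = []
    rec_mse: list[np.ndarray] = []

    def _mse(err: np.ndarray) -> np.ndarray:
        return (err ** 2).mean(axis=(1, 2))

    mse = None
    for epoch in range(config.max_epochs + 1):
        order = rng.permutation(N)  # order is immaterial under summed updates
        Ao = A[order]
        To = T[order]
        h = sigmoid(np.einsum("thi,ni->tnh", Whi, Ao) + bh[:, None, :])
        o = sigmoid(np.einsum("toh,tnh->tno", Woh, h) + bo[:, None, :])
        err = o - To[None, :, :]
        mse = _mse(err)
        if not np.all(np.isfinite(mse)):
            raise ModelError(f"non-finite training loss at epoch {epoch}")
        if epoch % config.trace_every == 0 or epoch == config.max_epochs:
            rec_epochs.append(epoch)
            rec_mse.append(mse.copy())
        if epoch == config.max_epochs:
            break
        do = err * o * (1.0 - o)
        dWoh = np.einsum("tno,tnh->toh", do, h)
        dh = np.einsum("toh,tno->tnh", Woh, do) * h * (1.0 - h)
        dWhi = np.einsum("tnh,ni->thi", dh, Ao)
        Whi -= lr * dWhi
        Woh -= lr * dWoh
        if use_bias:
            bo -= lr * do.sum(axis=1)
            bh -= lr * dh.sum(axis=1)

    out_weights = []
    for k in range(n_trials):
        out_weights.append(MLPWeights(
            W_hi=Whi[k].copy(), W_oh=Woh[k].copy(),
            b_h=bh[k].copy() if use_bias else None,
            b_o=bo[k].copy() if use_bias else None))
    epochs_arr = np.array(rec_epochs)
    mse_mat = np.stack(rec_mse)                              # (n_rec, T)
    traces = [TrainingTrace(epochs=epochs_arr.copy(), mse=mse_mat[:, k].copy(),
                            final_epoch=int(epochs_arr[-1]),
                            converged=bool(mse_mat[-1, k] < config.mse_target))
              for k in range(n_trials)]
    return out_weights, traces


def train(X: np.ndarray, T: np.ndarray, config: MLPConfig,
          rng: np.random.Generator | None = None) -> tuple[MLPWeights, TrainingTrace]:
    """Train one network on scaled inputs ``X`` (n, 5) and targets ``T`` (n, 2),
    both in [0, 1].  Returns the final weights and the MSE trace."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    w0 = init_weights(config, rng)
    weights, traces = _train_batch(np.asarray(X, float), np.asarray(T, float),
                                   config, [w0], rng)
    return weights[0], traces[0]


def run_trials(features: pd.DataFrame, config: MLPConfig | None = None,
               train_excerpts: tuple[str, ...] = DEFAULT_TRAIN_EXCERPTS,
               test_excerpts: tuple[str, ...] = DEFAULT_TEST_EXCERPTS) -> EnsembleResult:
    """The repeated-trials protocol: ``config.n_trials`` independently
    re-initialized networks trained on the training excerpts and evaluated on
    the held-out test excerpts.

    ``features`` is the excerpt x feature matrix (index: excerpt ids; columns
    scl, hr, resp, zyg, corr, mean_valence, mean_arousal).  Test inputs are
    scaled with the training-set min/max; predictions are inverse-mapped to
    the 1-9 scale and averaged across trials.
    """
    config = config if config is not None else MLPConfig()
    overlap = set(train_excerpts) & set(test_excerpts)
    if overlap:
        raise ModelError(f"train/test excerpt overlap: {sorted(overlap)}")
    missing = [e for e in (*train_excerpts, *test_excerpts) if e not in features.index]
    if missing:
        raise ModelError(f"excerpts missing from feature matrix: {missing}")

    Xtr = features.loc[list(train_excerpts), list(FEATURES)].to_numpy(dtype=float)
    Xte = features.loc[list(test_excerpts), list(FEATURES)].to_numpy(dtype=float)
    Ttr = rating_to_unit(
        features.loc[list(train_excerpts), ["mean_valence", "mean_arousal"]].to_numpy())

    scaling = ScalingParams.fit(Xtr)
    Xtr_s = scaling.transform(Xtr)
    Xte_s = scaling.transform(Xte)

    root = np.random.SeedSequence(config.seed)
    init_rngs = [np.random.default_rng(s) for s in root.spawn(config.n_trials)]
    w0 = [init_weights(config, r) for r in init_rngs]
    order_rng = np.random.default_rng(root.spawn(1)[0])
    weights, traces = _train_batch(Xtr_s, Ttr, config, w0, order_rng)

    preds = np.empty((config.n_trials, len(test_excerpts), config.n_out))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # test inputs may leave the training range
        for k, w in enumerate(weights):
            preds[k] = unit_to_rating(forward(w, Xte_s, config.input_sigmoid))
    return EnsembleResult(weights=weights, traces=traces, predictions=preds,
                          mean_predictions=preds.mean(axis=0),
                          test_excerpts=list(test_excerpts), scaling=scaling)
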