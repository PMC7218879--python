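"""From-scratch two-hidden-layer classifier: sigmoid hiddens, softmax output.

Weights are stored with an explicit bias row (row 0) so that layer
pre-activations are plain sums from index 0 with fixed units
``x_0 = h_0 = h'_0 = 1``.  Gradients are derived analytically:

* output deltas: ``o_r - t_r`` (softmax + cross-entropy),
* hidden deltas: ``h (1 - h) * (downstream deltas @ downstream weights)``,

and training is plain gradient descent (full-batch mean gradient by
default, per-sample stochastic mode available) with three stopping rules:
epoch cap, vanishing gradient, and validation-loss patience.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "NetworkConfig",
    "NetworkParameters",
    "ForwardTrace",
    "Gradients",
    "TrainingReport",
    "ClassProbabilities",
    "init_parameters",
    "forward",
    "cross_entropy",
    "backward",
    "apply_update",
    "train",
    "predict_proba",
]

LOG_CLAMP = 1e-300


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture and training hyperparameters.

    Defaults follow the reference setting: 93-dimensional input, hidden
    layers of 85 and 80 units, learning rate 0.01, at most 1000 epochs,
    minimum gradient 1e-6, and early stopping after 5 consecutive
    validation-loss increases.
    """

    output_dim: int
    input_dim: int = 93
    hidden1: int = 85
    hidden2: int = 80
    learning_rate: float = 0.01
    max_epochs: int = 1000
    min_gradient: float = 1e-6
    patience: int = 5
    validation_fraction: float = 0.15
    init_scale: float = 0.1
    seed: int = 0
    batch_mode: Literal["full", "stochastic"] = "full"

    def __post_init__(self) -> None:
        for name in ("input_dim", "hidden1", "hidden2", "output_dim"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0 < self.validation_fraction < 1:
            raise ValueError("validation_fraction must be in (0, 1)")
        if self.max_epochs < 0:
            raise ValueError("max_epochs must be >= 0")
        if self.batch_mode not in ("full", "stochastic"):
            raise ValueError(f"unknown batch_mode {self.batch_mode!r}")


@dataclass
class NetworkParameters:
    """Weight matrices with bias rows (row 0) and the class vocabulary.

    Shapes: ``w (input_dim+1, P)``, ``w_prime (P+1, Q)``,
    ``w_dprime (Q+1, R)``.
    """

    w: np.ndarray
    w_prime: np.ndarray
    w_dprime: np.ndarray
    class_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.w.shape[1] + 1 != self.w_prime.shape[0]:
            raise ValueError("w/w_prime shapes inconsistent")
        if self.w_prime.shape[1] + 1 != self.w_dprime.shape[0]:
            raise ValueError("w_prime/w_dprime shapes inconsistent")
        for m in (self.w, self.w_prime, self.w_dprime):
            if not np.isfinite(m).all():
                raise ValueError("non-finite weight")
        if self.class_names and len(self.class_names) != self.w_dprime.shape[1]:
            raise ValueError("class_names length must equal output_dim")

    @property
    def input_dim(self) -> int:
        return self.w.shape[0] - 1

    @property
    def output_dim(self) -> int:
        return self.w_dprime.shape[1]

    def copy(self) -> "NetworkParameters":
        return NetworkParameters(
            self.w.copy(), self.w_prime.copy(), self.w_dprime.copy(),
            self.class_names,
        )


@dataclass
class ForwardTrace:
    """Activations of one forward pass, bias units included."""

    x: np.ndarray        # (input_dim+1,), x[0] = 1
    h: np.ndarray        # (P+1,), h[0] = 1
    h_prime: np.ndarray  # (Q+1,), h_prime[0] = 1
    o: np.ndarray        # (R,), sums to 1


@dataclass
class Gradients:
    """Loss gradients w.r.t. every weight plus the layer error terms."""

    d_w: np.ndarray
    d_w_prime: np.ndarray
    d_w_dprime: np.ndarray
    delta_r: np.ndarray
    delta_q: np.ndarray
    delta_p: np.ndarray

    def max_abs(self) -> float:
        return max(
            float(np.abs(self.d_w).max()),
            float(np.abs(self.d_w_prime).max()),
            float(np.abs(self.d_w_dprime).max()),
        )


@dataclass
class TrainingReport:
    epochs_run: int
    stop_reason: Literal["max_epochs", "min_gradient", "patience"]
    train_loss_trace: list[float] = field(default_factory=list)
    validation_loss_trace: list[float] = field(default_factory=list)


@dataclass
class ClassProbabilities:
    class_names: tuple[str, ...]
    probabilities: np.ndarray

    def top_class(self) -> str:
        return self.class_names[int(np.argmax(self.probabilities))]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _softmax(z: np.ndarray) -> np.ndarray:
    e = np.exp(z - z.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


def init_parameters(config: NetworkConfig) -> NetworkParameters:
    """Seeded uniform(-init_scale, +init_scale) weights, bias rows included."""
    rng = np.random.default_rng(config.seed)
    scale = config.init_scale

    def draw(shape):
        if scale == 0:
            return np.zeros(shape)
        return rng.uniform(-scale, scale, size=shape)

    return NetworkParameters(
        w=draw((config.input_dim + 1, config.hidden1)),
        w_prime=draw((config.hidden1 + 1, config.hidden2)),
        w_dprime=draw((config.hidden2 + 1, config.output_dim)),
    )


def _with_bias(a: np.ndarray) -> np.ndarray:
    if a.ndim == 1:
        return np.concatenate(([1.0], a))
    return np.hstack((np.ones((a.shape[0], 1)), a))


def forward(params: NetworkParameters, feature: np.ndarray) -> ForwardTrace:
    """Single-sample forward pass; softmax computed with max-subtraction."""
    feature = np.asarray(feature, dtype=np.float64).ravel()
    if feature.size != params.input_dim:
        raise ValueError(
            f"feature length {feature.size} != input_dim {params.input_dim}"
        )
    x = _with_bias(feature)
    h = _with_bias(_sigmoid(x @ params.w))
    h_prime = _with_bias(_sigmoid(h @ params.w_prime))
    o = _softmax(h_prime @ params.w_dprime)
    return ForwardTrace(x=x, h=h, h_prime=h_prime, o=o)


def cross_entropy(o: np.ndarray, target_index: int) -> float:
    """One-hot cross-entropy ``-ln(o[target])``, clamped to avoid -ln 0."""
    o = np.asarray(o, dtype=np.float64)
    if not 0 <= target_index < o.size:
        raise IndexError(f"target index {target_index} out of range")
    return float(-np.log(max(o[target_index], LOG_CLAMP)))


def backward(
    params: NetworkParameters, trace: ForwardTrace, target_index: int
) -> Gradients:
    """Analytic gradients of the cross-entropy loss, bias rows included."""
    t = np.zeros(params.output_dim)
    t[target_index] = 1.0
    delta_r = trace.o - t
    d_w_dprime = np.outer(trace.h_prime, delta_r)
    hq = trace.h_prime[1:]
    delta_q = hq * (1.0 - hq) * (params.w_dprime[1:] @ delta_r)
    d_w_prime = np.outer(trace.h, delta_q)
    hp = trace.h[1:]
    delta_p = hp * (1.0 - hp) * (params.w_prime[1:] @ delta_q)
    d_w = np.outer(trace.x, delta_p)
    return Gradients(
        d_w=d_w, d_w_prime=d_w_prime, d_w_dprime=d_w_dprime,
        delta_r=delta_r, delta_q=delta_q, delta_p=delta_p,
    )


def apply_update(
    params: NetworkParameters, grads: Gradients, learning_rate: float
) -> NetworkParameters:
    """Gradient-descent step ``w ← w − η ∂E/∂w`` on all three matrices."""
    return NetworkParameters(
        w=params.w - learning_rate * grads.d_w,
        w_prime=params.w_prime - learning_rate * grads.d_w_prime,
        w_dprime=params.w_dprime - learning_rate * grads.d_w_dprime,
        class_names=params.class_names,
    )


def _batch_forward(params: NetworkParameters, X: np.ndarray):
    Xb = _with_bias(X)
    H = _with_bias(_sigmoid(Xb @ params.w))
    H2 = _with_bias(_sigmoid(H @ params.w_prime))
    O = _softmax(H2 @ params.w_dprime)
    return Xb, H, H2, O


def _batch_loss_grads(params: NetworkParameters, X: np.ndarray, T: np.ndarray):
    """Mean cross-entropy and mean gradients over the batch."""
    Xb, H, H2, O = _batch_forward(params, X)
    n = X.shape[0]
    loss = float(-(np.log(np.maximum(O, LOG_CLAMP)) * T).sum() / n)
    dOut = (O - T) / n
    g_dprime = H2.T @ dOut
    dq = H2[:, 1:] * (1.0 - H2[:, 1:]) * (dOut @ params.w_dprime[1:].T)
    g_prime = H.T @ dq
    dp = H[:, 1:] * (1.0 - H[:, 1:]) * (dq @ params.w_prime[1:].T)
    g_w = Xb.T @ dp
    return loss, (g_w, g_prime, g_dprime)


def _batch_mean_loss(params: NetworkParameters, X: np.ndarray, T: np.ndarray) -> float:
    _, _, _, O = _batch_forward(params, X)
    return float(-(np.log(np.maximum(O, LOG_CLAMP)) * T).sum() / X.shape[0])


def _stratified_split(
    y: np.ndarray, fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray] | None:
    """Per-class shuffled split; None if any class would be emptied."""
    train_idx, val_idx = [], []
    for c in np.unique(y):
        idx = np.flatnonzero(y == c)
        idx = idx[rng.permutation(idx.size)]
        n_val = int(round(fraction * idx.size))
        if n_val == 0 or n_val == idx.size:
            return None
        val_idx.append(idx[:n_val])
        train_idx.append(idx[n_val:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(val_idx))


def train(
    X: np.ndarray,
    y: Sequence[int],
    config: NetworkConfig,
    class_names: Sequence[str] = (),
) -> tuple[NetworkParameters, TrainingReport]:
    """Train on labeled features; returns parameters and a stopping report.

    A stratified validation split (``config.validation_fraction``, seeded)
    monitors generalization; if the split would empty a class, training
    falls back to no validation.  Stops at the epoch cap, when the largest
    absolute gradient entry drops below ``min_gradient``, or when the
    validation loss worsens ``patience`` epochs in a row (best-validation
    weights are returned).
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X must be (n_samples, input_dim) matching y")
    if X.shape[1] != config.input_dim:
        raise ValueError(
            f"feature dim {X.shape[1]} != config.input_dim {config.input_dim}"
        )
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training needs at least 2 classes")
    if y.min() < 0 or y.max() >= config.output_dim:
        raise ValueError("labels out of range for output_dim")

    rng = np.random.default_rng(config.seed)
    params = init_parameters(config)
    params.class_names = tuple(class_names)

    split = _stratified_split(y, config.validation_fraction, rng)
    if split is None:
        import logging

        logging.getLogger(__name__).warning(
            "validation split would empty a class; training without validation"
        )
        tr_idx = np.arange(y.size)
        val_idx = None
    else:
        tr_idx, val_idx = split

    T_all = np.zeros((y.size, config.output_dim))
    T_all[np.arange(y.size), y] = 1.0
    X_tr, T_tr = X[tr_idx], T_all[tr_idx]
    if val_idx is not None:
        X_val, T_val = X[val_idx], T_all[val_idx]

    train_trace: list[float] = []
    val_trace: list[float] = []
    best_params = params.copy()
    best_val = np.inf
    bad_streak = 0
    stop_reason = "max_epochs"
    epochs_run = 0

    for _ in range(config.max_epochs):
        if config.batch_mode == "full":
            loss, (g_w, g_p, g_dp) = _batch_loss_grads(params, X_tr, T_tr)
            grad_max = max(
                float(np.abs(g_w).max()),
                float(np.abs(g_p).max()),
                float(np.abs(g_dp).max()),
            )
            params = NetworkParameters(
                w=params.w - config.learning_rate * g_w,
                w_prime=params.w_prime - config.learning_rate * g_p,
                w_dprime=params.w_dprime - config.learning_rate * g_dp,
                class_names=params.class_names,
            )
        else:
            order = rng.permutation(X_tr.shape[0])
            loss_sum = 0.0
            grad_max = 0.0
            for i in order:
                trace = forward(params, X_tr[i])
                ti = int(np.argmax(T_tr[i]))
                loss_sum += cross_entropy(trace.o, ti)
                grads = backward(params, trace, ti)
                grad_max = max(grad_max, grads.max_abs())
                params = apply_update(params, grads, config.learning_rate)
            loss = loss_sum / X_tr.shape[0]

        epochs_run += 1
        train_trace.append(loss)
        if val_idx is not None:
            val_loss = _batch_mean_loss(params, X_val, T_val)
            val_trace.append(val_loss)
            if val_loss < best_val:
                best_val = val_loss
                best_params = params.copy()
                bad_streak = 0
            else:
                bad_streak += 1
                if bad_streak >= config.patience:
                    stop_reason = "patience"
                    params = best_params
                    break
        if grad_max < config.min_gradient:
            stop_reason = "min_gradient"
            break

    report = TrainingReport(
        epochs_run=epochs_run,
        stop_reason=stop_reason,
        train_loss_trace=train_trace,
        validation_loss_trace=val_trace,
    )
    return params, report


def predict_proba(
    params: NetworkParameters, feature: np.ndarray
) -> ClassProbabilities:
    """Class probabilities for one feature vector."""
    trace = forward(params, feature)
    names = params.class_names or tuple(
        f"class{i}" for i in range(params.output_dim)
    )
    return ClassProbabilities(class_names=names, probabilities=trace.o)
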