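"""Minimal dense feed-forward network machinery.

Every network in the pipeline is a chain of fully connected layers computing
y = F(W x + b), with F either ReLU or identity. This module provides the
pieces the higher-level models compose:

* He-uniform initialization (weights ~ U[-L, L], L = sqrt(6 / fan_in); zero
  biases), suited to ReLU units;
* a forward pass, plus a cached forward / backward pair for exact gradients
  of the mean-squared-error loss;
* mini-batch Adam training with optional patience-based early stopping on a
  validation set;
* bit-exact parameter serialization (npz archive with a JSON manifest).

Training is deterministic given (seed, batch_size): the batch order is
reshuffled each epoch from a generator owned by the run.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .exceptions import NumericalError, ValidationError

ACTIVATIONS = ("relu", "linear")


@dataclass
class Layer:
    """One dense layer: weights (fan_out x fan_in), bias (fan_out), activation tag."""

    W: np.ndarray
    b: np.ndarray
    activation: str = "relu"

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.W.ndim != 2 or self.b.ndim != 1 or self.W.shape[0] != self.b.shape[0]:
            raise ValidationError(
                f"layer shapes inconsistent: W {self.W.shape}, b {self.b.shape}"
            )
        if self.activation not in ACTIVATIONS:
            raise ValidationError(f"unknown activation {self.activation!r}")

    @property
    def fan_in(self) -> int:
        return self.W.shape[1]

    @property
    def fan_out(self) -> int:
        return self.W.shape[0]


@dataclass
class MLPParams:
    """An ordered chain of dense layers; consecutive dims must match."""

    layers: list[Layer]

    def __post_init__(self) -> None:
        for prev, nxt in zip(self.layers, self.layers[1:]):
            if prev.fan_out != nxt.fan_in:
                raise ValidationError(
                    f"layer dims do not chain: {prev.fan_out} -> {nxt.fan_in}"
                )
        for i, layer in enumerate(self.layers):
            if not (np.isfinite(layer.W).all() and np.isfinite(layer.b).all()):
                raise ValidationError(f"non-finite parameters in layer {i}")

    @property
    def input_dim(self) -> int:
        return self.layers[0].fan_in

    @property
    def output_dim(self) -> int:
        return self.layers[-1].fan_out

    @property
    def dims(self) -> list[int]:
        return [self.input_dim] + [layer.fan_out for layer in self.layers]

    def n_params(self) -> int:
        return sum(layer.W.size + layer.b.size for layer in self.layers)

    def copy(self) -> "MLPParams":
        return MLPParams(
            [Layer(l.W.copy(), l.b.copy(), l.activation) for l in self.layers]
        )


def he_uniform_init(
    layer_dims: list[int], seed: int, activations: list[str] | None = None
) -> MLPParams:
    """Initialize a chain of dense layers from He's uniform distribution.

    Weights of a layer with fan_in f are drawn from U[-L, L] with
    L = sqrt(6 / f); biases are zero. ``activations`` defaults to ReLU on
    every layer; pass an explicit list (e.g. ending in ``linear``) otherwise.
    Deterministic given ``seed``.
    """
    if len(layer_dims) < 2:
        raise ValidationError("need at least input and output dims")
    if any(d < 1 for d in layer_dims):
        raise ValidationError(f"layer dims must be >= 1, got {layer_dims}")
    if activations is None:
        activations = ["relu"] * (len(layer_dims) - 1)
    if len(activations) != len(layer_dims) - 1:
        raise ValidationError("one activation per layer required")
    rng = np.random.default_rng(seed)
    layers = []
    for fan_in, fan_out, act in zip(layer_dims, layer_dims[1:], activations):
        limit = math.sqrt(6.0 / fan_in)
        W = rng.uniform(-limit, limit, size=(fan_out, fan_in))
        layers.append(Layer(W, np.zeros(fan_out), act))
    return MLPParams(layers)


def _activate(z: np.ndarray, activation: str) -> np.ndarray:
    if activation == "relu":
        return np.maximum(z, 0.0)
    return z


def forward(params: MLPParams, x: np.ndarray) -> np.ndarray:
    """Forward pass; ``x`` is a vector or a (n_samples x input_dim) batch."""
    single = np.ndim(x) == 1
    h = np.atleast_2d(np.asarray(x, dtype=float))
    if h.shape[1] != params.input_dim:
        raise ValidationError(
            f"input dim {h.shape[1]} does not match network input {params.input_dim}"
        )
    for layer in params.layers:
        h = _activate(h @ layer.W.T + layer.b, layer.activation)
    return h[0] if single else h


def forward_cached(params: MLPParams, x: np.ndarray):
    """Forward pass keeping per-layer inputs and pre-activations for backprop."""
    h = np.atleast_2d(np.asarray(x, dtype=float))
    if h.shape[1] != params.input_dim:
        raise ValidationError(
            f"input dim {h.shape[1]} does not match network input {params.input_dim}"
        )
    caches = []
    for layer in params.layers:
        z = h @ layer.W.T + layer.b
        caches.append((h, z))
        h = _activate(z, layer.activation)
    return h, caches


def backward(params: MLPParams, caches, grad_out: np.ndarray):
    """Backpropagate a loss gradient w.r.t. the network output.

    Returns ``(grads, grad_x)`` where ``grads`` is a list of (dW, db) per
    layer and ``grad_x`` the gradient w.r.t. the network input batch.
    """
    g = np.asarray(grad_out, dtype=float)
    grads: list[tuple[np.ndarray, np.ndarray]] = [None] * len(params.layers)
    for i in range(len(params.layers) - 1, -1, -1):
        layer = params.layers[i]
        h_in, z = caches[i]
        if layer.activation == "relu":
            g = g * (z > 0)
        grads[i] = (g.T @ h_in, g.sum(axis=0))
        g = g @ layer.W
    return grads, g


def mse(pred: np.ndarray, truth: np.ndarray) -> float:
    return float(np.mean((np.asarray(pred) - np.asarray(truth)) ** 2))


@dataclass(frozen=True)
class TrainConfig:
    """Adam + loop settings. Defaults: lr 1e-3, betas (0.9, 0.999), eps 1e-8."""

    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    adam_eps: float = 1e-8
    batch_size: int = 32
    max_epochs: int = 100
    patience: int | None = None
    restore_best: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValidationError("batch_size must be >= 1")
        if self.patience is not None and self.patience < 1:
            raise ValidationError("patience must be >= 1 when set")


@dataclass
class TrainHistory:
    """Per-epoch losses; ``stopped_epoch`` is the 1-based last completed epoch."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    stopped_epoch: int = 0


class Adam:
    """Adaptive-moment optimizer over a flat list of parameter arrays."""

    def __init__(self, cfg: TrainConfig):
        self.cfg = cfg
        self.t = 0
        self.m: list[np.ndarray] | None = None
        self.v: list[np.ndarray] | None = None

    def step(self, arrays: list[np.ndarray], grads: list[np.ndarray]) -> None:
        """Update ``arrays`` in place from matching gradient arrays."""
        if self.m is None:
            self.m = [np.zeros_like(a) for a in arrays]
            self.v = [np.zeros_like(a) for a in arrays]
        cfg = self.cfg
        self.t += 1
        bc1 = 1.0 - cfg.beta1**self.t
        bc2 = 1.0 - cfg.beta2**self.t
        for a, g, m, v in zip(arrays, grads, self.m, self.v):
            m *= cfg.beta1
            m += (1.0 - cfg.beta1) * g
            v *= cfg.beta2
            v += (1.0 - cfg.beta2) * g * g
            a -= cfg.learning_rate * (m / bc1) / (np.sqrt(v / bc2) + cfg.adam_eps)


class EarlyStopping:
    """Patience-based stop on a validation-loss stream.

    Any strict decrease resets the counter. After ``patience`` consecutive
    non-improving epochs the *next* non-improving epoch triggers the stop, so
    with patience 3 and the best loss at epoch 1 training halts at epoch 5
    (1 best + 3 non-improving + the detection epoch).
    """

    def __init__(self, patience: int):
        if patience < 1:
            raise ValidationError("patience must be >= 1")
        self.patience = patience
        self.best = math.inf
        self.wait = 0
        self.stopped_epoch = 0

    def update(self, loss: float, epoch: int) -> bool:
        """Feed the validation loss of ``epoch`` (1-based); True means stop now."""
        if loss < self.best:
            self.best = loss
            self.wait = 0
            return False
        if self.wait >= self.patience:
            self.stopped_epoch = epoch
            return True
        self.wait += 1
        return False


def _check_finite(name: str, arr: np.ndarray) -> None:
    if not np.isfinite(arr).all():
        raise ValidationError(f"{name} contains NaN or Inf")


def train_mse(
    params: MLPParams,
    X: np.ndarray,
    Y: np.ndarray,
    cfg: TrainConfig,
    validation: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[MLPParams, TrainHistory]:
    """Train a dense chain against mean squared error with mini-batch Adam.

    ``X``/``Y`` are samples x dims. The input ``params`` object is not
    modified; a trained copy is returned. With ``cfg.patience`` set and a
    validation pair supplied, training halts once the validation loss has
    failed to improve for ``patience`` consecutive epochs (see
    :class:`EarlyStopping`); ``cfg.restore_best`` additionally rolls back to
    the parameters of the best validation epoch.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[0] != Y.shape[0]:
        raise ValidationError("X and Y row counts differ")
    _check_finite("X", X)
    _check_finite("Y", Y)
    if validation is not None:
        Xv = np.atleast_2d(np.asarray(validation[0], dtype=float))
        Yv = np.atleast_2d(np.asarray(validation[1], dtype=float))
        _check_finite("validation X", Xv)
        _check_finite("validation Y", Yv)

    params = params.copy()
    history = TrainHistory()
    if cfg.max_epochs == 0:
        return params, history

    arrays = [a for layer in params.layers for a in (layer.W, layer.b)]
    adam = Adam(cfg)
    rng = np.random.default_rng(cfg.seed)
    stopper = EarlyStopping(cfg.patience) if (cfg.patience and validation is not None) else None
    best_snapshot = None
    n = X.shape[0]

    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            pred, caches = forward_cached(params, X[idx])
            grad = (2.0 / pred.size) * (pred - Y[idx])
            grads, _ = backward(params, caches, grad)
            flat = [g for gw_gb in grads for g in gw_gb]
            adam.step(arrays, flat)
        train_loss = mse(forward(params, X), Y)
        if not math.isfinite(train_loss):
            raise NumericalError(f"training loss became non-finite at epoch {epoch}")
        history.train_loss.append(train_loss)
        history.stopped_epoch = epoch
        if validation is not None:
            val_loss = mse(forward(params, Xv), Yv)
            if not math.isfinite(val_loss):
                raise NumericalError(f"validation loss became non-finite at epoch {epoch}")
            history.val_loss.append(val_loss)
            if cfg.restore_best and (best_snapshot is None or val_loss < best_snapshot[0]):
                best_snapshot = (val_loss, params.copy())
            if stopper is not None and stopper.update(val_loss, epoch):
                break
    if cfg.restore_best and best_snapshot is not None:
        params = best_snapshot[1]
    return params, history


def save_params(params: MLPParams, path) -> None:
    """Serialize to a single npz archive with a JSON manifest of layer specs."""
    manifest = {
        "dims": params.dims,
        "activations": [layer.activation for layer in params.layers],
    }
    arrays = {}
    for i, layer in enumerate(params.layers):
        arrays[f"W{i}"] = layer.W
        arrays[f"b{i}"] = layer.b
    arrays["manifest"] = np.frombuffer(json.dumps(manifest).encode("utf-8"), dtype=np.uint8)
    np.savez(path, **arrays)


def load_params(path) -> MLPParams:
    """Inverse of :func:`save_params`; bit-exact round-trip."""
    with np.load(path) as archive:
        manifest = json.loads(bytes(archive["manifest"]).decode("utf-8"))
        layers = [
            Layer(archive[f"W{i}"], archive[f"b{i}"], act)
            for i, act in enumerate(manifest["activations"])
        ]
    return MLPParams(layers)
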