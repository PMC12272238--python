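"""Multi-output feedforward network trained with a masked MSE loss.

The network maps an FC feature vector to simultaneous predictions of all of
a source dataset's phenotypes (one output node per phenotype).  Missing
phenotype entries are excluded from the loss exactly: the per-cell squared
error is multiplied by the observedness mask and normalized by the number of
observed cells, so an entirely masked column contributes zero gradient.

Architecture and training defaults (all overridable via :class:`MLPConfig`):
three ReLU hidden layers of 256/128/64 units, inverted dropout 0.3 on the
hidden activations, Adam with learning rate 1e-3, batch size 128, at most
100 epochs, early stopping when the validation loss has not improved for 10
consecutive epochs (the best-validation weights are restored).  Training is
deterministic given a seed; inference never applies dropout and is
bit-reproducible.

The implementation is plain NumPy: the models involved are small enough
that a dense forward/backward pass is fast, and keeping the arithmetic in
one place makes the masked loss, layer freezing (used by transfer
learning), and seeding contracts exact and testable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._seeds import stage_rng
from .exceptions import StateError, ValidationError

__all__ = ["MLPConfig", "MLPModel", "init_mlp", "train_mlp_arrays", "AdamState"]


@dataclass
class MLPConfig:
    hidden_sizes: tuple[int, ...] = (256, 128, 64)
    dropout_rate: float = 0.3
    learning_rate: float = 1e-3
    batch_size: int = 128
    max_epochs: int = 100
    patience: int = 10

    def __post_init__(self) -> None:
        if len(self.hidden_sizes) < 1:
            raise ValidationError("the network needs at least one hidden layer")
        if any(h < 1 for h in self.hidden_sizes):
            raise ValidationError("hidden layer sizes must be positive")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValidationError("dropout_rate must be in [0, 1)")
        if self.max_epochs < 1:
            raise ValidationError("max_epochs must be >= 1")


@dataclass
class MLPModel:
    """Weights/biases per layer; ReLU on hidden layers, linear output."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    dropout_rate: float = 0.0

    @property
    def layer_sizes(self) -> tuple[int, ...]:
        return (self.weights[0].shape[0], *(w.shape[1] for w in self.weights))

    @property
    def n_outputs(self) -> int:
        return self.weights[-1].shape[1]

    def copy(self) -> "MLPModel":
        return MLPModel(
            [w.copy() for w in self.weights],
            [b.copy() for b in self.biases],
            self.dropout_rate,
        )

    def hidden_activations(self, x: np.ndarray, upto: int | None = None) -> np.ndarray:
        """ReLU activations after hidden layer ``upto`` (default: all)."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        n_hidden = len(self.weights) - 1
        upto = n_hidden if upto is None else upto
        a = x
        for i in range(upto):
            a = np.maximum(a @ self.weights[i] + self.biases[i], 0.0)
        return a

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Deterministic forward pass (dropout disabled)."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != self.weights[0].shape[0]:
            raise ValidationError(
                f"feature length {x.shape[1]} != input layer "
                f"{self.weights[0].shape[0]}"
            )
        a = self.hidden_activations(x)
        return a @ self.weights[-1] + self.biases[-1]


def init_mlp(
    n_inputs: int,
    n_outputs: int,
    config: MLPConfig,
    seed: int,
    key: str = "mlp_init",
) -> MLPModel:
    """He-normal initialization for ReLU layers; zero biases.

    Each layer draws from its own derived stream, and output-layer columns
    are drawn column-wise, so the initialization of one output node does not
    depend on how many other output nodes exist.
    """
    sizes = (n_inputs, *config.hidden_sizes, n_outputs)
    weights, biases = [], []
    n_layers = len(sizes) - 1
    for layer, (fan_in, fan_out) in enumerate(zip(sizes[:-1], sizes[1:])):
        sd = np.sqrt(2.0 / fan_in)
        if layer == n_layers - 1:
            cols = [
                stage_rng(seed, key, layer, j).normal(0.0, sd, size=fan_in)
                for j in range(fan_out)
            ]
            w = np.column_stack(cols)
        else:
            w = stage_rng(seed, key, layer).normal(0.0, sd, size=(fan_in, fan_out))
        weights.append(w)
        biases.append(np.zeros(fan_out))
    return MLPModel(weights, biases, config.dropout_rate)


@dataclass
class AdamState:
    """First/second moment accumulators for a list of parameter arrays."""

    m: list[np.ndarray]
    v: list[np.ndarray]
    t: int = 0

    @classmethod
    def for_params(cls, params: list[np.ndarray]) -> "AdamState":
        return cls([np.zeros_like(p) for p in params], [np.zeros_like(p) for p in params])

    def step(
        self,
        params: list[np.ndarray],
        grads: list[np.ndarray],
        lr: float,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.t += 1
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= beta1
            m += (1 - beta1) * g
            v *= beta2
            v += (1 - beta2) * g * g
            mhat = m / (1 - beta1**self.t)
            vhat = v / (1 - beta2**self.t)
            p -= lr * mhat / (np.sqrt(vhat) + eps)


def masked_mse(pred: np.ndarray, y: np.ndarray, mask: np.ndarray) -> float:
    """Mean squared error over observed cells only."""
    n_obs = mask.sum()
    if n_obs == 0:
        return 0.0
    return float((mask * (pred - y) ** 2).sum() / n_obs)


def _forward_train(
    model: MLPModel, x: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, list[np.ndarray], list[np.ndarray]]:
    """Forward pass with inverted dropout; returns output, activations, masks."""
    acts = [x]
    drops = []
    a = x
    p = model.dropout_rate
    for i in range(len(model.weights) - 1):
        a = np.maximum(a @ model.weights[i] + model.biases[i], 0.0)
        if p > 0:
            keep = (rng.random(a.shape) >= p) / (1.0 - p)
            a = a * keep
            drops.append(keep)
        else:
            drops.append(None)
        acts.append(a)
    out = a @ model.weights[-1] + model.biases[-1]
    return out, acts, drops


def _backward(
    model: MLPModel,
    x_batch_out: np.ndarray,
    acts: list[np.ndarray],
    drops: list[np.ndarray],
    dloss_dout: np.ndarray,
    trainable: list[int],
) -> dict[int, tuple[np.ndarray, np.ndarray]]:
    """Backprop; returns gradients only for layers listed in ``trainable``."""
    grads: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    min_layer = min(trainable)
    delta = dloss_dout
    for layer in range(len(model.weights) - 1, -1, -1):
        if layer in trainable:
            grads[layer] = (acts[layer].T @ delta, delta.sum(axis=0))
        if layer == min_layer:
            break
        delta = delta @ model.weights[layer].T
        # back through dropout then ReLU of the previous hidden layer
        if drops[layer - 1] is not None:
            delta = delta * drops[layer - 1]
        delta = delta * (acts[layer] > 0)
    return grads


def train_mlp_arrays(
    x_train: np.ndarray,
    y_train: np.ndarray,
    mask_train: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
    mask_val: np.ndarray,
    config: MLPConfig,
    seed: int = 0,
    model: MLPModel | None = None,
    trainable_layers: list[int] | None = None,
    patience: int | None = None,
) -> tuple[MLPModel, dict]:
    """Train (or continue training) a network on array data.

    When ``model`` is given, training continues from its weights; otherwise a
    fresh network is initialized.  ``trainable_layers`` restricts updates to
    the listed layer indices (used by transfer-learning finetuning); frozen
    layers are never touched.  Early stopping monitors the masked validation
    loss and restores the best weights.  Returns (model, history).
    """
    x_train = np.asarray(x_train, dtype=float)
    y_train = np.asarray(y_train, dtype=float)
    mask_train = np.asarray(mask_train, dtype=bool)
    if y_train.ndim == 1:
        y_train = y_train[:, None]
        mask_train = mask_train.reshape(y_train.shape)
    # zero out masked cells so stray values (even non-finite) cannot leak
    y_train = np.where(mask_train, y_train, 0.0)
    if x_train.shape[0] == 0:
        raise ValidationError("empty training split")
    y_val = np.asarray(y_val, dtype=float)
    if y_val.ndim == 1:
        y_val = y_val[:, None]
    mask_val = np.asarray(mask_val, dtype=bool).reshape(y_val.shape)
    y_val = np.where(mask_val, y_val, 0.0)

    rng = stage_rng(seed, "mlp_train")
    if model is None:
        model = init_mlp(x_train.shape[1], y_train.shape[1], config, seed)
    else:
        model = model.copy()
    n_layers = len(model.weights)
    if trainable_layers is None:
        trainable_layers = list(range(n_layers))
    patience = config.patience if patience is None else patience

    params: list[np.ndarray] = []
    for layer in trainable_layers:
        params.extend([model.weights[layer], model.biases[layer]])
    adam = AdamState.for_params(params)

    n = x_train.shape[0]
    batch = max(1, min(config.batch_size, n))
    best_loss = np.inf
    best_weights = model.copy()
    best_epoch = -1
    stall = 0
    history = {"train_loss": [], "val_loss": []}

    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        epoch_obs = 0
        for start in range(0, n, batch):
            idx = order[start : start + batch]
            xb, yb, mb = x_train[idx], y_train[idx], mask_train[idx]
            out, acts, drops = _forward_train(model, xb, rng)
            n_obs = mb.sum()
            if n_obs == 0:
                continue
            resid = (out - yb) * mb
            epoch_loss += float((resid * (out - yb)).sum())
            epoch_obs += int(n_obs)
            dloss = 2.0 * resid / n_obs
            grads = _backward(model, xb, acts, drops, dloss, trainable_layers)
            flat_grads = []
            for layer in trainable_layers:
                gw, gb = grads[layer]
                flat_grads.extend([gw, gb])
            adam.step(params, flat_grads, config.learning_rate)
        history["train_loss"].append(epoch_loss / max(epoch_obs, 1))

        val_loss = masked_mse(model.predict(x_val), y_val, mask_val)
        history["val_loss"].append(val_loss)
        if val_loss < best_loss - 1e-12:
            best_loss = val_loss
            best_weights = model.copy()
            best_epoch = epoch
            stall = 0
        else:
            stall += 1
            if stall >= patience:
                break

    history["best_epoch"] = best_epoch
    history["best_val_loss"] = best_loss
    return best_weights, history
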