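"""Transfer-learning baseline: finetune the pre-trained network on K shots.

The multi-output network pre-trained on the extra-large source dataset is
adapted to a single new phenotype by (1) replacing its output layer with a
freshly initialized single-output head and (2) updating only the last two
layers — the new head and the last hidden layer — while all earlier layers
stay frozen (their parameters are bit-identical before and after).

A fixed learning rate is chosen by 5-fold cross-validation over a grid; the
final finetune uses all K participants with an inner 80/20 split for early
stopping.  Finetuning runs for at most 10 epochs (the adaptation sample is
tiny) with early-stopping patience 3; ties in the CV score prefer the
smallest learning rate.  Dropout is disabled during finetuning: with K of
order tens, early stopping is the regularizer, and a deterministic forward
pass lets the frozen trunk be precomputed.

Because the trunk is frozen, its activations for a given participant never
change; :func:`frozen_activations` computes them once so that repeated
finetunes (e.g. across evaluation repetitions) only touch the two trainable
layers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seeds import stage_rng
from .exceptions import ProtocolError, ValidationError
from .learners import kfold_indices
from .mlp import MLPConfig, MLPModel, init_mlp, train_mlp_arrays

__all__ = ["FinetuneConfig", "FinetunedModel", "finetune", "frozen_activations",
           "finetune_head", "predict_finetuned"]


@dataclass
class FinetuneConfig:
    lr_grid: tuple[float, ...] = (1e-4, 1e-3, 1e-2)
    max_epochs: int = 10
    patience: int = 3
    batch_size: int = 16
    n_folds: int = 5
    train_fraction: float = 0.8  # inner split for early stopping

    def __post_init__(self) -> None:
        if len(self.lr_grid) == 0:
            raise ValidationError("lr_grid must be non-empty")
        if self.max_epochs < 1:
            raise ValidationError("max_epochs must be >= 1")


@dataclass
class FinetunedModel:
    """The frozen trunk plus the two finetuned layers, as one network."""

    model: MLPModel  # full network with single-output head
    n_frozen_layers: int
    learning_rate: float

    def predict(self, features: np.ndarray) -> np.ndarray:
        return predict_finetuned(self, features)


def predict_finetuned(model: FinetunedModel, features: np.ndarray) -> np.ndarray:
    """Deterministic single-output forward pass, shape (n,)."""
    return model.model.predict(features)[:, 0]


def frozen_activations(pretrained: MLPModel, features: np.ndarray) -> np.ndarray:
    """Activations at the frozen/trainable boundary (input to the last
    hidden layer)."""
    n_hidden = len(pretrained.weights) - 1
    if n_hidden < 2:
        raise ValidationError(
            "finetuning the last two layers needs at least two hidden layers"
        )
    return pretrained.hidden_activations(features, upto=n_hidden - 1)


def _head_model(pretrained: MLPModel, seed: int) -> MLPModel:
    """The trainable tail: last hidden layer + a fresh single-output head.

    The head is initialized with the same He-normal family used in
    pretraining, from a recorded seed.
    """
    tail_sizes = pretrained.layer_sizes[-3:]  # (in, last_hidden, old T)
    cfg = MLPConfig(hidden_sizes=(tail_sizes[1],), dropout_rate=0.0,
                    max_epochs=1)
    fresh = init_mlp(tail_sizes[0], 1, cfg, seed, key="finetune_head")
    return MLPModel(
        [pretrained.weights[-2].copy(), fresh.weights[-1]],
        [pretrained.biases[-2].copy(), fresh.biases[-1]],
        dropout_rate=0.0,
    )


def finetune_head(
    activations: np.ndarray,
    y: np.ndarray,
    pretrained: MLPModel,
    config: FinetuneConfig,
    seed: int = 0,
) -> tuple[MLPModel, float]:
    """Choose a learning rate by CV and finetune the two-layer tail.

    ``activations`` are the frozen-trunk activations of the K participants.
    Returns (tail network, chosen learning rate).
    """
    h = np.atleast_2d(np.asarray(activations, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    k = y.size
    if k < config.n_folds:
        raise ProtocolError(
            f"finetuning needs at least {config.n_folds} participants "
            f"for {config.n_folds}-fold CV, got {k}"
        )
    lrs = np.asarray(config.lr_grid, dtype=float)

    def _train_tail(rows: np.ndarray, lr: float, fit_seed: int) -> MLPModel:
        """Finetune on ``rows`` with an inner 80/20 early-stopping split."""
        rng = stage_rng(fit_seed, "finetune_split")
        perm = rng.permutation(rows.size)
        n_tr = max(1, int(round(config.train_fraction * rows.size)))
        n_tr = min(n_tr, rows.size - 1) if rows.size > 1 else rows.size
        tr, va = rows[perm[:n_tr]], rows[perm[n_tr:]]
        tail = _head_model(pretrained, seed)
        cfg = MLPConfig(
            hidden_sizes=(tail.layer_sizes[1],),
            dropout_rate=0.0,
            learning_rate=lr,
            batch_size=config.batch_size,
            max_epochs=config.max_epochs,
            patience=config.patience,
        )
        ones = np.ones((tr.size, 1), dtype=bool)
        ones_va = np.ones((va.size, 1), dtype=bool)
        tuned, _ = train_mlp_arrays(
            h[tr], y[tr], ones, h[va], y[va], ones_va,
            cfg, seed=fit_seed, model=tail,
        )
        return tuned

    if lrs.size == 1:
        best_lr = float(lrs[0])
    else:
        folds = kfold_indices(k, config.n_folds, stage_rng(seed, "finetune_cv"))
        errs = np.zeros((len(folds), lrs.size))
        for f, (tr, va) in enumerate(folds):
            for i, lr in enumerate(lrs):
                tail = _train_tail(tr, lr, int(stage_rng(seed, "ft_fold", f, i).integers(2**31)))
                pred = tail.predict(h[va])[:, 0]
                errs[f, i] = np.mean((pred - y[va]) ** 2)
        scores = errs.mean(axis=0)
        # ties prefer the smallest (most conservative) learning rate
        best_lr = float(np.min(lrs[np.flatnonzero(scores == np.min(scores))]))

    final_seed = int(stage_rng(seed, "ft_final").integers(2**31))
    tail = _train_tail(np.arange(k), best_lr, final_seed)
    return tail, best_lr


def finetune(
    pretrained: MLPModel,
    kshot_features: np.ndarray,
    kshot_target: np.ndarray,
    config: FinetuneConfig | None = None,
    seed: int = 0,
) -> FinetunedModel:
    """Adapt the pre-trained multi-output network to one new phenotype.

    Only the last hidden layer and the (fresh, single-output) head are
    updated; every earlier parameter is shared with ``pretrained`` unchanged.
    """
    config = config or FinetuneConfig()
    x = np.atleast_2d(np.asarray(kshot_features, dtype=float))
    h = frozen_activations(pretrained, x)
    tail, lr = finetune_head(h, kshot_target, pretrained, config, seed=seed)
    n_frozen = len(pretrained.weights) - 2
    full = MLPModel(
        [w.copy() for w in pretrained.weights[:n_frozen]] + list(tail.weights),
        [b.copy() for b in pretrained.biases[:n_frozen]] + list(tail.biases),
        dropout_rate=0.0,
    )
    return FinetunedModel(full, n_frozen, lr)
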