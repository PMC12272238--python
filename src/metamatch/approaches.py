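"""Concrete K-shot approaches wired for the evaluation protocol.

Each class wraps one prediction strategy around a fixed target dataset and
precomputes everything that does not depend on the K-shot sample: the
classical-KRR approach precomputes the full participant-participant
correlation kernel; the meta-matching approaches precompute the
prediction-feature matrix (and its kernel) for every target participant;
transfer learning precomputes the frozen-trunk activations.  This is purely
a computational reuse — nothing adapted on the K shots ever sees evaluation
labels.
"""

from __future__ import annotations

import numpy as np

from ._seeds import stage_rng
from .exceptions import ValidationError
from .features import correlation_kernel
from .learners import DEFAULT_LAMBDA_GRID, _eig_dual_path, tune_krr_kernel
from .mlp import MLPModel
from .stacking import MultilayerModel
from .transfer import FinetuneConfig, finetune_head

__all__ = [
    "ClassicalKRRApproach",
    "MetaMatchingApproach",
    "TransferApproach",
    "default_approaches",
]


class _KernelKRRMixin:
    """Shared K-shot KRR machinery on a precomputed kernel."""

    kernel: np.ndarray
    lambda_grid: np.ndarray

    def _krr_predict(
        self, shot: np.ndarray, ev: np.ndarray, y_shot: np.ndarray, seed: int
    ) -> np.ndarray:
        k_ss = self.kernel[np.ix_(shot, shot)]
        lam, _ = tune_krr_kernel(
            k_ss, y_shot, self.lambda_grid, rng=stage_rng(seed, "krr_cv")
        )
        mu = float(np.mean(y_shot))
        alpha = _eig_dual_path(k_ss, y_shot - mu, np.array([lam]))[:, 0]
        return self.kernel[np.ix_(ev, shot)] @ alpha + mu


class ClassicalKRRApproach(_KernelKRRMixin):
    """Baseline: correlation-kernel KRR trained on the K shots only.

    Uses the raw (unnormalized) FC vectors; per-participant normalization
    provably does not change the correlation kernel, so this choice is
    cosmetic.
    """

    name = "classical_krr"

    def __init__(self, target_features: np.ndarray, lambda_grid=DEFAULT_LAMBDA_GRID):
        self.kernel = correlation_kernel(np.asarray(target_features, dtype=float))
        self.lambda_grid = np.asarray(lambda_grid, dtype=float)

    def adapt_and_predict(self, shot, ev, y_shot, phenotype, seed):
        return self._krr_predict(shot, ev, y_shot, seed)


class MetaMatchingApproach(_KernelKRRMixin):
    """Stacking meta-learner over a trained multilayer model's features.

    ``variant`` selects the feature set: 'stacking' (single source),
    'dataset_stacking', or 'multilayer'.
    """

    def __init__(
        self,
        model: MultilayerModel,
        target_features: np.ndarray,
        variant: str,
        include_xl_lrr: bool = False,
        lambda_grid=DEFAULT_LAMBDA_GRID,
        name: str | None = None,
    ):
        self.model = model
        self.variant = variant
        self.name = name or variant
        self.prediction_features, self.column_labels = model.features_for_variant(
            variant, np.asarray(target_features, dtype=float),
            include_xl_lrr=include_xl_lrr,
        )
        self.kernel = correlation_kernel(self.prediction_features)
        self.lambda_grid = np.asarray(lambda_grid, dtype=float)

    def adapt_and_predict(self, shot, ev, y_shot, phenotype, seed):
        return self._krr_predict(shot, ev, y_shot, seed)


class TransferApproach:
    """Finetune the pre-trained multi-output network on the K shots."""

    name = "transfer"

    def __init__(
        self,
        pretrained: MLPModel,
        target_features: np.ndarray,
        config: FinetuneConfig | None = None,
    ):
        from .transfer import frozen_activations

        self.pretrained = pretrained
        self.config = config or FinetuneConfig()
        self.activations = frozen_activations(
            pretrained, np.asarray(target_features, dtype=float)
        )

    def adapt_and_predict(self, shot, ev, y_shot, phenotype, seed):
        tail, _ = finetune_head(
            self.activations[shot], y_shot, self.pretrained, self.config,
            seed=seed,
        )
        return tail.predict(self.activations[ev])[:, 0]


def default_approaches(
    model: MultilayerModel,
    target_features: np.ndarray,
    lambda_grid=DEFAULT_LAMBDA_GRID,
    finetune_config: FinetuneConfig | None = None,
) -> list:
    """The five approaches compared throughout: classical KRR, transfer
    learning, and the three meta-matching variants."""
    xl = model.by_class("extra_large")[0]
    if xl.mlp is None:
        raise ValidationError("transfer learning needs the extra-large MLP")
    return [
        ClassicalKRRApproach(target_features, lambda_grid),
        TransferApproach(xl.mlp, target_features, finetune_config),
        MetaMatchingApproach(model, target_features, "stacking", lambda_grid=lambda_grid),
        MetaMatchingApproach(model, target_features, "dataset_stacking", lambda_grid=lambda_grid),
        MetaMatchingApproach(model, target_features, "multilayer", lambda_grid=lambda_grid),
    ]
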