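"""Haufe-transform feature importance.

Predictive weight vectors of regularized models are not interpretable edge
by edge; the Haufe transform converts a predictive model into an activation
pattern by computing, for each FC edge, the covariance between the edge
value and the model's *prediction* across participants.  A positive value
means higher connectivity at that edge goes with the model predicting a
larger phenotype value.  For an exactly linear predictor yhat = X w on
centered features this equals the feature covariance matrix times w.

A *pseudo ground truth* importance map is obtained by training a
correlation-kernel KRR model on the full target sample (CV-tuned lambda)
and Haufe-transforming its in-sample predictions; importance maps from
K-shot models are then scored by their Pearson correlation with it.
Covariances use the unbiased (n - 1) denominator; correlations between maps
are denominator-invariant anyway.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._seeds import stage_rng
from .exceptions import DegenerateInputError, ValidationError
from .learners import DEFAULT_LAMBDA_GRID, fit_krr_tuned
from .evaluation import pearson_metric

__all__ = [
    "ImportanceMap",
    "haufe_importance",
    "pseudo_ground_truth",
    "importance_agreement",
]


@dataclass
class ImportanceMap:
    """Per-edge importance values in the canonical edge order."""

    values: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("importance values must be finite")

    def __len__(self) -> int:
        return self.values.size


def haufe_importance(
    features: np.ndarray, predictions: np.ndarray, source: str = ""
) -> ImportanceMap:
    """Covariance of each feature with the model predictions.

    ``features`` is (n, E); ``predictions`` is the model output for the same
    n participants (n >= 3, non-constant).
    """
    x = np.atleast_2d(np.asarray(features, dtype=float))
    yhat = np.asarray(predictions, dtype=float).ravel()
    if x.shape[0] != yhat.size:
        raise ValidationError("features and predictions disagree on n")
    if yhat.size < 3:
        raise ValidationError("need at least 3 participants")
    if yhat.std() <= 0:
        raise DegenerateInputError("constant predictions: importance undefined")
    xc = x - x.mean(axis=0)
    yc = yhat - yhat.mean()
    cov = xc.T @ yc / (yhat.size - 1)
    return ImportanceMap(cov, source=source)


def pseudo_ground_truth(
    features: np.ndarray,
    target: np.ndarray,
    lambda_grid: np.ndarray = DEFAULT_LAMBDA_GRID,
    seed: int = 0,
    mask: np.ndarray | None = None,
) -> ImportanceMap:
    """Reference importance map from a full-sample KRR model.

    Fits correlation-kernel KRR with CV-tuned lambda on all participants
    with the target observed, then Haufe-transforms its in-sample
    predictions over those same participants.
    """
    x = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(target, dtype=float).ravel()
    if mask is None:
        mask = np.isfinite(y)
    obs = np.flatnonzero(np.asarray(mask, dtype=bool).ravel())
    x, y = x[obs], y[obs]
    model = fit_krr_tuned(
        x, y, lambda_grid, rng=stage_rng(seed, "pgt"), target_name="pseudo_gt"
    )
    preds = model.predict(x)
    return haufe_importance(x, preds, source="pseudo_ground_truth")


def importance_agreement(a: ImportanceMap, b: ImportanceMap) -> float:
    """Pearson correlation between two importance maps (same edge order)."""
    if len(a) != len(b):
        raise ValidationError(f"map lengths differ: {len(a)} vs {len(b)}")
    return pearson_metric(a.values, b.values)
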