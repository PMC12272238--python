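"""Base predictor families: correlation-kernel KRR and linear ridge (LRR).

Kernel ridge regression here always uses the Pearson-correlation kernel
between participants' FC feature vectors, the standard choice for
connectome-based phenotype prediction.  Targets are mean-centered before the
dual solve and the mean is added back at prediction time, since a
correlation kernel has no intercept pathway.  Linear ridge regression fits
one weight vector per phenotype with an unpenalized intercept.

Hyper-parameter tuning for both families is grid search over the L2 weight
lambda with 5-fold cross-validation: folds are a random equal partition of
the provided participants, the score is the validation mean-squared error
averaged over folds, and ties prefer the largest lambda (stronger
regularization is the safer default in the small-sample regimes this
package targets).  The default grid is {0} plus 20 logarithmically spaced
values from 1e-4 to 1e4.

Implementation note: for a fixed fold the solutions for every lambda on the
grid come from a single symmetric eigendecomposition, with eigenvalue
shifts; directions with (s + lambda) numerically zero are dropped
(pseudo-inverse convention), so lambda = 0 yields the minimum-norm
interpolant rather than a failure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from ._seeds import stage_rng
from .exceptions import (
    DegenerateInputError,
    NumericalError,
    ProtocolError,
    ValidationError,
)
from .features import correlation_kernel

__all__ = [
    "KRRModel",
    "LRRModel",
    "DEFAULT_LAMBDA_GRID",
    "fit_krr",
    "tune_krr",
    "fit_krr_tuned",
    "predict_krr",
    "fit_lrr",
    "predict_lrr",
]

DEFAULT_LAMBDA_GRID = np.concatenate([[0.0], np.logspace(-4, 4, 20)])

_EPS = 1e-12


def kfold_indices(
    n: int, n_folds: int, rng: np.random.Generator
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Random equal partition into folds; deterministic given the generator."""
    if n < n_folds:
        raise ProtocolError(
            f"{n} participants cannot be split into {n_folds} folds; "
            "use fewer folds or more participants"
        )
    perm = rng.permutation(n)
    chunks = np.array_split(perm, n_folds)
    out = []
    for i, val in enumerate(chunks):
        train = np.concatenate([c for j, c in enumerate(chunks) if j != i])
        out.append((np.sort(train), np.sort(val)))
    return out


def _pick_lambda(lams: np.ndarray, scores: np.ndarray) -> float:
    """Largest lambda among those tied for the best (lowest) CV error."""
    best = np.min(scores)
    tied = np.flatnonzero(scores == best)
    return float(np.max(lams[tied]))


# ---------------------------------------------------------------------------
# kernel ridge regression
# ---------------------------------------------------------------------------


@dataclass
class KRRModel:
    """Correlation-kernel ridge model for one or more targets.

    The training feature rows are retained because evaluating the kernel on
    new participants requires them.  Per target we keep the indices of the
    observed training rows (``supports``), the dual coefficients, and the
    target mean added back at prediction.
    """

    lam: float
    train_features: np.ndarray
    supports: list[np.ndarray]
    dual_coefs: list[np.ndarray]
    y_means: np.ndarray
    target_names: list[str]

    @property
    def n_targets(self) -> int:
        return len(self.target_names)

    def predict(self, new_features: np.ndarray) -> np.ndarray:
        return predict_krr(self, new_features)


def _solve_dual(k: np.ndarray, y: np.ndarray, lam: float) -> np.ndarray:
    """Solve (K + lam I) alpha = y via Cholesky; y must be centered."""
    a = k + lam * np.eye(k.shape[0])
    try:
        c, low = scipy.linalg.cho_factor(a)
        return scipy.linalg.cho_solve((c, low), y)
    except scipy.linalg.LinAlgError as err:
        raise NumericalError(
            "kernel system is singular (duplicate participants at lambda = 0?); "
            "use lambda > 0"
        ) from err


def _eig_dual_path(
    k_train: np.ndarray, y_centered: np.ndarray, lams: np.ndarray
) -> np.ndarray:
    """Dual coefficients for every lambda from one eigendecomposition.

    Returns (n_train, n_lambda).  Near-zero shifted eigenvalues are dropped,
    so lambda = 0 gives the minimum-norm solution.
    """
    s, u = scipy.linalg.eigh(k_train)
    t = u.T @ y_centered
    denom = s[:, None] + lams[None, :]
    scale = np.abs(s).max() if s.size else 1.0
    keep = np.abs(denom) > _EPS * max(scale, 1.0)
    inv = np.divide(1.0, denom, out=np.zeros_like(denom), where=keep)
    return u @ (t[:, None] * inv)


def fit_krr(
    features: np.ndarray,
    targets: np.ndarray,
    lam: float,
    mask: np.ndarray | None = None,
    target_names: list[str] | None = None,
    kernel: np.ndarray | None = None,
) -> KRRModel:
    """Fit KRR with a fixed lambda on the observed rows of each target.

    ``targets`` is (n,) or (n, T); ``mask`` marks observed entries.  The dual
    solution satisfies (K + lam I) alpha = y_centered on each target's
    observed sub-kernel.
    """
    features = np.asarray(features, dtype=float)
    y = np.asarray(targets, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    if lam < 0:
        raise ValidationError("lambda must be non-negative")
    if y.shape[0] != features.shape[0]:
        raise ValidationError("targets and features disagree on n participants")
    if mask is None:
        mask = np.isfinite(y)
    mask = np.asarray(mask, dtype=bool).reshape(y.shape)
    if target_names is None:
        target_names = [f"target_{j}" for j in range(y.shape[1])]
    if kernel is None:
        kernel = correlation_kernel(features)

    supports, coefs, means = [], [], []
    for j in range(y.shape[1]):
        obs = np.flatnonzero(mask[:, j])
        if obs.size < 2:
            raise ValidationError(
                f"target {target_names[j]!r} has {obs.size} observed rows; need >= 2"
            )
        yj = y[obs, j]
        mu = float(yj.mean())
        alpha = _solve_dual(kernel[np.ix_(obs, obs)], yj - mu, lam)
        supports.append(obs)
        coefs.append(alpha)
        means.append(mu)
    return KRRModel(float(lam), features, supports, coefs, np.array(means), list(target_names))


def predict_krr(model: KRRModel, new_features: np.ndarray) -> np.ndarray:
    """Predictions (n_new, T); squeezed to (n_new,) for a single target."""
    new_features = np.atleast_2d(np.asarray(new_features, dtype=float))
    if new_features.shape[1] != model.train_features.shape[1]:
        raise ValidationError(
            f"feature length {new_features.shape[1]} != training length "
            f"{model.train_features.shape[1]}"
        )
    k_cross = correlation_kernel(new_features, model.train_features)
    out = np.empty((new_features.shape[0], model.n_targets))
    for j in range(model.n_targets):
        out[:, j] = k_cross[:, model.supports[j]] @ model.dual_coefs[j] + model.y_means[j]
    return out[:, 0] if model.n_targets == 1 else out


def tune_krr_kernel(
    kernel: np.ndarray,
    y: np.ndarray,
    lambda_grid: np.ndarray = DEFAULT_LAMBDA_GRID,
    n_folds: int = 5,
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> tuple[float, np.ndarray]:
    """Choose lambda by k-fold CV on a precomputed training kernel.

    Returns (best lambda, per-lambda mean validation MSE).  Deterministic
    given the generator/seed.
    """
    lams = np.asarray(lambda_grid, dtype=float)
    if lams.size == 0:
        raise ValidationError("empty lambda grid")
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if rng is None:
        rng = stage_rng(seed, "tune_krr")
    folds = kfold_indices(n, n_folds, rng)
    errs = np.zeros((len(folds), lams.size))
    for f, (tr, va) in enumerate(folds):
        mu = y[tr].mean()
        alphas = _eig_dual_path(kernel[np.ix_(tr, tr)], y[tr] - mu, lams)
        preds = kernel[np.ix_(va, tr)] @ alphas + mu
        errs[f] = np.mean((preds - y[va, None]) ** 2, axis=0)
    scores = errs.mean(axis=0)
    return _pick_lambda(lams, scores), scores


def tune_krr(
    features: np.ndarray,
    y: np.ndarray,
    lambda_grid: np.ndarray = DEFAULT_LAMBDA_GRID,
    n_folds: int = 5,
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> tuple[float, np.ndarray]:
    """Grid-search lambda for correlation-kernel KRR by k-fold CV."""
    kernel = correlation_kernel(np.asarray(features, dtype=float))
    return tune_krr_kernel(kernel, y, lambda_grid, n_folds, rng=rng, seed=seed)


def fit_krr_tuned(
    features: np.ndarray,
    y: np.ndarray,
    lambda_grid: np.ndarray = DEFAULT_LAMBDA_GRID,
    n_folds: int = 5,
    rng: np.random.Generator | None = None,
    seed: int = 0,
    target_name: str = "target",
) -> KRRModel:
    """CV-tune lambda then refit on all provided participants."""
    features = np.asarray(features, dtype=float)
    kernel = correlation_kernel(features)
    lam, _ = tune_krr_kernel(kernel, y, lambda_grid, n_folds, rng=rng, seed=seed)
    y = np.asarray(y, dtype=float).ravel()
    mu = float(y.mean())
    alpha = _eig_dual_path(kernel, y - mu, np.array([lam]))[:, 0]
    return KRRModel(
        lam,
        features,
        [np.arange(y.size)],
        [alpha],
        np.array([mu]),
        [target_name],
    )


# ---------------------------------------------------------------------------
# linear ridge regression
# ---------------------------------------------------------------------------


@dataclass
class LRRModel:
    """Linear ridge model for one phenotype: weights, unpenalized intercept,
    and the CV-chosen lambda."""

    weights: np.ndarray
    intercept: float
    lam: float
    target_name: str = "target"

    def predict(self, features: np.ndarray) -> np.ndarray:
        return predict_lrr(self, features)


def _ridge_path(xc: np.ndarray, yc: np.ndarray, lams: np.ndarray) -> np.ndarray:
    """Weights (E, n_lambda) for centered data, all lambdas at once.

    Works in whichever of the primal (E x E) or dual (n x n) gram is smaller.
    """
    n, e = xc.shape
    if e <= n:
        s, v = scipy.linalg.eigh(xc.T @ xc)
        t = v.T @ (xc.T @ yc)
        basis = v
    else:
        s, u = scipy.linalg.eigh(xc @ xc.T)
        t = u.T @ yc
        basis = xc.T @ u
    denom = s[:, None] + lams[None, :]
    scale = np.abs(s).max() if s.size else 1.0
    keep = np.abs(denom) > _EPS * max(scale, 1.0)
    inv = np.divide(1.0, denom, out=np.zeros_like(denom), where=keep)
    return basis @ (t[:, None] * inv)


def fit_lrr(
    features: np.ndarray,
    y: np.ndarray,
    lambda_grid: np.ndarray = DEFAULT_LAMBDA_GRID,
    n_folds: int = 5,
    rng: np.random.Generator | None = None,
    seed: int = 0,
    mask: np.ndarray | None = None,
    target_name: str = "target",
) -> LRRModel:
    """Per-phenotype linear ridge: CV-tune lambda on the observed rows, then
    refit on all observed rows with an unpenalized intercept."""
    x = np.asarray(features, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if mask is None:
        mask = np.isfinite(y)
    obs = np.flatnonzero(np.asarray(mask, dtype=bool).ravel())
    if obs.size == 0:
        raise ValidationError(f"phenotype {target_name!r} has no observed rows")
    x, y = x[obs], y[obs]
    lams = np.asarray(lambda_grid, dtype=float)
    if lams.size == 0:
        raise ValidationError("empty lambda grid")
    if rng is None:
        rng = stage_rng(seed, "tune_lrr")
    folds = kfold_indices(x.shape[0], n_folds, rng)
    errs = np.zeros((len(folds), lams.size))
    for f, (tr, va) in enumerate(folds):
        xm, ym = x[tr].mean(axis=0), y[tr].mean()
        w = _ridge_path(x[tr] - xm, y[tr] - ym, lams)
        preds = (x[va] - xm) @ w + ym
        errs[f] = np.mean((preds - y[va, None]) ** 2, axis=0)
    lam = _pick_lambda(lams, errs.mean(axis=0))
    xm, ym = x.mean(axis=0), y.mean()
    w = _ridge_path(x - xm, y - ym, np.array([lam]))[:, 0]
    intercept = float(ym - xm @ w)
    return LRRModel(w, intercept, lam, target_name)


def predict_lrr(model: LRRModel, features: np.ndarray) -> np.ndarray:
    x = np.atleast_2d(np.asarray(features, dtype=float))
    if x.shape[1] != model.weights.size:
        raise ValidationError(
            f"feature length {x.shape[1]} != model length {model.weights.size}"
        )
    return x @ model.weights + model.intercept
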