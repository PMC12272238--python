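"""Functional-connectivity feature engineering.

A participant's resting-state functional connectivity (FC) is a symmetric
P x P matrix of edge weights between brain parcels.  All predictors in this
package consume its strict lower triangle, vectorized in a single canonical
order, optionally normalized per participant, and compared between
participants with a Pearson-correlation kernel.

Canonical edge order
--------------------
``vectorize_lower_triangle`` walks the strictly-lower-triangular entries
row-major: (1,0), (2,0), (2,1), (3,0), ...  This same order is used for
Haufe importance maps and every serialized container; for a P x P matrix it
yields E = P(P-1)/2 edges (87,571 for the P = 419 parcellation commonly
used with these data).

Per-participant normalization subtracts the vector mean and divides by the
L2-norm of the *demeaned* vector, making each feature vector exactly
zero-mean and unit-norm.  This is a package convention: it makes the
operation idempotent and reduces the correlation kernel to a plain dot
product on normalized vectors.  Different FC pipelines center edge
distributions differently (global-signal regression centers them at zero,
ICA-FIX does not); this normalization removes such per-participant offset
and scale differences, and it provably does not change the correlation
kernel at all.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateInputError, ValidationError

__all__ = [
    "FCMatrix",
    "FeatureVector",
    "vectorize_lower_triangle",
    "devectorize",
    "normalize_features",
    "correlation_kernel",
    "n_edges",
    "n_parcels",
]

#: symmetry tolerance for FC matrices; they are correlation-like, so any
#: larger asymmetry indicates an upstream error rather than rounding.
SYMMETRY_TOL = 1e-8


def n_edges(p: int) -> int:
    """Number of strict lower-triangular entries of a P x P matrix."""
    return p * (p - 1) // 2


def n_parcels(e: int) -> int:
    """Invert ``n_edges``; raises if ``e`` is not a valid edge count."""
    p = int((1 + np.sqrt(1 + 8 * e)) / 2 + 0.5)
    if n_edges(p) != e:
        raise ValidationError(f"{e} is not P*(P-1)/2 for any integer P")
    return p


@dataclass
class FCMatrix:
    """A participant's symmetric connectivity matrix.

    The diagonal carries no information for prediction and is ignored by
    vectorization (self-connectivity is conventionally 1 but nothing here
    depends on that).
    """

    values: np.ndarray
    participant_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        _check_symmetric(self.values)

    @property
    def n_parcels(self) -> int:
        return self.values.shape[0]

    def vectorize(self) -> "FeatureVector":
        return vectorize_lower_triangle(self)


@dataclass
class FeatureVector:
    """Vectorized strict lower triangle of an FC matrix (canonical order)."""

    values: np.ndarray
    participant_id: str = ""
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()

    def __len__(self) -> int:
        return self.values.size

    def normalize(self) -> "FeatureVector":
        out = normalize_features(self.values[None, :])[0]
        return FeatureVector(out, self.participant_id, normalized=True)


def _check_symmetric(m: np.ndarray, tol: float = SYMMETRY_TOL) -> None:
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValidationError(f"FC matrix must be square, got shape {m.shape}")
    if m.shape[0] < 2:
        raise ValidationError("FC matrix needs at least 2 parcels")
    asym = np.abs(m - m.T)
    ij = np.unravel_index(np.argmax(asym), asym.shape)
    if asym[ij] > tol:
        raise ValidationError(
            f"FC matrix is asymmetric at entry {ij}: "
            f"|M[i,j] - M[j,i]| = {asym[ij]:.3e} > {tol:.1e}"
        )


def vectorize_lower_triangle(fc: FCMatrix | np.ndarray) -> FeatureVector:
    """Vectorize the strict lower triangle of a symmetric matrix.

    Returns the entries (i, j) with i > j in row-major order.  A 419 x 419
    matrix yields a length-87,571 vector.
    """
    if isinstance(fc, FCMatrix):
        values, pid = fc.values, fc.participant_id
    else:
        values, pid = np.asarray(fc, dtype=float), ""
        _check_symmetric(values)
    p = values.shape[0]
    rows, cols = np.tril_indices(p, k=-1)
    return FeatureVector(values[rows, cols], pid, normalized=False)


def devectorize(vec: FeatureVector | np.ndarray, diagonal: float = 1.0) -> np.ndarray:
    """Rebuild the symmetric matrix whose strict lower triangle is ``vec``.

    The inverse of :func:`vectorize_lower_triangle` up to the diagonal, which
    is filled with ``diagonal``.
    """
    v = vec.values if isinstance(vec, FeatureVector) else np.asarray(vec, dtype=float)
    p = n_parcels(v.size)
    m = np.full((p, p), 0.0)
    rows, cols = np.tril_indices(p, k=-1)
    m[rows, cols] = v
    m = m + m.T
    np.fill_diagonal(m, diagonal)
    return m


def normalize_features(x: np.ndarray) -> np.ndarray:
    """Demean each row and scale it to unit L2-norm.

    ``x`` is (n_participants, n_edges); a 1-D vector is treated as one row
    and returned 1-D.  Idempotent.  Raises :class:`DegenerateInputError` for
    constant rows (zero norm after demeaning).
    """
    x = np.asarray(x, dtype=float)
    one_d = x.ndim == 1
    x = np.atleast_2d(x)
    if x.shape[1] < 2:
        raise ValidationError("need at least 2 features to normalize")
    centered = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    bad = np.flatnonzero(norms <= 0)
    if bad.size:
        raise DegenerateInputError(
            f"constant feature vector(s) at row(s) {bad.tolist()}: "
            "zero norm after demeaning"
        )
    out = centered / norms[:, None]
    return out[0] if one_d else out


def correlation_kernel(a: np.ndarray, b: np.ndarray | None = None) -> np.ndarray:
    """Pearson-correlation kernel between rows of ``a`` and rows of ``b``.

    Entry (i, j) is the Pearson correlation of row i of ``a`` with row j of
    ``b`` (``b`` defaults to ``a``).  Values lie in [-1, 1] and k(x, x) = 1.
    Because each row is standardized internally, the kernel is invariant to
    any per-row affine rescaling of the inputs — in particular to
    :func:`normalize_features`.
    """
    an = normalize_features(np.atleast_2d(np.asarray(a, dtype=float)))
    bn = an if b is None else normalize_features(np.atleast_2d(np.asarray(b, dtype=float)))
    if an.shape[1] != bn.shape[1]:
        raise ValidationError(
            f"feature length mismatch: {an.shape[1]} vs {bn.shape[1]}"
        )
    k = an @ bn.T
    return np.clip(k, -1.0, 1.0)
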