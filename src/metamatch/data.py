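"""In-memory containers for datasets: phenotype tables and source datasets.

A :class:`PhenotypeTable` is an N x T value matrix with an explicit
missingness mask — real phenotype batteries are rarely complete, and every
learner in this package trains per phenotype on the observed rows only.
A :class:`SourceDataset` bundles the table with the participants' FC feature
vectors and an 80/20 train/validation split.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ValidationError

__all__ = ["PhenotypeTable", "SourceDataset", "make_split"]

SIZE_CLASSES = ("extra_large", "large", "medium")

#: default sample-size thresholds for assigning a size class
SIZE_CLASS_THRESHOLDS = {"extra_large": 10_000, "large": 2_000}


def size_class_for(n: int) -> str:
    if n >= SIZE_CLASS_THRESHOLDS["extra_large"]:
        return "extra_large"
    if n >= SIZE_CLASS_THRESHOLDS["large"]:
        return "large"
    return "medium"


@dataclass
class PhenotypeTable:
    """Participants x phenotypes with an observedness mask (True = observed)."""

    values: np.ndarray
    mask: np.ndarray
    participant_ids: list[str]
    phenotype_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        n, t = self.values.shape
        if self.mask.shape != (n, t):
            raise ValidationError(
                f"mask shape {self.mask.shape} != values shape {(n, t)}"
            )
        if len(self.participant_ids) != n or len(self.phenotype_names) != t:
            raise ValidationError("label lengths do not match table shape")
        if not np.all(np.isfinite(self.values[self.mask])):
            raise ValidationError("non-finite value in an observed cell")
        if t and n:
            if not self.mask.any(axis=1).all():
                raise ValidationError("a participant has no observed phenotype")
            if not self.mask.any(axis=0).all():
                raise ValidationError("a phenotype has no observed participant")

    @property
    def n_participants(self) -> int:
        return self.values.shape[0]

    @property
    def n_phenotypes(self) -> int:
        return self.values.shape[1]

    def column(self, name_or_idx: str | int) -> tuple[np.ndarray, np.ndarray]:
        """One phenotype's (values, mask) pair."""
        j = (
            self.phenotype_names.index(name_or_idx)
            if isinstance(name_or_idx, str)
            else int(name_or_idx)
        )
        return self.values[:, j], self.mask[:, j]

    def to_frame(self) -> pd.DataFrame:
        """Tidy frame with NaN in unobserved cells (for CSV round-trips)."""
        vals = np.where(self.mask, self.values, np.nan)
        df = pd.DataFrame(vals, columns=self.phenotype_names)
        df.insert(0, "participant_id", self.participant_ids)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PhenotypeTable":
        if "participant_id" not in df.columns:
            raise ValidationError("phenotype table needs a participant_id column")
        ids = df["participant_id"].astype(str).tolist()
        body = df.drop(columns=["participant_id"]).astype(float)
        vals = body.to_numpy()
        mask = np.isfinite(vals)
        return cls(np.where(mask, vals, 0.0), mask, ids, list(body.columns))


def make_split(n: int, rng: np.random.Generator, train_fraction: float = 0.8) -> tuple[np.ndarray, np.ndarray]:
    """Random disjoint train/validation index split (completely random: no
    demographic matching, mirroring how source datasets are split here)."""
    perm = rng.permutation(n)
    n_train = int(round(train_fraction * n))
    n_train = min(max(n_train, 1), n - 1) if n > 1 else n
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


@dataclass
class SourceDataset:
    """One dataset: normalized FC features, phenotypes, and an 80/20 split."""

    name: str
    features: np.ndarray  # (N, E), expected normalized for cross-dataset use
    phenotypes: PhenotypeTable
    size_class: str = "medium"
    train_idx: np.ndarray | None = None
    val_idx: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.shape[0] != self.phenotypes.n_participants:
            raise ValidationError(
                f"{self.features.shape[0]} feature rows vs "
                f"{self.phenotypes.n_participants} phenotype rows"
            )
        if self.size_class not in SIZE_CLASSES:
            raise ValidationError(f"unknown size class {self.size_class!r}")
        if self.train_idx is not None and self.val_idx is not None:
            tr = np.asarray(self.train_idx)
            va = np.asarray(self.val_idx)
            if np.intersect1d(tr, va).size:
                raise ValidationError("train and validation indices overlap")
            self.train_idx, self.val_idx = tr, va

    @property
    def n_participants(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def ensure_split(self, rng: np.random.Generator) -> None:
        if self.train_idx is None or self.val_idx is None:
            self.train_idx, self.val_idx = make_split(self.n_participants, rng)
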