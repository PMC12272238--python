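"""Meta-matching: translating source-dataset predictors to new phenotypes.

The premise is that a phenotype collected in a small target study is usually
correlated with phenotypes available in larger source datasets, so a model
trained to predict *source* phenotypes from functional connectivity carries
information about the *target* phenotype.  Meta-matching exploits this with
stacking: apply the source models to the K available target participants,
then train a correlation-kernel KRR meta-learner that maps the resulting
prediction vector to the target phenotype.

Three variants are implemented, differing in which prediction features feed
the final stack:

* **single-source stacking** — only the extra-large dataset's multi-output
  network (optionally also its per-phenotype linear ridge models);
* **dataset stacking** — the extra-large network + ridge models plus each
  smaller dataset's ridge models, all trained independently;
* **multilayer meta-matching** — as dataset stacking, but each smaller
  dataset additionally contributes *stacked* predictions: per-phenotype KRR
  models trained on that dataset to predict its phenotypes from the larger
  datasets' predictions (large datasets stack on the extra-large block;
  medium datasets stack on the extra-large block plus the large datasets'
  ridge predictions).  This doubles each smaller dataset's contribution.

With the reference configuration of five sources exposing 67/36/23/42/61
phenotypes, single-source stacking uses 67 (or 134) features, dataset
stacking 2*67 + 36 + 23 + 42 + 61 = 296, and multilayer meta-matching
134 + 72 + 46 + 84 + 122 = 458.

Every prediction column carries a (dataset, family, phenotype) label; the
canonical column order is dataset order (extra-large, then large, then
medium, preserving input order within a class), then family
(mlp, lrr, stack), then the dataset's phenotype order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seeds import stage_rng
from .data import SourceDataset
from .exceptions import (
    ConfigurationError,
    ProtocolError,
    StateError,
    ValidationError,
)
from .learners import (
    DEFAULT_LAMBDA_GRID,
    KRRModel,
    LRRModel,
    fit_krr_tuned,
    fit_lrr,
)
from .mlp import MLPConfig, MLPModel, train_mlp_arrays

__all__ = [
    "ColumnLabel",
    "BaseLearnerBundle",
    "StackingModel",
    "MultilayerModel",
    "AdaptedModel",
    "train_bundle",
    "train_multilayer",
    "fit_stacking",
    "adapt",
    "VARIANTS",
]

FAMILY_ORDER = ("mlp", "lrr", "stack")
VARIANTS = ("stacking", "dataset_stacking", "multilayer")

#: floor for target standard deviations when z-scoring phenotypes
_SD_FLOOR = 1e-12

ColumnLabel = tuple[str, str, str]  # (dataset, family, phenotype)


@dataclass
class BaseLearnerBundle:
    """Trained direct predictors for one source dataset.

    Extra-large datasets expose two model families (a multi-output MLP and
    per-phenotype LRR); large/medium datasets expose LRR only (their second,
    stacked family lives in the :class:`MultilayerModel`).  Phenotypes are
    z-scored with train-split statistics before fitting and predictions are
    returned on the original scale.
    """

    dataset_name: str
    size_class: str
    phenotype_names: list[str]
    mlp: MLPModel | None
    lrr: list[LRRModel]
    target_means: np.ndarray
    target_sds: np.ndarray

    def __post_init__(self) -> None:
        if self.size_class == "extra_large" and self.mlp is None:
            raise ConfigurationError(
                f"extra-large bundle {self.dataset_name!r} requires an MLP"
            )
        if len(self.lrr) != len(self.phenotype_names):
            raise ValidationError("one LRR model per phenotype is required")

    @property
    def n_phenotypes(self) -> int:
        return len(self.phenotype_names)

    @property
    def families(self) -> tuple[str, ...]:
        return ("mlp", "lrr") if self.mlp is not None else ("lrr",)

    def labels(self, family: str) -> list[ColumnLabel]:
        return [(self.dataset_name, family, p) for p in self.phenotype_names]

    def predict_family(self, family: str, features: np.ndarray) -> np.ndarray:
        """De-standardized predictions (n, T) from one model family."""
        if family == "mlp":
            if self.mlp is None:
                raise StateError(f"bundle {self.dataset_name!r} has no MLP")
            z = self.mlp.predict(features)
        elif family == "lrr":
            z = np.column_stack([m.predict(features) for m in self.lrr])
        else:
            raise ValidationError(f"unknown family {family!r}")
        return z * self.target_sds + self.target_means

    def predict_direct(self, features: np.ndarray) -> tuple[np.ndarray, list[ColumnLabel]]:
        """All direct predictions of this bundle, canonical family order."""
        blocks, labels = [], []
        for family in self.families:
            blocks.append(self.predict_family(family, features))
            labels.extend(self.labels(family))
        return np.column_stack(blocks), labels


@dataclass
class StackingModel:
    """A correlation-kernel KRR meta-learner over prediction features."""

    krr: KRRModel
    input_labels: list[ColumnLabel]
    target_name: str

    def predict(self, prediction_features: np.ndarray) -> np.ndarray:
        f = np.atleast_2d(np.asarray(prediction_features, dtype=float))
        if f.shape[1] != len(self.input_labels):
            raise ValidationError(
                f"stacking model expects {len(self.input_labels)} input "
                f"columns, got {f.shape[1]}"
            )
        return self.krr.predict(f)


def fit_stacking(
    prediction_features: np.ndarray,
    target: np.ndarray,
    lambda_grid: np.ndarray = DEFAULT_LAMBDA_GRID,
    seed: int = 0,
    rng: np.random.Generator | None = None,
    input_labels: list[ColumnLabel] | None = None,
    target_name: str = "target",
    n_folds: int = 5,
) -> StackingModel:
    """Train the stacking meta-learner on K participants' prediction features.

    All feature columns are always used (no truncation at small K); lambda is
    chosen by 5-fold CV on the K participants and the final model is refit on
    all of them.
    """
    f = np.atleast_2d(np.asarray(prediction_features, dtype=float))
    y = np.asarray(target, dtype=float).ravel()
    if f.shape[0] != y.size:
        raise ValidationError("prediction features and target disagree on K")
    if f.shape[0] < n_folds:
        raise ProtocolError(
            f"stacking needs at least {n_folds} participants for "
            f"{n_folds}-fold CV, got {f.shape[0]}"
        )
    if f.shape[1] < 2:
        raise ValidationError(
            "the correlation kernel over prediction features needs >= 2 columns"
        )
    if input_labels is None:
        input_labels = [("", "", f"col_{j}") for j in range(f.shape[1])]
    krr = fit_krr_tuned(
        f, y, lambda_grid, n_folds=n_folds, rng=rng, seed=seed, target_name=target_name
    )
    return StackingModel(krr, list(input_labels), target_name)


# ---------------------------------------------------------------------------
# bundle training
# ---------------------------------------------------------------------------


def train_bundle(
    dataset: SourceDataset,
    seed: int = 0,
    mlp_config: MLPConfig | None = None,
    lambda_grid: np.ndarray = DEFAULT_LAMBDA_GRID,
) -> BaseLearnerBundle:
    """Train the direct predictors for one source dataset.

    Extra-large datasets: the MLP trains on the 80% split with the 20% split
    for early stopping, and per-phenotype LRR models are CV-tuned on the 80%
    split.  Large/medium datasets: per-phenotype LRR CV-tuned on the full
    dataset.  Phenotypes are z-scored with train-split statistics.
    """
    ds = dataset
    ds.ensure_split(stage_rng(seed, "split", ds.name))
    pt = ds.phenotypes
    tr = ds.train_idx

    # train-split z-statistics per phenotype (observed entries only)
    means = np.empty(pt.n_phenotypes)
    sds = np.empty(pt.n_phenotypes)
    for j in range(pt.n_phenotypes):
        obs = pt.mask[tr, j]
        vals = pt.values[tr, j][obs]
        if vals.size == 0:  # fall back to all observed rows
            vals = pt.values[pt.mask[:, j], j]
        means[j] = vals.mean()
        sds[j] = max(vals.std(), _SD_FLOOR)
    z = (pt.values - means) / sds

    mlp = None
    if ds.size_class == "extra_large":
        cfg = mlp_config or MLPConfig()
        mlp_seed = int(stage_rng(seed, "mlp_seed", ds.name).integers(2**31))
        va = ds.val_idx
        mlp, _ = train_mlp_arrays(
            ds.features[tr], z[tr], pt.mask[tr],
            ds.features[va], z[va], pt.mask[va],
            cfg, seed=mlp_seed,
        )
        lrr_rows = tr
    else:
        lrr_rows = np.arange(ds.n_participants)

    lrr = []
    for j, name in enumerate(pt.phenotype_names):
        rng = stage_rng(seed, "lrr", ds.name, j)
        lrr.append(
            fit_lrr(
                ds.features[lrr_rows], z[lrr_rows, j], lambda_grid,
                rng=rng, mask=pt.mask[lrr_rows, j], target_name=name,
            )
        )
    return BaseLearnerBundle(
        ds.name, ds.size_class, list(pt.phenotype_names), mlp, lrr, means, sds
    )


# ---------------------------------------------------------------------------
# the multilayer model
# ---------------------------------------------------------------------------


@dataclass
class MultilayerModel:
    """Bundles plus intermediate stackers; maps FC features to the full
    concatenated prediction-feature matrix."""

    bundles: list[BaseLearnerBundle]
    stackers: dict[str, list[StackingModel]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.by_class("extra_large"):
            raise ConfigurationError("at least one extra-large dataset is required")

    def by_class(self, size_class: str) -> list[BaseLearnerBundle]:
        return [b for b in self.bundles if b.size_class == size_class]

    # -- feature blocks -----------------------------------------------------

    def xl_block(self, features: np.ndarray) -> tuple[np.ndarray, list[ColumnLabel]]:
        """MLP + LRR predictions of every extra-large bundle (134-style)."""
        blocks, labels = [], []
        for b in self.by_class("extra_large"):
            m, lab = b.predict_direct(features)
            blocks.append(m)
            labels.extend(lab)
        return np.column_stack(blocks), labels

    def large_lrr_block(self, features: np.ndarray) -> tuple[np.ndarray, list[ColumnLabel]]:
        blocks, labels = [], []
        for b in self.by_class("large"):
            blocks.append(b.predict_family("lrr", features))
            labels.extend(b.labels("lrr"))
        if not blocks:
            return np.empty((np.atleast_2d(features).shape[0], 0)), []
        return np.column_stack(blocks), labels

    def stacker_inputs(self, size_class: str, features: np.ndarray) -> tuple[np.ndarray, list[ColumnLabel]]:
        """Upstream prediction features consumed by a class's stackers."""
        xl, xl_lab = self.xl_block(features)
        if size_class == "large":
            return xl, xl_lab
        if size_class == "medium":
            lg, lg_lab = self.large_lrr_block(features)
            return np.column_stack([xl, lg]) if lg.shape[1] else xl, xl_lab + lg_lab
        raise ValidationError(f"no stackers for size class {size_class!r}")

    def features(self, features: np.ndarray) -> tuple[np.ndarray, list[ColumnLabel]]:
        """The full multilayer prediction-feature matrix (458-style)."""
        features = np.atleast_2d(np.asarray(features, dtype=float))
        blocks, labels = [], []
        xl, xl_lab = self.xl_block(features)
        blocks.append(xl)
        labels.extend(xl_lab)
        upstream: dict[str, np.ndarray] = {}
        for size_class in ("large", "medium"):
            members = self.by_class(size_class)
            if not members:
                continue
            upstream[size_class], _ = self.stacker_inputs(size_class, features)
            for b in members:
                blocks.append(b.predict_family("lrr", features))
                labels.extend(b.labels("lrr"))
                stackers = self.stackers.get(b.dataset_name)
                if stackers is None:
                    raise StateError(
                        f"no intermediate stackers trained for {b.dataset_name!r}"
                    )
                stacked = np.column_stack(
                    [s.predict(upstream[size_class]) for s in stackers]
                )
                blocks.append(stacked)
                labels.extend(b.labels("stack"))
        return np.column_stack(blocks), labels

    def dataset_stacking_features(self, features: np.ndarray) -> tuple[np.ndarray, list[ColumnLabel]]:
        """Direct predictions only (296-style): xl MLP+LRR, others LRR."""
        features = np.atleast_2d(np.asarray(features, dtype=float))
        blocks, labels = [], []
        xl, xl_lab = self.xl_block(features)
        blocks.append(xl)
        labels.extend(xl_lab)
        for size_class in ("large", "medium"):
            for b in self.by_class(size_class):
                blocks.append(b.predict_family("lrr", features))
                labels.extend(b.labels("lrr"))
        return np.column_stack(blocks), labels

    def single_source_features(
        self, features: np.ndarray, include_lrr: bool = False
    ) -> tuple[np.ndarray, list[ColumnLabel]]:
        """Extra-large predictions only: MLP (67-style) or MLP+LRR (134)."""
        features = np.atleast_2d(np.asarray(features, dtype=float))
        blocks, labels = [], []
        for b in self.by_class("extra_large"):
            fams = ("mlp", "lrr") if include_lrr else ("mlp",)
            for fam in fams:
                blocks.append(b.predict_family(fam, features))
                labels.extend(b.labels(fam))
        return np.column_stack(blocks), labels

    def features_for_variant(
        self, variant: str, features: np.ndarray, include_xl_lrr: bool = False
    ) -> tuple[np.ndarray, list[ColumnLabel]]:
        if variant == "stacking":
            return self.single_source_features(features, include_lrr=include_xl_lrr)
        if variant == "dataset_stacking":
            return self.dataset_stacking_features(features)
        if variant == "multilayer":
            return self.features(features)
        raise ConfigurationError(f"unknown variant {variant!r}; choose from {VARIANTS}")

    # -- bookkeeping --------------------------------------------------------

    @property
    def total_feature_count(self) -> int:
        """Multilayer column count: 2*T for every dataset (two families each)."""
        return sum(2 * b.n_phenotypes for b in self.bundles)

    @property
    def dataset_stacking_count(self) -> int:
        return sum(
            2 * b.n_phenotypes if b.size_class == "extra_large" else b.n_phenotypes
            for b in self.bundles
        )


def train_multilayer(
    source_datasets: list[SourceDataset],
    seed: int = 0,
    mlp_config: MLPConfig | None = None,
    lambda_grid: np.ndarray = DEFAULT_LAMBDA_GRID,
) -> MultilayerModel:
    """Train bundles for every source dataset plus the intermediate stackers.

    Dataset order is normalized to extra-large, large, medium (input order
    preserved within each class).  Intermediate stackers for a large/medium
    dataset are trained per phenotype on that dataset's full sample (rows
    with the phenotype observed), with lambda tuned by 5-fold CV there.
    """
    by_class = {c: [d for d in source_datasets if d.size_class == c]
                for c in ("extra_large", "large", "medium")}
    if not by_class["extra_large"]:
        raise ConfigurationError(
            "multilayer meta-matching requires at least one extra-large dataset"
        )
    ordered = by_class["extra_large"] + by_class["large"] + by_class["medium"]
    bundles = [
        train_bundle(d, seed=seed, mlp_config=mlp_config, lambda_grid=lambda_grid)
        for d in ordered
    ]
    model = MultilayerModel(bundles)

    stackers: dict[str, list[StackingModel]] = {}
    for size_class in ("large", "medium"):
        for ds in by_class[size_class]:
            inputs, in_labels = model.stacker_inputs(size_class, ds.features)
            per_pheno = []
            for j, name in enumerate(ds.phenotypes.phenotype_names):
                y, obs_mask = ds.phenotypes.values[:, j], ds.phenotypes.mask[:, j]
                obs = np.flatnonzero(obs_mask)
                rng = stage_rng(seed, "stacker", ds.name, j)
                per_pheno.append(
                    fit_stacking(
                        inputs[obs], y[obs], lambda_grid, rng=rng,
                        input_labels=in_labels,
                        target_name=f"{ds.name}:{name}",
                    )
                )
            stackers[ds.name] = per_pheno
    model.stackers = stackers
    return model


# ---------------------------------------------------------------------------
# K-shot adaptation
# ---------------------------------------------------------------------------


@dataclass
class AdaptedModel:
    """A multilayer/dataset-stacking/single-source model adapted to one
    target phenotype with K participants."""

    variant: str
    model: MultilayerModel
    stacker: StackingModel
    include_xl_lrr: bool = False

    def predict(self, features: np.ndarray) -> np.ndarray:
        f, _ = self.model.features_for_variant(
            self.variant, features, include_xl_lrr=self.include_xl_lrr
        )
        return self.stacker.predict(f)


def adapt(
    variant: str,
    model: MultilayerModel,
    kshot_features: np.ndarray,
    kshot_target: np.ndarray,
    lambda_grid: np.ndarray = DEFAULT_LAMBDA_GRID,
    seed: int = 0,
    rng: np.random.Generator | None = None,
    include_xl_lrr: bool = False,
    target_name: str = "target",
) -> AdaptedModel:
    """Adapt a trained model to a new phenotype from K labeled participants."""
    f, labels = model.features_for_variant(
        variant, kshot_features, include_xl_lrr=include_xl_lrr
    )
    stacker = fit_stacking(
        f, kshot_target, lambda_grid, seed=seed, rng=rng,
        input_labels=labels, target_name=target_name,
    )
    return AdaptedModel(variant, model, stacker, include_xl_lrr)
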