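"""Synthetic multi-dataset connectome-phenotype collections.

The generator produces the statistical structure meta-matching exploits,
without any real data: per participant a latent trait vector z ~ N(0, I_L)
drives both the FC feature vector and the phenotypes,

    x = rownorm(A_d) z + shift_d * 1 + eps,   eps ~ N(0, sigma_x^2 I_E)
    y_t = b_{d,t} . z + eta,                  eta ~ N(0, sigma_y^2)

where A_d is a dataset-specific loading matrix sharing a common core across
datasets (a small dataset-specific tilt models site/pipeline differences in
how traits express in connectivity), and each phenotype direction mixes a
*shared prototype* with a dataset-unique direction,

    b_{d,t} = unit( c * s_{t mod L} + (1 - c) * u_{d,t} ),

with c = ``cross_loading_strength``.  Shared prototypes make phenotype
batteries in different datasets latently correlated — the premise that a
small study's phenotype correlates with some phenotype measured in a large
population dataset.  At c = 0 target phenotypes carry no transferable
relation to source phenotypes; at c = 1 with zero noise they are exact
functions of the recoverable latents.

``feature_shift`` adds a constant offset to every edge of a dataset,
emulating pipelines that do or do not center the FC distribution at zero;
per-participant normalization must (and does) erase it.  Missingness is
applied completely at random at the configured rate, then repaired
minimally so every participant keeps >= 1 observed phenotype and every
phenotype >= 1 observed participant.

Everything is deterministic given the config seed: population-level
parameters (common core, shared prototypes) derive from the seed alone, and
each dataset's parameters and noise derive from (seed, dataset name).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seeds import stage_rng
from .data import PhenotypeTable, SourceDataset
from .exceptions import ValidationError
from .features import devectorize, n_edges, normalize_features

__all__ = ["DatasetSpec", "SimulationConfig", "simulate_collection", "default_suite"]

#: magnitude of the dataset-specific tilt added to the common FC loading core
LOADING_TILT = 0.25


@dataclass
class DatasetSpec:
    """Size, phenotype battery, and noise levels for one simulated dataset."""

    name: str
    n: int
    t: int
    size_class: str = "medium"
    feature_shift: float = 0.0
    noise_sd_features: float = 1.0
    noise_sd_phenotypes: float = 0.5
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 10:
            raise ValidationError(f"{self.name}: need n >= 10, got {self.n}")
        if self.t < 1:
            raise ValidationError(f"{self.name}: need t >= 1")
        if not 0.0 <= self.missing_rate <= 0.9:
            raise ValidationError(f"{self.name}: missing_rate must be in [0, 0.9]")


@dataclass
class SimulationConfig:
    p: int = 40
    l: int = 6
    datasets: list[DatasetSpec] = field(default_factory=list)
    target: DatasetSpec | None = None
    cross_loading_strength: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.p < 2:
            raise ValidationError("need p >= 2 parcels")
        if self.l < 1:
            raise ValidationError("need l >= 1 latent factors")
        if not 0.0 <= self.cross_loading_strength <= 1.0:
            raise ValidationError("cross_loading_strength must be in [0, 1]")
        if self.target is None:
            raise ValidationError("a target dataset spec is required")
        names = [d.name for d in self.datasets] + [self.target.name]
        if len(set(names)) != len(names):
            raise ValidationError("dataset names must be unique")


def _unit_rows(m: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(m, axis=1, keepdims=True)
    return m / np.maximum(norms, 1e-300)


def _repair_mask(mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Flip the minimum number of cells so no row/column is all-missing."""
    mask = mask.copy()
    for i in np.flatnonzero(~mask.any(axis=1)):
        mask[i, rng.integers(mask.shape[1])] = True
    for j in np.flatnonzero(~mask.any(axis=0)):
        mask[rng.integers(mask.shape[0]), j] = True
    return mask


def _simulate_dataset(
    spec: DatasetSpec,
    config: SimulationConfig,
    core: np.ndarray,
    prototypes: np.ndarray,
) -> SourceDataset:
    e = n_edges(config.p)
    c = config.cross_loading_strength
    rng = stage_rng(config.seed, "dataset", spec.name)

    # dataset-tilted FC loading matrix, rows unit-norm so edge signal var = 1
    tilt = rng.normal(0.0, 1.0, size=(e, config.l))
    a_d = _unit_rows(core + LOADING_TILT * tilt)

    # phenotype directions: shared prototype (weight c) + unique part (1 - c)
    unique = _unit_rows(rng.normal(0.0, 1.0, size=(spec.t, config.l)))
    shared = prototypes[np.arange(spec.t) % prototypes.shape[0]]
    b_d = _unit_rows(c * shared + (1.0 - c) * unique)

    z = rng.normal(0.0, 1.0, size=(spec.n, config.l))
    x = z @ a_d.T + spec.feature_shift
    if spec.noise_sd_features > 0:
        x = x + rng.normal(0.0, spec.noise_sd_features, size=x.shape)
    y = z @ b_d.T
    if spec.noise_sd_phenotypes > 0:
        y = y + rng.normal(0.0, spec.noise_sd_phenotypes, size=y.shape)

    if spec.missing_rate > 0:
        mask = rng.random(y.shape) >= spec.missing_rate
        mask = _repair_mask(mask, rng)
    else:
        mask = np.ones(y.shape, dtype=bool)

    ids = [f"{spec.name}_{i:05d}" for i in range(spec.n)]
    names = [f"{spec.name}_pheno_{j:02d}" for j in range(spec.t)]
    table = PhenotypeTable(np.where(mask, y, 0.0), mask, ids, names)
    ds = SourceDataset(
        spec.name, normalize_features(x), table, size_class=spec.size_class
    )
    ds.ensure_split(stage_rng(config.seed, "split", spec.name))
    # generative internals, exposed for validation and property checks
    ds.raw_features = x  # pre-normalization vectors, for FC reconstruction
    ds.latents = z
    ds.loadings = a_d
    ds.phenotype_directions = b_d
    return ds


def fc_matrices(dataset: SourceDataset) -> np.ndarray:
    """Symmetric (n, P, P) FC matrices rebuilt from the raw feature vectors."""
    raw = getattr(dataset, "raw_features", dataset.features)
    return np.stack([devectorize(v) for v in raw])


def simulate_collection(
    config: SimulationConfig,
) -> tuple[list[SourceDataset], SourceDataset]:
    """Generate (source datasets, target dataset) from one config."""
    e = n_edges(config.p)
    pop_rng = stage_rng(config.seed, "population")
    core = pop_rng.normal(0.0, 1.0, size=(e, config.l))
    prototypes = _unit_rows(pop_rng.normal(0.0, 1.0, size=(config.l, config.l)))
    sources = [
        _simulate_dataset(spec, config, core, prototypes) for spec in config.datasets
    ]
    target = _simulate_dataset(config.target, config, core, prototypes)
    return sources, target


def default_suite_config(seed: int = 0) -> SimulationConfig:
    """The canonical desk-scale scenario: five sources whose sample sizes
    span a ~13:1 ratio, one target, moderate noise.

    The extra-large source is pipeline-centered (zero feature shift); the
    others carry a non-zero shift, exercising the normalization contract.
    """
    src = [
        DatasetSpec("src_xl", 4000, 20, "extra_large", 0.0, 8.0, 0.5, 0.1),
        DatasetSpec("src_large", 1500, 12, "large", 0.3, 8.0, 0.5, 0.1),
        DatasetSpec("src_med_a", 300, 8, "medium", 0.3, 8.0, 0.5, 0.1),
        DatasetSpec("src_med_b", 300, 8, "medium", 0.3, 8.0, 0.5, 0.1),
        DatasetSpec("src_med_c", 300, 8, "medium", 0.3, 8.0, 0.5, 0.1),
    ]
    target = DatasetSpec("target", 600, 10, "medium", 0.3, 8.0, 0.5, 0.0)
    return SimulationConfig(
        p=40, l=6, datasets=src, target=target,
        cross_loading_strength=0.7, seed=seed,
    )


def default_suite(seed: int = 0) -> tuple[list[SourceDataset], SourceDataset]:
    """Generate the canonical scenario (see :func:`default_suite_config`)."""
    return simulate_collection(default_suite_config(seed))


def tiny_suite_config(seed: int = 0) -> SimulationConfig:
    """A minutes-free miniature of the default suite for smoke tests and
    quick pipeline runs: three sources (one per size class), tiny target."""
    src = [
        DatasetSpec("src_xl", 160, 4, "extra_large", 0.0, 0.8, 0.4, 0.0),
        DatasetSpec("src_large", 100, 3, "large", 0.3, 0.8, 0.4, 0.0),
        DatasetSpec("src_med", 60, 2, "medium", 0.3, 0.8, 0.4, 0.0),
    ]
    target = DatasetSpec("target", 80, 2, "medium", 0.3, 0.8, 0.4, 0.0)
    return SimulationConfig(
        p=10, l=3, datasets=src, target=target,
        cross_loading_strength=0.7, seed=seed,
    )
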