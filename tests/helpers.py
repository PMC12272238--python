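"""Small builders for custom synthetic collections used across tests."""

from __future__ import annotations

import numpy as np

from metamatch.data import PhenotypeTable, SourceDataset
from metamatch.features import normalize_features
from metamatch.simulate import DatasetSpec, SimulationConfig, simulate_collection


def make_latent_collection(
    seed: int,
    specs: list[tuple[str, int, int, str]],
    target_spec: tuple[str, int, int] = ("tgt", 200, 2),
    noise_sd_features: float = 4.0,
    noise_sd_phenotypes: float = 0.3,
    cross_loading: float = 0.8,
    p: int = 10,
    l: int = 4,
):
    """A custom collection from (name, N, T, size_class) specs.

    ``cross_loading=1.0`` makes every phenotype direction exactly its shared
    prototype, so target phenotype j is the same latent score as the source
    phenotypes with matching prototype plus independent noise (the oracle
    phenotype scenario).
    """
    datasets = [
        DatasetSpec(
            name, n, t, cls,
            feature_shift=0.0 if cls == "extra_large" else 0.2,
            noise_sd_features=noise_sd_features,
            noise_sd_phenotypes=noise_sd_phenotypes,
        )
        for name, n, t, cls in specs
    ]
    target = DatasetSpec(
        *target_spec, "medium",
        feature_shift=0.2,
        noise_sd_features=noise_sd_features,
        noise_sd_phenotypes=noise_sd_phenotypes,
    )
    cfg = SimulationConfig(
        p=p, l=l, datasets=datasets, target=target,
        cross_loading_strength=cross_loading, seed=seed,
    )
    return simulate_collection(cfg)


def make_noise_dataset(rng: np.random.Generator, n_features: int, n: int = 80, t: int = 3):
    """A medium dataset whose phenotypes are pure noise (nothing to transfer)."""
    x = rng.normal(size=(n, n_features))
    y = rng.normal(size=(n, t))
    table = PhenotypeTable(
        y, np.ones_like(y, dtype=bool),
        [f"noise_{i}" for i in range(n)],
        [f"noise_pheno_{j}" for j in range(t)],
    )
    return SourceDataset("noise_ds", normalize_features(x), table, "medium")
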