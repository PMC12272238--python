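"""Shared fixtures.

The expensive pieces — the canonical synthetic suite, its trained multilayer
model, and the paired K-shot evaluation grid — are session-scoped so the
directional and importance checks share one run.
"""

from __future__ import annotations

import numpy as np
import pytest

import metamatch as mm
from metamatch.approaches import default_approaches
from metamatch.mlp import MLPConfig
from metamatch.simulate import tiny_suite_config
from metamatch.stacking import train_multilayer

SUITE_SEED = 20260930

#: small architecture for tests that train the network but do not study it
TINY_MLP = MLPConfig(hidden_sizes=(32, 16, 8), max_epochs=30, patience=5)


@pytest.fixture(scope="session")
def tiny_collection():
    return mm.simulate_collection(tiny_suite_config(SUITE_SEED))


@pytest.fixture(scope="session")
def tiny_model(tiny_collection):
    sources, _ = tiny_collection
    return train_multilayer(sources, seed=SUITE_SEED, mlp_config=TINY_MLP)


@pytest.fixture(scope="session")
def default_collection():
    return mm.default_suite(SUITE_SEED)


@pytest.fixture(scope="session")
def default_model(default_collection):
    sources, _ = default_collection
    return train_multilayer(sources, seed=SUITE_SEED)


@pytest.fixture(scope="session")
def default_eval(default_collection, default_model):
    """Paired K-shot grid on the canonical suite: 5 approaches,
    K in {10, 100}, 20 repetitions, all 10 target phenotypes."""
    _, target = default_collection
    approaches = default_approaches(default_model, target.features)
    result = mm.run_kshot_experiment(
        approaches,
        target.phenotypes.values,
        target.phenotypes.mask,
        target.phenotypes.phenotype_names,
        ks=[10, 100],
        n_repetitions=20,
        seed=SUITE_SEED,
        on_error="raise",
    )
    return result
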