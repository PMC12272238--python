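"""Deterministic seed fan-out.

Every source of randomness in the package derives from a single top-level
integer seed through :func:`stage_rng`.  A stage is identified by a sequence
of keys (strings or small integers); strings are hashed with CRC-32 so the
derivation is stable across processes and platforms.  Two runs with the same
top-level seed therefore replay identically, and distinct stages get
statistically independent streams via :class:`numpy.random.SeedSequence`.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stage_rng", "stage_seed"]


def _key_to_int(key: str | int) -> int:
    if isinstance(key, (int, np.integer)):
        if key < 0:
            raise ValueError("seed keys must be non-negative")
        return int(key)
    return zlib.crc32(str(key).encode("utf-8"))


def stage_seed(seed: int, *keys: str | int) -> np.random.SeedSequence:
    """Derive a SeedSequence for one named stage from the top-level seed."""
    entropy = [int(seed)] + [_key_to_int(k) for k in keys]
    return np.random.SeedSequence(entropy)


def stage_rng(seed: int, *keys: str | int) -> np.random.Generator:
    """A fresh Generator for the stage identified by ``keys``."""
    return np.random.default_rng(stage_seed(seed, *keys))
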