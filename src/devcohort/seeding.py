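"""Deterministic labeled random streams.

A single master seed is expanded into independent per-component streams
keyed by string labels, so adding one mechanism to a pipeline never
perturbs the draws of another.  Labels are hashed (SHA-256) into the seed
material, making the derivation order-independent and collision-resistant.
"""

from __future__ import annotations

import hashlib
from typing import Iterable

import numpy as np

__all__ = ["derive_seed_sequence", "derive_rng", "derive_seeds"]


def derive_seed_sequence(master_seed: int, label: str) -> np.random.SeedSequence:
    """Seed sequence for one labeled component stream."""
    digest = hashlib.sha256(label.encode("utf-8")).digest()
    words = [int(w) for w in np.frombuffer(digest[:16], dtype=np.uint32)]
    return np.random.SeedSequence([int(master_seed) & 0xFFFFFFFF, *words])


def derive_rng(master_seed: int, label: str) -> np.random.Generator:
    """Generator for one labeled component stream."""
    return np.random.default_rng(derive_seed_sequence(master_seed, label))


def derive_seeds(
    master_seed: int, labels: Iterable[str]
) -> dict[str, np.random.Generator]:
    """Independent generators for a set of unique component labels."""
    labels = list(labels)
    if len(set(labels)) != len(labels):
        raise ValueError("component labels must be unique")
    return {label: derive_rng(master_seed, label) for label in labels}
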