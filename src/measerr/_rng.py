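"""Seed handling: every stochastic entry point accepts an int seed, a
numpy SeedSequence, a Generator, or None (fresh OS entropy)."""

from __future__ import annotations

import numpy as np

SeedLike = "int | np.random.SeedSequence | np.random.Generator | None"


def as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def spawn(seed, n: int) -> list[np.random.SeedSequence]:
    """Derive n independent child seed sequences deterministically."""
    if isinstance(seed, np.random.SeedSequence):
        return seed.spawn(n)
    if isinstance(seed, np.random.Generator):
        return seed.bit_generator.seed_seq.spawn(n)  # type: ignore[attr-defined]
    return np.random.SeedSequence(seed).spawn(n)
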