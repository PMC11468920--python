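"""Seed handling: every stochastic function accepts either a seed or a Generator."""

from __future__ import annotations

import numpy as np

RngLike = "int | np.random.Generator | np.random.SeedSequence | None"


def as_rng(seed) -> np.random.Generator:
    """Coerce an int seed, SeedSequence, Generator or None to a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def spawn_seeds(seed: int, n: int) -> list[np.random.SeedSequence]:
    """Derive ``n`` independent child seed sequences from an integer seed."""
    return np.random.SeedSequence(seed).spawn(n)
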