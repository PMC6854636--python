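"""Seed handling: one user seed, split into independent streams.

Every stochastic routine takes a single integer seed and derives any
internal streams with :func:`spawn`, so a pipeline run is reproducible from
one number and parallel stages never share a stream.
"""

from __future__ import annotations

import numpy as np

__all__ = ["rng_from_seed", "spawn"]


def rng_from_seed(seed: int | np.random.Generator) -> np.random.Generator:
    """Return a Generator; pass through if already one."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(int(seed))


def spawn(seed: int, n: int) -> list[np.random.Generator]:
    """Split ``seed`` into ``n`` independent child generators."""
    ss = np.random.SeedSequence(int(seed))
    return [np.random.default_rng(child) for child in ss.spawn(n)]
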