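"""Deterministic seed splitting.

Every stochastic routine in the package takes an integer seed and, when it
needs several independent random streams, derives child seeds through
:func:`child_seeds`.  The split is done with :class:`numpy.random.SeedSequence`
so that streams spawned for different purposes (community generation,
contamination planting, literature sampling, bootstrap resampling, ...) are
statistically independent and bit-reproducible.
"""

from __future__ import annotations

import numpy as np

__all__ = ["child_seeds", "rng_from"]


def child_seeds(seed: int, n: int) -> list[int]:
    """Derive ``n`` independent integer child seeds from a master seed.

    Children are drawn from ``SeedSequence(seed).spawn(n)`` and folded to a
    single 31-bit integer each, so they can be passed around as plain ints.
    """
    if n < 0:
        raise ValueError("n must be nonnegative")
    children = np.random.SeedSequence(seed).spawn(n)
    return [int(c.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF) for c in children]


def rng_from(seed_or_rng: int | np.random.Generator) -> np.random.Generator:
    """Return a Generator: pass through an existing one, or seed a fresh one."""
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)
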