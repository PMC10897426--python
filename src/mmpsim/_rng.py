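"""Seed-derivation helpers.

All public mmpsim entry points take a single integer seed. Sub-streams
(replicates, generations) are derived from it with ``child_seeds`` rather
than ``SeedSequence.spawn``: spawning mutates the parent's spawn counter, so
reusing one SeedSequence object across, e.g., grid points would silently
break replay and common-random-number comparisons. ``child_seeds`` is a pure
function of (seed, n).
"""

from __future__ import annotations

import numpy as np

_MASK31 = (1 << 31) - 1


def child_seeds(seed: int, n: int) -> list[int]:
    """Derive ``n`` independent 31-bit integer seeds from ``seed``.

    Deterministic: identical (seed, n) always yields the same list, and the
    first k entries do not depend on n being larger than k.
    """
    state = np.random.SeedSequence(int(seed)).generate_state(n, dtype=np.uint64)
    return [int(s) & _MASK31 for s in state]


def rng_from(seed: int) -> np.random.Generator:
    """A fresh PCG64 generator for an integer seed."""
    return np.random.default_rng(int(seed))
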