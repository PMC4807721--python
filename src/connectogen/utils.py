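"""Small shared helpers (RNG plumbing)."""

from __future__ import annotations

import numpy as np


def as_rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    """Normalize a seed or Generator to a numpy Generator.

    Every stochastic operation in the package draws from an explicitly
    passed generator; global numpy state is never touched.
    """
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def spawn_seeds(seed: int | None, n: int) -> list[int]:
    """Derive ``n`` independent child seeds (< 2**31) from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n, dtype=np.uint64)]
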