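"""Shared helpers: seed handling and warning accounting."""
from __future__ import annotations

import numpy as np

MAX_SEED = 2**31 - 1


def rng_from_seed(seed: int | None) -> np.random.Generator:
    return np.random.default_rng(seed)


def spawn_seeds(seed: int | None, n: int) -> list[int]:
    """Derive `n` independent child seeds (each < 2^31) from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % MAX_SEED + 1 for s in ss.generate_state(n, dtype=np.uint64)]


def msprime_seed(rng: np.random.Generator) -> int:
    """msprime wants a strictly positive 32-bit seed."""
    return int(rng.integers(1, MAX_SEED))
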