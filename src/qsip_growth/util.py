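"""Small shared helpers: reproducible child seeds and rounding."""

from __future__ import annotations

import hashlib
import math

import numpy as np

MAX_SEED = 2**31 - 1


def derive_seed(seed: int, *tokens) -> int:
    """Derive a child seed from a master seed and a label path.

    Children are independent of call order: the same (seed, tokens) pair
    always yields the same child, so adding or removing other stochastic
    steps does not perturb results.
    """
    key = ":".join([str(int(seed))] + [str(t) for t in tokens])
    digest = hashlib.blake2b(key.encode(), digest_size=8).digest()
    return int.from_bytes(digest, "big") % MAX_SEED


def rng_for(seed: int, *tokens) -> np.random.Generator:
    return np.random.default_rng(derive_seed(seed, *tokens))


def round_half_up(x: float) -> int:
    """Round to nearest integer with ties away from zero (report convention)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))
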