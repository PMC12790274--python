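"""Single-master-seed RNG policy.

One master seed per run; each consumer derives an independent child stream
from a stable text label, so adding a new generator never perturbs the draws
of an existing one and every stream is bit-reproducible across platforms.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["rng_for", "child_seed_seq"]

_MASK = (1 << 31) - 1


def child_seed_seq(seed: int, *labels: str) -> np.random.SeedSequence:
    """Seed sequence for the child stream named by ``labels`` under ``seed``."""
    keys = [int(seed) & _MASK] + [zlib.crc32(lbl.encode("utf-8")) for lbl in labels]
    return np.random.SeedSequence(keys)


def rng_for(seed: int, *labels: str) -> np.random.Generator:
    """Generator for the child stream named by ``labels`` under ``seed``."""
    return np.random.default_rng(child_seed_seq(seed, *labels))
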