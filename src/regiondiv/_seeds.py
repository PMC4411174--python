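"""Deterministic seed derivation.

Every stochastic stage derives its generator from the master seed plus a
stable key (stage name, pair indices, replicate number), so re-running a
single stage reproduces the original stream and no global RNG state is
ever touched.
"""

from __future__ import annotations

import zlib

import numpy as np


def _key_int(key) -> int:
    if isinstance(key, str):
        return zlib.crc32(key.encode("utf-8"))
    return int(key) & 0xFFFFFFFF


def seed_sequence(master_seed: int, *keys) -> np.random.SeedSequence:
    return np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF]
                                  + [_key_int(k) for k in keys])


def rng_for(master_seed: int, *keys) -> np.random.Generator:
    """A PCG64 generator keyed on the master seed and stage-specific keys."""
    return np.random.default_rng(seed_sequence(master_seed, *keys))
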