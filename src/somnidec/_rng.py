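"""Deterministic seed derivation.

A single master seed drives a whole simulated cohort; independent streams
for each (subject, night, stage, ...) are derived by hashing the purpose
keys into a ``SeedSequence`` spawn key, so regenerating any part of a
cohort in isolation yields bit-identical output.
"""

from __future__ import annotations

import zlib

import numpy as np


def _key_to_int(key) -> int:
    if isinstance(key, (int, np.integer)):
        return int(key) & 0xFFFFFFFF
    return zlib.crc32(str(key).encode())


def seed_sequence(seed: int, *keys) -> np.random.SeedSequence:
    return np.random.SeedSequence(int(seed), spawn_key=tuple(_key_to_int(k) for k in keys))


def rng_for(seed: int, *keys) -> np.random.Generator:
    """A Generator for the stream identified by ``(seed, *keys)``."""
    return np.random.default_rng(seed_sequence(seed, *keys))
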