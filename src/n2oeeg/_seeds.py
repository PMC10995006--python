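"""Deterministic seed-substream derivation.

A single master seed fans out to named substreams so that any stage
(a participant's recording, one shuffle iteration of one fold) can be
regenerated in isolation, bit-identically, without consuming randomness
from any other stage.
"""

from __future__ import annotations

import zlib

import numpy as np


def _token_key(token: object) -> int:
    if isinstance(token, (int, np.integer)):
        return int(token) & 0xFFFFFFFF
    # Stable across processes (unlike hash()).
    return zlib.crc32(str(token).encode("utf-8"))


def substream(seed: int, *tokens: object) -> np.random.Generator:
    """Generator for the substream named by ``tokens`` under ``seed``."""
    key = tuple(_token_key(t) for t in tokens)
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed, spawn_key=key)))


def child_seed(seed: int, *tokens: object) -> int:
    """A derived integer seed (< 2**31) for the named substream."""
    key = tuple(_token_key(t) for t in tokens)
    return int(np.random.SeedSequence(seed, spawn_key=key).generate_state(1)[0] % (2**31))
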