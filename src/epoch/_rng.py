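"""Seed handling.

All randomness in the package flows from a single integer seed through
named streams: ``stream_rng(seed, *key)`` builds a ``numpy`` Generator
from ``SeedSequence(seed)`` extended with a deterministic hash of the
key words.  Two call sites with different keys draw independent streams;
the same (seed, key) pair always yields the same stream, so adding or
reordering stages does not perturb the numbers of unrelated stages.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stream_rng"]


def _key_words(key: tuple) -> list[int]:
    words = []
    for part in key:
        if isinstance(part, (int, np.integer)):
            words.append(int(part) & 0xFFFFFFFF)
        else:
            words.append(zlib.crc32(str(part).encode("utf8")))
    return words


def stream_rng(seed: int, *key) -> np.random.Generator:
    """Generator for the stream named by ``key`` under the global ``seed``."""
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *_key_words(key)])
    return np.random.default_rng(ss)
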