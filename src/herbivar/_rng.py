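"""Deterministic stream derivation.

Every stochastic stage derives its generator from a root seed plus a tuple of
string/int keys, so toggling one stage never shifts another stage's stream and
identical seeds reproduce identical output across platforms.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["derive_rng", "derive_seed"]


def _key_to_int(key) -> int:
    if isinstance(key, (int, np.integer)):
        return int(key) & 0xFFFFFFFF
    return zlib.crc32(str(key).encode("utf-8"))


def derive_seed(root: int, *keys) -> np.random.SeedSequence:
    """A SeedSequence uniquely determined by ``root`` and the key path."""
    return np.random.SeedSequence([int(root) & 0x7FFFFFFF] + [_key_to_int(k) for k in keys])


def derive_rng(root: int, *keys) -> np.random.Generator:
    """A fresh Generator for the stream identified by ``root`` and ``keys``."""
    return np.random.default_rng(derive_seed(root, *keys))
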