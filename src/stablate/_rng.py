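"""Deterministic RNG plumbing.

One root seed per experiment; every sampler derives its own child stream from
the root seed plus a string key, so adding a sampler never perturbs the draws
of an existing one.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_rng", "child_seed"]


def child_seed(root_seed: int, *keys: str | int) -> int:
    """Derive a stable 31-bit child seed from a root seed and a key path."""
    h = zlib.crc32(repr((int(root_seed),) + tuple(keys)).encode())
    return int(h) % (2**31 - 1)


def child_rng(root_seed: int, *keys: str | int) -> np.random.Generator:
    """A numpy Generator keyed by (root_seed, *keys); same inputs, same stream."""
    return np.random.default_rng(child_seed(root_seed, *keys))
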