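"""Deterministic sub-seed derivation.

One master seed per experiment; every stage (dataset generation, fold
allocation, per-epoch shuffles, ...) draws its own generator from a
:class:`numpy.random.SeedSequence` keyed by the master seed plus stable
integer tags, so any single fold or epoch is reproducible in isolation.
"""

from __future__ import annotations

import zlib

import numpy as np


def _tag(x) -> int:
    if isinstance(x, (int, np.integer)):
        return int(x) & 0xFFFFFFFF
    return zlib.crc32(str(x).encode())


def subseed_sequence(master: int, *tags) -> np.random.SeedSequence:
    return np.random.SeedSequence([int(master) & 0xFFFFFFFF] + [_tag(t) for t in tags])


def derive_rng(master: int, *tags) -> np.random.Generator:
    """A fresh generator deterministically keyed by ``(master, *tags)``."""
    return np.random.default_rng(subseed_sequence(master, *tags))


def derive_seed(master: int, *tags) -> int:
    """A 31-bit integer seed deterministically keyed by ``(master, *tags)``."""
    return int(subseed_sequence(master, *tags).generate_state(1)[0] & 0x7FFFFFFF)
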