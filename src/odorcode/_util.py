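"""Shared helpers: named random substreams and package logging."""

from __future__ import annotations

import logging
import zlib

import numpy as np

logger = logging.getLogger("odorcode")


def derive_rng(seed: int, name: str) -> np.random.Generator:
    """Return a generator for the named substream of a root seed.

    Streams are independent across names and stable across runs, so toggling
    one pipeline stage never perturbs another stage's randomness.
    """
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode())])


def as_rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)
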