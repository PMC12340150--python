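"""Shared helpers: seeded sub-streams and lightweight logging."""

from __future__ import annotations

import logging
import zlib

import numpy as np

log = logging.getLogger("pepmarker")

_MOD = 2**31 - 1


def substream(seed: int, label: str) -> np.random.Generator:
    """Derive an independent RNG from a master seed and a fixed label.

    Every stochastic operation in the package draws from its own labeled
    stream so that adding a stage never perturbs the draws of another.
    """
    mix = (int(seed) * 1_000_003 + zlib.crc32(label.encode("utf8"))) % _MOD
    return np.random.default_rng(mix)


def child_seed(seed: int, label: str) -> int:
    """Integer form of :func:`substream` (for APIs that take a seed)."""
    return (int(seed) * 1_000_003 + zlib.crc32(label.encode("utf8"))) % _MOD
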