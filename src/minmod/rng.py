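"""Named random substreams derived from one master seed.

Every stochastic operation in the package takes a master ``seed`` and draws
from a named substream, so that the different generators (cohorts, variant
tables, Monte-Carlo screens, ...) are decoupled: adding draws to one never
perturbs another.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a generator for the substream ``name`` of master ``seed``.

    The substream key is a CRC32 of the name, so streams are stable across
    sessions and platforms. Identical (seed, name) pairs yield bit-identical
    streams.
    """
    if seed < 0:
        raise ValueError("seed must be non-negative")
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))
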