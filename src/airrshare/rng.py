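"""Seeded random-stream plumbing.

All randomness flows from one top-level integer seed. Each pipeline stage
draws from its own named substream, so stage-level reruns are independently
reproducible and inserting draws into one stage never perturbs another.
"""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the named substream of *seed*.

    The substream key is a CRC32 of the stage name, so the mapping is stable
    across runs, platforms and Python versions.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, key])
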