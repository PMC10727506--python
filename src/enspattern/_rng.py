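"""Deterministic child random streams.

Every stochastic operation derives its own generator from a master seed and
a short operation name, so reruns of one stage reproduce exactly without
consuming draws from other stages.
"""

from __future__ import annotations

import zlib

import numpy as np


def child_rng(seed: int, op_name: str) -> np.random.Generator:
    """Generator for operation ``op_name`` under master ``seed``.

    The op name is hashed with CRC32 (stable across processes and Python
    versions, unlike the builtin ``hash``) and mixed into the seed sequence.
    """
    key = zlib.crc32(op_name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, key]))
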