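"""Deterministic per-operation random streams.

Every stochastic operation draws from ``rng_for(seed, "op-name")`` so adding
or reordering one stage never perturbs another stage's draws.
"""

from __future__ import annotations

import zlib

import numpy as np


def rng_for(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode())])
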