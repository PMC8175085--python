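"""Keyed random-number streams.

Every stochastic operation in the package draws from a generator derived
from (root seed, operation key). Streams are independent of call order,
so adding or reordering simulation steps never perturbs the others.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["derived_rng", "derived_seed"]


def derived_seed(seed: int, *keys: str | int) -> np.random.SeedSequence:
    """Build a SeedSequence for ``seed`` split by the given stable keys.

    String keys are hashed with CRC-32 so the split depends only on the
    key text, never on Python's per-process hash randomization.
    """
    entropy = [int(seed) & 0x7FFFFFFF]
    for k in keys:
        if isinstance(k, str):
            entropy.append(zlib.crc32(k.encode("utf-8")))
        else:
            entropy.append(int(k) & 0xFFFFFFFF)
    return np.random.SeedSequence(entropy)


def derived_rng(seed: int, *keys: str | int) -> np.random.Generator:
    """A ``numpy.random.Generator`` on the keyed stream (seed, *keys)."""
    return np.random.default_rng(derived_seed(seed, *keys))
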