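"""Named, order-independent random substreams.

Every synthetic-data generator draws from its own substream derived from
(seed, stream name), so adding or reordering generators never perturbs the
output of the others and a fixed seed gives bit-identical output.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a PCG64 generator for the named substream of ``seed``."""
    if seed < 0:
        raise ValueError("seed must be non-negative")
    entropy = [int(seed), zlib.crc32(name.encode("utf-8"))]
    return np.random.default_rng(np.random.SeedSequence(entropy))
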