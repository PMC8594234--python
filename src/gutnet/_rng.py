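"""Named random streams.

One user-facing integer seed drives every stochastic stage of the package.
Each stage draws from its own stream, derived from the global seed plus a
stable CRC32 hash of the stage name, so individual stages are reproducible
independently of how many draws other stages consumed.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stream"]


def stream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the stage ``name`` under the global ``seed``."""
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, key]))
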