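"""Named, seed-stable random streams.

Each logical output (lesion placement, signal noise, cohort draws, ...)
gets its own generator derived from the global seed and a stream name, so
adding a consumer never shifts the draws of another.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["named_rng"]


def named_rng(seed: int, name: str) -> np.random.Generator:
    """Return a generator for stream ``name`` derived from ``seed``.

    The stream key is a CRC32 of the name, so the mapping is stable across
    processes and Python versions (unlike ``hash``).
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(key,)))
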