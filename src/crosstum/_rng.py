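"""Splittable random-number discipline.

Every stochastic component draws from its own named substream of a single
top-level integer seed, so adding or reordering one generator never perturbs
the draws of another. Substream keys are derived with CRC-32, which is stable
across processes (unlike Python's randomized ``hash``).
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return an independent ``Generator`` for (seed, name).

    The same (seed, name) pair always yields a bit-identical stream;
    distinct names yield statistically independent streams.
    """
    key = zlib.crc32(name.encode("utf-8"))
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(key,))
    return np.random.default_rng(ss)
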