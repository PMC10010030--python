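"""Seeded random-number substreams.

All randomness in the package flows from a single integer seed.  Each
operation derives its own independent substream by hashing a stable
operation name into a :class:`numpy.random.SeedSequence` spawn key, so
adding draws to one operation never perturbs another.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def _stable_key(name: str) -> int:
    return zlib.crc32(name.encode("utf-8"))


def substream(seed: int, name: str, index: int = 0) -> np.random.Generator:
    """Return a Generator for operation ``name`` derived from ``seed``.

    ``index`` distinguishes repeated draws within one operation
    (e.g. bootstrap replicate number).
    """
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(_stable_key(name), int(index)))
    return np.random.default_rng(ss)
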