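"""Deterministic random-stream splitting.

All randomness in the package flows from a single integer seed.  Independent
streams are derived by hashing string labels (plus optional integer counters)
into a ``numpy.random.SeedSequence`` spawn key, so adding a consumer never
perturbs the draws of existing ones.
"""

from __future__ import annotations

import zlib

import numpy as np


def rng_for(seed: int, *key: str | int) -> np.random.Generator:
    """Return a Generator for stream ``key`` derived from the root ``seed``.

    ``key`` components may be strings (hashed with CRC-32) or plain integers
    (used as-is), e.g. ``rng_for(7, "stopover", 12)``.
    """
    spawn = tuple(
        zlib.crc32(k.encode()) if isinstance(k, str) else int(k) for k in key
    )
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=spawn))
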