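"""Deterministic sub-seed derivation.

All stochastic stages derive their generators from a single master seed plus a
stable string token (stage name, sample id, iteration index), so that the same
master seed reproduces every draw regardless of execution order.
"""

from __future__ import annotations

import zlib

import numpy as np


def child_rng(master_seed: int, *tokens: object) -> np.random.Generator:
    """A generator keyed by the master seed and a stable hash of the tokens."""
    key = zlib.crc32("|".join(str(t) for t in tokens).encode("utf-8"))
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=(key,))
    return np.random.default_rng(ss)
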