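"""Deterministic child RNG streams.

One root seed governs a whole pipeline run; every stochastic operation derives
its own stream from (root seed, *names), so adding or reordering samples does
not perturb the draws of the others.
"""
from __future__ import annotations

import zlib

import numpy as np


def child_rng(root_seed: int, *names: str) -> np.random.Generator:
    """Return a Generator keyed by the root seed plus a tuple of labels.

    Labels are hashed with CRC32, which is stable across platforms and
    sessions (unlike Python's salted ``hash``).
    """
    key = tuple(zlib.crc32(n.encode("utf-8")) for n in names)
    return np.random.default_rng(np.random.SeedSequence(root_seed, spawn_key=key))
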