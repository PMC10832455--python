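"""Deterministic random-stream management.

All randomness in the package flows from a single integer root seed.
Named substreams are derived with :class:`numpy.random.SeedSequence` so that
each pipeline stage draws from its own stream: adding draws to one stage
never perturbs another.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "child_seed"]


def _name_key(name: str) -> int:
    # stable across processes/platforms, unlike hash()
    return zlib.crc32(name.encode("utf-8"))


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the named substream of ``seed``."""
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=(_name_key(name),)))


def child_seed(seed: int, name: str) -> int:
    """A derived integer seed (< 2**31) for APIs that take plain seeds."""
    ss = np.random.SeedSequence(int(seed), spawn_key=(_name_key(name),))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))
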