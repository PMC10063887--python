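"""Deterministic seed splitting.

Every stochastic routine derives its generator from one master seed plus a
tuple of string/int labels naming the stream ("haplotypes", pop index,
chromosome index, ...).  The same master seed therefore yields
byte-identical output regardless of call order, and independent streams
never collide.
"""

from __future__ import annotations

import hashlib

import numpy as np


def _label_key(labels: tuple) -> list[int]:
    digest = hashlib.sha256(repr(labels).encode()).digest()
    return [int.from_bytes(digest[i : i + 4], "little") for i in range(0, 16, 4)]


def rng_for(seed: int, *labels) -> np.random.Generator:
    """Generator for the stream identified by ``labels`` under ``seed``."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(_label_key(labels)))
    return np.random.default_rng(ss)


def subseed(seed: int, *labels) -> int:
    """A derived integer seed (< 2**31) for APIs that take plain seeds."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(_label_key(labels)))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))
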