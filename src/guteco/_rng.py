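"""Deterministic random-stream derivation.

Every stochastic operation in the package draws from a numpy Generator whose
SeedSequence is derived from (seed, *names): the names are stable strings
(operation name, sample id, canonical pair id, ...) hashed with CRC32. This
makes results independent of iteration order and stable across runs: adding a
new consumer never perturbs an existing stream.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_rng", "child_seed_sequence"]


def _key(part: object) -> int:
    return zlib.crc32(str(part).encode("utf-8"))


def child_seed_sequence(seed: int, *names: object) -> np.random.SeedSequence:
    """SeedSequence for the stream named by ``names`` under a global ``seed``."""
    return np.random.SeedSequence(int(seed), spawn_key=tuple(_key(n) for n in names))


def child_rng(seed: int, *names: object) -> np.random.Generator:
    """Generator for the stream named by ``names`` under a global ``seed``."""
    return np.random.default_rng(child_seed_sequence(seed, *names))
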