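"""Named, reproducible random streams.

A single user-facing seed is expanded into independent per-stage streams by
hashing stage names into the seed sequence, so adding a stage never perturbs
the draws of another.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stream", "spawn"]


def stream(seed: int, *names: object) -> np.random.Generator:
    """Return a generator for the stream identified by ``seed`` and ``names``."""
    entropy = [int(seed) & 0xFFFFFFFF] + [
        zlib.crc32(str(n).encode("utf-8")) for n in names
    ]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def spawn(rng: np.random.Generator, n: int) -> list[np.random.Generator]:
    """Split ``rng`` into ``n`` independent child generators."""
    return [np.random.default_rng(s) for s in rng.bit_generator.seed_seq.spawn(n)]
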