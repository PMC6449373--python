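"""Deterministic random-stream plumbing.

A single user-facing seed fans out into independent per-stage substreams.
Each stage salts the seed with a CRC32 of its name, so any stage can be
re-run in isolation and reproduce exactly the stream it saw inside a full
pipeline run.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stage_rng", "stage_seed"]


def stage_seed(seed: int, stage: str) -> int:
    """Derive a stable 31-bit child seed for a named stage."""
    return (int(seed) ^ zlib.crc32(stage.encode("utf-8"))) % (2**31)


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """A numpy Generator seeded deterministically from (seed, stage name)."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) % (2**31), zlib.crc32(stage.encode("utf-8"))])
    )
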