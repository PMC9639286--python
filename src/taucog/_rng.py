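"""Seeded random-stream management.

All randomness in the package flows from one root seed. Each pipeline stage
draws from a named substream so that re-running a single stage, or permuting
stage order, never perturbs the draws of another stage.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stage_rng"]


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Return a Generator for a named stage derived from the root seed.

    The substream key is a CRC-32 of the stage name, so the mapping
    (seed, stage) -> stream is stable across sessions and platforms.
    """
    key = zlib.crc32(stage.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))
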