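"""Deterministic per-stage random streams.

All randomness in the package flows through :func:`stage_rng`, which derives
an independent substream from a single integer seed and a stage name, so each
pipeline stage is reproducible on its own and stages never share state.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stage_rng", "stage_seed"]


def stage_seed(seed: int, stage: str) -> np.random.SeedSequence:
    """Seed sequence for a named stage derived from a root seed."""
    if not isinstance(seed, (int, np.integer)):
        raise TypeError(f"seed must be an integer, got {type(seed).__name__}")
    tag = zlib.crc32(stage.encode("utf-8"))
    return np.random.SeedSequence(entropy=int(seed), spawn_key=(tag,))


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent generator for a named stage of the pipeline."""
    return np.random.default_rng(stage_seed(seed, stage))
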