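"""Named random substreams derived from a single root seed.

Every stochastic stage of the pipeline (cohort generation, stochastic
application of a derived predictor, bootstrap subsampling) draws from its own
substream so that changing one stage never perturbs another.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for stage `name`, deterministically derived from `seed`.

    The stage name is hashed (CRC-32, stable across platforms and sessions)
    and folded into the seed sequence, so distinct names give independent
    streams while identical (seed, name) pairs reproduce byte-identically.
    """
    if not isinstance(seed, (int, np.integer)):
        raise TypeError(f"seed must be an integer, got {type(seed).__name__}")
    tag = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, tag]))
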