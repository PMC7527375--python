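"""Small shared helpers: seeded substreams and percentage formatting."""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, *keys) -> np.random.Generator:
    """Independent random generator derived from a master seed and string keys.

    Keys are hashed with CRC32 so the stream for a given (seed, key) pair is
    stable across runs and across cohort subsetting.
    """
    entropy = [int(seed)] + [zlib.crc32(str(k).encode("utf-8")) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def percent(numerator: float, denominator: float, ndigits: int = 1) -> float:
    """Percentage of `numerator` in `denominator`, rounded for reporting."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    return round(100.0 * numerator / denominator, ndigits)
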