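"""Named substreams of randomness.

Every stochastic routine in the package draws from a generator obtained via
:func:`substream`, keyed by a user seed plus a short label.  Two calls with
the same ``(seed, label)`` pair return generators producing identical streams,
while different labels give statistically independent streams.  This lets
each module be exercised in isolation without consuming another module's
random numbers, and makes whole-pipeline runs bit-reproducible.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "child_seed"]


def substream(seed: int, label: str) -> np.random.Generator:
    """Return an independent :class:`numpy.random.Generator` for (seed, label)."""
    entropy = [int(seed) & 0x7FFFFFFF, zlib.crc32(label.encode("utf-8"))]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def child_seed(seed: int, label: str) -> int:
    """Derive a deterministic integer seed below 2**31 from (seed, label)."""
    return int(substream(seed, label).integers(0, 2**31 - 1))
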