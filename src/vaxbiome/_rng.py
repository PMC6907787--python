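"""Named random substreams.

All randomness in the package flows from one master seed.  Each component
(counts, mock, IgA, ELISA, Gibbs chains, forest bootstraps, ...) draws from
its own named substream so that changing the configuration of one component
never perturbs the draws of another.
"""

from __future__ import annotations

from zlib import crc32

import numpy as np

__all__ = ["substream", "child_seeds"]


def substream(seed: int, label: str) -> np.random.Generator:
    """Return a Generator keyed by ``(seed, label)``.

    The label is hashed with CRC-32, which is stable across platforms and
    Python processes (unlike the builtin ``hash``).
    """
    entropy = [int(seed) & 0x7FFFFFFF, crc32(label.encode("utf-8"))]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def child_seeds(seed: int, label: str, n: int) -> np.ndarray:
    """n distinct 31-bit integer seeds derived from a named substream."""
    return substream(seed, label).integers(0, 2**31 - 1, size=n)
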