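"""Seed management: named substreams derived from a single top-level seed.

Every source of randomness in the package draws from a ``numpy`` Generator
obtained through :func:`substream`, so adding draws in one stage (e.g. more
bootstrap replicates) never perturbs another stage's stream.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, label: str) -> np.random.Generator:
    """Return a Generator for stage ``label`` deterministically derived from ``seed``."""
    if seed is None:
        raise ValueError("an explicit integer seed is required")
    tag = zlib.crc32(label.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag]))
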