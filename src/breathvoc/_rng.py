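"""Deterministic seed derivation for named sub-streams.

A single root seed drives every stochastic stage; each stage draws from a
sub-stream derived from (root seed, stage name) so stages can be toggled
without perturbing one another's draws.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "subseed"]


def subseed(seed: int, name: str) -> int:
    """Derive a stable 31-bit child seed from a root seed and a stream name."""
    tag = zlib.crc32(name.encode("utf-8"))
    return int(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, tag]).generate_state(1)[0] & 0x7FFFFFFF)


def substream(seed: int, name: str) -> np.random.Generator:
    """A ``numpy`` Generator for the named sub-stream of ``seed``."""
    return np.random.default_rng(subseed(seed, name))
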