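"""Seed plumbing: one user-facing seed, hierarchically split per stage.

Every stochastic operation takes an integer seed and derives its generator
through :func:`rng_for` with a stable string label, so a single pipeline seed
reproduces every stage byte-for-byte while stages remain independent.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["rng_for", "child_seed"]


def child_seed(seed: int, label: str) -> int:
    """Derive a stable child seed (< 2**31) from ``seed`` and a stage label."""
    return (int(seed) ^ zlib.crc32(label.encode("utf-8"))) % (2**31)


def rng_for(seed: int, label: str = "") -> np.random.Generator:
    """Return a Generator seeded from ``seed`` and an optional stage label."""
    if label:
        return np.random.default_rng(
            np.random.SeedSequence([int(seed) % (2**31), zlib.crc32(label.encode("utf-8"))])
        )
    return np.random.default_rng(int(seed) % (2**31))
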