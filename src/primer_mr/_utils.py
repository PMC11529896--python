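"""Shared small helpers: seeded RNG streams and numerically safe ops."""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stream_rng", "standardize"]


def stream_rng(seed: int, tag: str) -> np.random.Generator:
    """Return a Generator for a named stage, derived from one global seed.

    Each (seed, tag) pair maps to an independent stream, so adding a stage
    never perturbs the draws of another.
    """
    tag_int = zlib.crc32(tag.encode("utf-8")) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, tag_int]))


def standardize(v: np.ndarray) -> np.ndarray:
    """Center and scale to unit sample SD; zero-variance input maps to zeros."""
    v = np.asarray(v, dtype=float)
    sd = v.std()
    if sd == 0.0:
        return np.zeros_like(v)
    return (v - v.mean()) / sd
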