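"""Deterministic seed derivation.

All randomness in the package flows from one root integer seed; each stage
or repetition derives an independent child seed through ``derive_seed`` so
that reruns with the same root are bit-identical while stages stay
statistically independent.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["derive_seed", "rng_for"]


def _as_int(tag) -> int:
    if isinstance(tag, (int, np.integer)):
        return int(tag)
    if isinstance(tag, str):
        return zlib.crc32(tag.encode("utf-8"))
    raise TypeError(f"seed tag must be int or str, got {type(tag)!r}")


def derive_seed(root: int, *tags) -> int:
    """Derive a child seed (< 2**31) from a root seed and hashable tags."""
    entropy = [_as_int(root)] + [_as_int(t) for t in tags]
    return int(np.random.SeedSequence(entropy).generate_state(1)[0] % (2**31))


def rng_for(root: int, *tags) -> np.random.Generator:
    """A ``numpy`` generator keyed by root seed and stage tags."""
    return np.random.default_rng(derive_seed(root, *tags))
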