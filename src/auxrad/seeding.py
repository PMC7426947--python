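"""Deterministic seed derivation.

A single master seed fans out to named per-stage / per-layer streams so that
any stage (data generation, weight init, dropout, shuffling, augmentation)
is independently reproducible and two training regimes sharing a component
(e.g. the encoder) draw identical init streams for it.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["derive_seed", "rng_for"]


def derive_seed(master: int, label: str) -> int:
    """Derive a child seed < 2**31 from a master seed and a stream label."""
    h = hashlib.blake2b(f"{int(master)}:{label}".encode(), digest_size=8)
    return int.from_bytes(h.digest(), "little") % (2**31)


def rng_for(master: int, label: str) -> np.random.Generator:
    """A numpy Generator seeded from ``derive_seed(master, label)``."""
    return np.random.default_rng(derive_seed(master, label))
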