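"""Seed plumbing: one master integer seed, split per named stream.

Every source of randomness in the package derives a child generator from a
single integer through :func:`child_rng`. The split is counter-based (label
hashes feed a :class:`numpy.random.SeedSequence` spawn key), so adding a new
stream never perturbs the draws of existing ones.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_rng", "child_seed"]


def _label_key(label: str | int) -> int:
    if isinstance(label, (int, np.integer)):
        return int(label) & 0xFFFFFFFF
    return zlib.crc32(str(label).encode("utf-8"))


def child_seed(seed: int, *labels: str | int) -> int:
    """Derive a reproducible 31-bit child seed from ``seed`` and stream labels."""
    ss = np.random.SeedSequence(int(seed), spawn_key=tuple(_label_key(l) for l in labels))
    return int(ss.generate_state(1, np.uint32)[0]) & 0x7FFFFFFF


def child_rng(seed: int, *labels: str | int) -> np.random.Generator:
    """Generator for the named stream ``labels`` under master ``seed``."""
    ss = np.random.SeedSequence(int(seed), spawn_key=tuple(_label_key(l) for l in labels))
    return np.random.default_rng(ss)
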