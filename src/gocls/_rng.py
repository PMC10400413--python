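"""Seed management.

A single master seed is expanded into independent per-component streams via
``numpy.random.SeedSequence`` spawn keys, so that adding randomness to one
subsystem never perturbs the draws of another.  String labels are hashed to
integers with CRC32 to form the spawn key.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_rng", "child_seed"]


def _key(parts: tuple) -> tuple[int, ...]:
    out = []
    for p in parts:
        if isinstance(p, str):
            out.append(zlib.crc32(p.encode()))
        else:
            out.append(int(p) & 0xFFFFFFFF)
    return tuple(out)


def child_rng(seed: int, *parts) -> np.random.Generator:
    """Independent generator for component ``parts`` under ``seed``."""
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=_key(parts)))


def child_seed(seed: int, *parts) -> int:
    """Derived integer seed (< 2**31) for component ``parts``."""
    ss = np.random.SeedSequence(int(seed), spawn_key=_key(parts))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)
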