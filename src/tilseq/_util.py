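"""Shared helpers: seeded substreams and hamming distance."""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, name: str) -> np.random.Generator:
    """Return an independent RNG for a named substream of a top-level seed.

    Streams are keyed by a CRC32 of the name, so adding a new generator
    never perturbs the draws of an existing one.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(key,)))


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length strings.

    Raises ValueError on a length mismatch: unequal-length sequences have
    no defined substitution distance here and callers must never link them.
    """
    if len(a) != len(b):
        raise ValueError(f"hamming distance undefined for lengths {len(a)} != {len(b)}")
    return sum(ca != cb for ca, cb in zip(a, b))


class InputError(ValueError):
    """Malformed or inconsistent user input."""


class ConfigError(ValueError):
    """Invalid simulation or pipeline configuration."""
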