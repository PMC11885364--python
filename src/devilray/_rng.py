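"""Seed plumbing: one top-level seed, named deterministic substreams per module."""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, label: str) -> np.random.Generator:
    """Return a Generator deterministically derived from (seed, label).

    Every stochastic operation in the package draws from a named substream so
    that module-level tests and the end-to-end pipeline see identical streams
    for the same top-level seed.
    """
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, zlib.crc32(label.encode())])


def substream_seed(seed: int, label: str) -> int:
    """A plain integer seed (< 2^31) derived from (seed, label), for APIs that
    want an int rather than a Generator."""
    return int(substream(seed, label).integers(0, 2**31 - 1))
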