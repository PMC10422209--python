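"""Deterministic seed fan-out.

A single global seed is expanded into named substreams so that pipeline
stages (phantom generation, weight init, batch shuffling, panel selection)
can be re-run independently yet reproducibly.
"""

from __future__ import annotations

import zlib

import numpy as np


def child_sequence(seed: int, name: str) -> np.random.SeedSequence:
    """Seed sequence for the named substream of a global seed."""
    return np.random.SeedSequence([int(seed), zlib.crc32(name.encode("utf-8"))])


def child_rng(seed: int, name: str) -> np.random.Generator:
    """Generator for the named substream of a global seed."""
    return np.random.default_rng(child_sequence(seed, name))


def child_seed(seed: int, name: str) -> int:
    """Plain integer seed (< 2**31) for the named substream."""
    return int(child_sequence(seed, name).generate_state(1)[0] % (2**31))
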