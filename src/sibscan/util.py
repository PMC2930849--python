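"""Shared numerical helpers: seeding, Haldane map function, meioses."""

from __future__ import annotations

import zlib

import numpy as np


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent generator for a named pipeline stage under one seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(stage.encode())]))


def haldane_theta(d_cm) -> np.ndarray:
    """Recombination fraction for a map distance in cM (no interference)."""
    return 0.5 * (1.0 - np.exp(-0.02 * np.asarray(d_cm, dtype=float)))


def meiosis_bits(rng: np.random.Generator, cm: np.ndarray, n_meioses: int,
                 fixed_index: int | None = None,
                 fixed_bits: np.ndarray | None = None) -> np.ndarray:
    """Simulate grandparental-origin indicators along one chromosome.

    Returns an (n_meioses, n_markers) 0/1 array.  Each meiosis is an
    independent two-state Markov chain over the ordered cM positions
    with Haldane switch probabilities.  If ``fixed_index`` is given the
    chain is conditioned to take ``fixed_bits`` at that marker and is
    generated outward from it (the chain is reversible, so this is the
    exact conditional law).
    """
    m = len(cm)
    theta = haldane_theta(np.diff(cm))
    bits = np.empty((n_meioses, m), dtype=np.int8)
    if fixed_index is None:
        start = 0
        bits[:, 0] = rng.integers(0, 2, size=n_meioses)
    else:
        start = fixed_index
        bits[:, start] = fixed_bits
    for j in range(start + 1, m):
        flip = rng.uniform(size=n_meioses) < theta[j - 1]
        bits[:, j] = bits[:, j - 1] ^ flip
    for j in range(start - 1, -1, -1):
        flip = rng.uniform(size=n_meioses) < theta[j]
        bits[:, j] = bits[:, j + 1] ^ flip
    return bits
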