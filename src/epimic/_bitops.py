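"""Packed bit-set primitives for fast joint-genotype counting.

Sample-membership sets (one per SNP genotype, plus the two phenotype
strata) are stored as packed 64-bit words so that a joint-genotype count
is an AND followed by a population count.  All higher-level statistics in
the package reduce to these counts.
"""
from __future__ import annotations

import numpy as np

__all__ = ["pack_bool", "popcount", "count_and"]


def pack_bool(mask: np.ndarray) -> np.ndarray:
    """Pack a boolean array along its last axis into uint64 words.

    The bit order within a word is an internal convention; it is
    consistent across all sets packed for the same sample axis, which is
    all that intersection counting requires.
    """
    bits = np.packbits(np.ascontiguousarray(mask, dtype=np.uint8), axis=-1)
    n_bytes = bits.shape[-1]
    pad = (-n_bytes) % 8
    if pad:
        bits = np.concatenate(
            [bits, np.zeros(bits.shape[:-1] + (pad,), dtype=np.uint8)], axis=-1
        )
    return bits.view(np.uint64)


def popcount(words: np.ndarray, axis: int = -1) -> np.ndarray:
    """Total number of set bits along ``axis``."""
    return np.bitwise_count(words).sum(axis=axis, dtype=np.int64)


def count_and(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Popcount of the intersection of two broadcastable packed sets."""
    return popcount(a & b)
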