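"""Canonical pair ordering for vectorized dissimilarity matrices.

Everything in the package uses one pair order: the upper triangle in
row-major order, i.e. pairs (i, j) with i < j sorted by i then j.  This is
exactly the order produced by ``np.triu_indices(n, k=1)``.
"""
from __future__ import annotations

import math

import numpy as np

from .exceptions import InvalidArgumentError


def n_pairs(n_items: int) -> int:
    """Number of unordered item pairs, n(n-1)/2."""
    return n_items * (n_items - 1) // 2


def n_items_from_pairs(m: int) -> int:
    """Invert ``n_pairs``; raise if *m* is not a triangular number."""
    n = int(round((1 + math.isqrt(1 + 8 * m)) / 2))
    if n_pairs(n) != m:
        raise InvalidArgumentError(f"{m} is not n(n-1)/2 for any integer n")
    return n


def pair_index(i: int, j: int, n: int) -> int:
    """Position of pair (i, j), i != j, in the canonical vector order."""
    if i == j:
        raise InvalidArgumentError("diagonal entries have no pair index")
    if i > j:
        i, j = j, i
    return i * n - i * (i + 1) // 2 + (j - i - 1)


def pair_indices(items: np.ndarray, n: int) -> np.ndarray:
    """Canonical vector positions of all pairs among *items* (sorted ascending).

    The returned positions follow the upper-triangle order of the sorted item
    subset, matching the per-trial distance order used throughout.
    """
    items = np.sort(np.asarray(items, dtype=np.intp))
    ii, jj = np.triu_indices(items.size, k=1)
    a, b = items[ii], items[jj]
    return a * n - a * (a + 1) // 2 + (b - a - 1)


def permute_pair_order(perm: np.ndarray) -> np.ndarray:
    """Index array mapping a pair vector under an item relabeling.

    If ``v`` is an RDM vector and ``perm`` maps new item index -> old item
    index, then ``v[permute_pair_order(perm)]`` is the vector of the
    relabeled RDM.
    """
    perm = np.asarray(perm, dtype=np.intp)
    n = perm.size
    ii, jj = np.triu_indices(n, k=1)
    a, b = perm[ii], perm[jj]
    lo, hi = np.minimum(a, b), np.maximum(a, b)
    return lo * n - lo * (lo + 1) // 2 + (hi - lo - 1)
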