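"""Sequential numbering and partitioning of variant pairs.

All unordered variant pairs ``(i, j)``, ``i < j``, over ``N`` variants
are numbered ``1 .. M`` with ``M = N(N-1)/2`` in nested-loop order:
``(1,2), (1,3), ..., (1,N), (2,3), ...``.  The numbering makes an
exhaustive scan resumable and lets the id range be split evenly across
workers: ids map to pairs in O(1) via the triangular-root inversion, so
no worker needs to walk the loop from the start.

Pair ids and the ``(i, j)`` labels here are 1-based, matching the usual
presentation; dataset column indices elsewhere in the package are
0-based (subtract 1 when indexing a genotype matrix).
"""

from __future__ import annotations

from math import isqrt
from typing import Callable

from .dataset import GenotypeDataset


def n_pairs(n_variants: int) -> int:
    """Total number of unordered variant pairs, N(N-1)/2."""
    return n_variants * (n_variants - 1) // 2


def index_from_pair(i: int, j: int, n_variants: int) -> int:
    """Sequential 1-based id of pair ``(i, j)`` with ``1 <= i < j <= N``."""
    if not (1 <= i < j <= n_variants):
        raise ValueError(f"need 1 <= i < j <= {n_variants}, got ({i}, {j})")
    done = (i - 1) * n_variants - (i - 1) * i // 2  # pairs with first index < i
    return done + (j - i)


def pair_from_index(k: int, n_variants: int) -> tuple[int, int]:
    """Invert the pair numbering: id ``k`` -> 1-based ``(i, j)``, ``i < j``.

    Closed-form triangular-root inversion with an integer correction
    step, so the map is exact for all ids representable as Python ints.
    """
    m_total = n_pairs(n_variants)
    if not (1 <= k <= m_total):
        raise ValueError(f"pair id {k} outside 1..{m_total}")
    rem = m_total - k  # pairs strictly after k
    # largest m with m(m+1)/2 <= rem
    m = (isqrt(8 * rem + 1) - 1) // 2
    while (m + 1) * (m + 2) // 2 <= rem:
        m += 1
    while m * (m + 1) // 2 > rem:
        m -= 1
    i = n_variants - (m + 1)
    j = n_variants - (rem - m * (m + 1) // 2)
    return i, j


def partition(m_total: int, workers: int) -> list[range]:
    """Split pair ids ``1..M`` into contiguous per-worker ranges.

    The first ``workers - 1`` ranges have size ``ceil(M / workers)``;
    the last holds the remainder and may be smaller or empty.  Ranges
    are disjoint and jointly cover ``1..M``.
    """
    if workers < 1:
        raise ValueError("need at least one worker")
    if m_total < 0:
        raise ValueError("pair count must be non-negative")
    chunk = -(-m_total // workers) if m_total else 0
    out = []
    for w in range(workers):
        start = min(1 + w * chunk, m_total + 1)
        stop = min(start + chunk, m_total + 1)
        out.append(range(start, stop))
    return out


def chromosome_mask(
    dataset: GenotypeDataset, cross_chrom_only: bool
) -> Callable[[int, int], bool]:
    """Predicate on 0-based variant indices admitting a pair to the scan.

    With ``cross_chrom_only`` set, only pairs whose variants carry
    different chromosome labels pass (string equality; no normalization
    is attempted, so ``"1"`` and ``"chr1"`` count as different).
    """
    if not cross_chrom_only:
        return lambda i, j: True
    chrom = dataset.chromosome
    return lambda i, j: chrom[i] != chrom[j]
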