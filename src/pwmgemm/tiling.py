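"""Zero-aware tiling of the pattern matrix.

Motifs shorter than the longest one leave trailing zeros in their pattern
columns; with length-diverse motif sets most of the multiply-adds in the
score products then hit structural zeros.  Sorting the columns by motif
length (ascending) and recursively splitting the column range into tiles
lets each tile use only its first ``4 * m_i`` rows, ``m_i`` being the
longest motif inside, so the discarded bottom-left zero block never enters
a product:

    R^o[:, c_i:c_{i+1}] = S[:, 4o : 4(o + m_i)] @ P[0 : 4 m_i, c_i:c_{i+1}]

Each binary split is placed where the discarded zero area is maximal, and
recursion stops once the best discardable area falls below ``min_area``
(in matrix elements).  Splits discarding zero area are never taken, which
guarantees termination even at ``min_area = 0``.  Tiling is purely a
performance transformation: the assembled score block is identical (up to
floating-point round-off) to the untiled product.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np

from .engine import PatternMatrix

DEFAULT_MIN_AREA = 4096


@dataclass(frozen=True)
class Tile:
    """Half-open column interval [start, stop) using rows [0, 4*m_i)."""

    start: int
    stop: int
    m_i: int

    @property
    def n_columns(self) -> int:
        return self.stop - self.start


def sort_columns(pattern: PatternMatrix) -> Tuple[PatternMatrix, np.ndarray]:
    """Stable-sort pattern columns ascending by motif length.

    Returns the permuted matrix and the permutation applied; the original
    column index survives in each column's metadata, so occurrences keep
    reporting their original motif identity and ordering.
    """
    lengths = np.array([col.length for col in pattern.columns])
    perm = np.argsort(lengths, kind="stable")
    permuted = PatternMatrix(
        values=pattern.values[:, perm],
        columns=tuple(pattern.columns[i] for i in perm),
        m=pattern.m,
    )
    return permuted, perm


def best_split(tile: Tile, lengths: Sequence[int]) -> Tuple[int, int]:
    """Best split position and the zero area it would discard.

    For a split at ``s`` in (start, stop) the left tile's rows shrink from
    ``4 * m_i`` to ``4 * lengths[s-1]``, discarding a zero block of area
    ``4 * (m_i - lengths[s-1]) * (s - start)``.  Returns the argmax,
    ties broken toward the smallest ``s``; a single-column tile has no
    split signal and returns ``(-1, 0)``.
    """
    if tile.n_columns < 2:
        return -1, 0
    best_s, best_area = -1, 0
    for s in range(tile.start + 1, tile.stop):
        area = 4 * (tile.m_i - lengths[s - 1]) * (s - tile.start)
        if area > best_area:
            best_s, best_area = s, area
    return best_s, best_area


def partition(pattern: PatternMatrix, min_area: int = DEFAULT_MIN_AREA) -> List[Tile]:
    """Recursively split the (length-sorted) columns into tiles.

    A tile is split only when the best discardable zero area is positive
    and at least ``min_area``; the returned tiles partition the column
    range exactly.
    """
    if min_area < 0:
        raise ValueError(f"min_area must be >= 0, got {min_area}")
    lengths = [col.length for col in pattern.columns]
    if any(lengths[i] > lengths[i + 1] for i in range(len(lengths) - 1)):
        raise ValueError("pattern columns must be sorted by length; use sort_columns first")

    def recurse(start: int, stop: int) -> List[Tile]:
        tile = Tile(start=start, stop=stop, m_i=lengths[stop - 1])
        s, area = best_split(tile, lengths)
        if s < 0 or area == 0 or area < min_area:
            return [tile]
        return recurse(start, s) + recurse(s, stop)

    return recurse(0, pattern.n_columns)


def tiled_product(
    S: np.ndarray, pattern: PatternMatrix, tiles: Sequence[Tile], o: int
) -> np.ndarray:
    """Assemble the h x c score block from one product per tile."""
    R = np.empty((S.shape[0], pattern.n_columns))
    for tile in tiles:
        R[:, tile.start:tile.stop] = (
            S[:, 4 * o: 4 * (o + tile.m_i)]
            @ pattern.values[: 4 * tile.m_i, tile.start:tile.stop]
        )
    return R


def zero_fraction(pattern: PatternMatrix, tiles: Sequence[Tile] = None) -> float:
    """Fraction of *stored* matrix elements that are structural zeros.

    Without tiles: zeros of the full 4m x c layout.  With tiles: zeros
    retained inside the tiles' reduced row ranges (the discarded blocks no
    longer count).  Returns 0.0 for an empty layout.
    """
    lengths = [col.length for col in pattern.columns]
    if tiles is None:
        tiles = [Tile(0, pattern.n_columns, pattern.m)]
    stored = 0
    zeros = 0
    for tile in tiles:
        stored += 4 * tile.m_i * tile.n_columns
        zeros += sum(4 * (tile.m_i - lengths[k]) for k in range(tile.start, tile.stop))
    return zeros / stored if stored else 0.0
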