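"""Bit-packed Fitch scoring used by the tree-search hot paths.

All characters of a matrix are packed into one big Python integer per
taxon, ten bits per character (one bit per state 0-9; a missing cell sets
all ten).  A full Fitch pass over a nested-tuple tree then costs a handful
of bitwise operations per node irrespective of the number of characters:
the per-character set intersection/union and the "intersection empty"
test are carried out blockwise with shift/mask folds and a single
popcount.  Only total tree length is computed here; the readable
per-character path lives in :mod:`parsclad.parsimony`.
"""

from __future__ import annotations

from .matrix import MISSING, CharacterMatrix

BLOCK = 10          # bits per character
FULL_BLOCK = 0x3FF  # all ten state bits


class PackedMatrix:
    """A character matrix packed for fast total-length Fitch scoring.

    Parameters
    ----------
    matrix:
        Source matrix.
    order:
        Taxon row indices in rep order: rep leaf ``k`` is taxon
        ``order[k]``; ``order[0]`` is the base leaf.
    weights:
        Optional per-character positive integer weights; a character of
        weight *w* is simply packed *w* times, so a packed length is the
        weighted Fitch length.
    """

    def __init__(self, matrix: CharacterMatrix, order: list[int],
                 weights: list[int] | None = None):
        if weights is None:
            weights = [1] * matrix.n_characters
        cols: list[int] = []  # character column index, repeated per weight
        for j, w in enumerate(weights):
            if w != int(w) or w <= 0:
                raise ValueError("packed weights must be positive integers")
            cols.extend([j] * int(w))
        self.n_blocks = len(cols)
        self.mask1 = int(("0" * (BLOCK - 1) + "1") * self.n_blocks, 2)
        self._mask5 = int(("00000" + "11111") * self.n_blocks, 2)
        cells = matrix.cells
        self.leaf_masks: list[int] = []
        for t in order:
            m = 0
            for b, j in enumerate(cols):
                s = int(cells[t, j])
                if s == MISSING:
                    m |= FULL_BLOCK << (b * BLOCK)
                else:
                    m |= 1 << (b * BLOCK + s)
            self.leaf_masks.append(m)

    def _occupied(self, x: int) -> int:
        """Per-block OR-fold of the ten state bits down to the block LSB."""
        y = (x | (x >> 5)) & self._mask5
        z = y | (y >> 2)
        z |= (z >> 1) | (z >> 2)
        return z & self.mask1

    def length(self, rep) -> int:
        """Total (weighted) Fitch length of the unrooted binary tree ``rep``."""
        masks = self.leaf_masks
        occupied = self._occupied
        mask1 = self.mask1

        def rec(nd) -> tuple[int, int]:
            if isinstance(nd, int):
                return masks[nd], 0
            a, ca = rec(nd[0])
            b, cb = rec(nd[1])
            inter = a & b
            empty = mask1 & ~occupied(inter)
            return inter | ((a | b) & (empty * FULL_BLOCK)), ca + cb + empty.bit_count()

        state, count = rec(rep)
        empty = mask1 & ~occupied(state & masks[0])
        return count + empty.bit_count()
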