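"""Binary presence/absence character matrices with missing values.

A character assigns each taxon one of three states: ``1`` (present, the
derived state), ``0`` (absent, the ancestral state) or ``?`` (ambiguous /
missing).  Internally the matrix is stored as two boolean numpy arrays of
shape ``(k, n)`` -- ``ones`` and ``missing`` -- so per-character set tests
used by the labeling kernel vectorize across characters.  Per-character
taxon bit masks are also exposed for the clade-based APIs.
"""

from __future__ import annotations

from typing import Iterable, List, Sequence, Tuple

import numpy as np

from .taxa import TaxonSet, bits

__all__ = ["CharacterMatrix"]

_STATE_CHARS = {0: "0", 1: "1", 2: "?"}


def _mask_from_row(row: np.ndarray) -> int:
    """Pack a boolean vector (taxon axis) into a bit-mask int."""
    packed = np.packbits(row.astype(np.uint8), bitorder="little")
    return int.from_bytes(packed.tobytes(), "little")


class CharacterMatrix:
    """A set of ordered binary characters over a fixed taxon set.

    For every character the taxa are partitioned into *ones*, *zeros* and
    *missing*; the three sets are pairwise disjoint and cover the taxon set.
    """

    def __init__(self, taxa: TaxonSet, ones: np.ndarray, missing: np.ndarray):
        ones = np.asarray(ones, dtype=bool)
        missing = np.asarray(missing, dtype=bool)
        if ones.ndim != 2 or ones.shape != missing.shape:
            raise ValueError("ones and missing must be (k, n) boolean arrays of equal shape")
        if ones.shape[1] != taxa.n:
            raise ValueError(f"matrix has {ones.shape[1]} columns but taxon set has {taxa.n}")
        if np.any(ones & missing):
            raise ValueError("a cell cannot be both 1 and missing")
        self.taxa = taxa
        self.ones = ones
        self.missing = missing
        self.k = ones.shape[0]
        self.n = taxa.n
        self._ones_masks: List[int] | None = None
        self._missing_masks: List[int] | None = None

    # ------------------------------------------------------------------ #
    # constructors

    @classmethod
    def from_triples(
        cls, taxa: TaxonSet, triples: Iterable[Tuple[int, int, int]]
    ) -> "CharacterMatrix":
        """Build from per-character ``(ones, zeros, missing)`` bit masks.

        The three masks of each triple must partition the taxon set.
        """
        triples = list(triples)
        k = len(triples)
        ones = np.zeros((k, taxa.n), dtype=bool)
        missing = np.zeros((k, taxa.n), dtype=bool)
        for i, (o, z, m) in enumerate(triples):
            if o & z or o & m or z & m or (o | z | m) != taxa.full_mask:
                raise ValueError(f"character {i}: masks do not partition the taxon set")
            for j in bits(o):
                ones[i, j] = True
            for j in bits(m):
                missing[i, j] = True
        return cls(taxa, ones, missing)

    @classmethod
    def from_rows(cls, taxa: TaxonSet, rows: Sequence[str]) -> "CharacterMatrix":
        """Build from per-taxon state strings over ``{0,1,?}`` (row = taxon)."""
        if len(rows) != taxa.n:
            raise ValueError("one row per taxon required")
        k = len(rows[0]) if rows else 0
        ones = np.zeros((k, taxa.n), dtype=bool)
        missing = np.zeros((k, taxa.n), dtype=bool)
        for j, row in enumerate(rows):
            if len(row) != k:
                raise ValueError(f"row {j} has length {len(row)}, expected {k}")
            for i, ch in enumerate(row):
                if ch == "1":
                    ones[i, j] = True
                elif ch == "?":
                    missing[i, j] = True
                elif ch != "0":
                    raise ValueError(f"illegal state {ch!r}")
        return cls(taxa, ones, missing)

    # ------------------------------------------------------------------ #
    # per-character masks

    def _build_masks(self) -> None:
        self._ones_masks = [_mask_from_row(self.ones[i]) for i in range(self.k)]
        self._missing_masks = [_mask_from_row(self.missing[i]) for i in range(self.k)]

    @property
    def ones_masks(self) -> List[int]:
        if self._ones_masks is None:
            self._build_masks()
        return self._ones_masks  # type: ignore[return-value]

    @property
    def missing_masks(self) -> List[int]:
        if self._missing_masks is None:
            self._build_masks()
        return self._missing_masks  # type: ignore[return-value]

    def char_triple(self, i: int) -> Tuple[int, int, int]:
        """``(ones, zeros, missing)`` masks of character ``i``."""
        o = self.ones_masks[i]
        m = self.missing_masks[i]
        z = self.taxa.full_mask & ~o & ~m
        return o, z, m

    def triples(self) -> List[Tuple[int, int, int]]:
        return [self.char_triple(i) for i in range(self.k)]

    # ------------------------------------------------------------------ #
    # vectorized membership tests (used by the labeling kernel)

    def _idx(self, mask: int) -> List[int]:
        return bits(mask)

    def any_ones(self, mask: int) -> np.ndarray:
        """Boolean (k,) vector: character has >=1 state-1 taxon inside ``mask``."""
        idx = self._idx(mask)
        if not idx:
            return np.zeros(self.k, dtype=bool)
        return self.ones[:, idx].any(axis=1)

    def any_zeros(self, mask: int) -> np.ndarray:
        idx = self._idx(mask)
        if not idx:
            return np.zeros(self.k, dtype=bool)
        sub_one = self.ones[:, idx]
        sub_mis = self.missing[:, idx]
        return (~sub_one & ~sub_mis).any(axis=1)

    def any_nonmissing(self, mask: int) -> np.ndarray:
        idx = self._idx(mask)
        if not idx:
            return np.zeros(self.k, dtype=bool)
        return (~self.missing[:, idx]).any(axis=1)

    # ------------------------------------------------------------------ #
    # misc

    def row_string(self, taxon_index: int) -> str:
        """The taxon's states as a ``0/1/?`` string (file-writer order)."""
        out = []
        for i in range(self.k):
            if self.missing[i, taxon_index]:
                out.append("?")
            elif self.ones[i, taxon_index]:
                out.append("1")
            else:
                out.append("0")
        return "".join(out)

    def informative_flags(self) -> np.ndarray:
        """Parsimony informativeness: >=2 ones and >=2 zeros among non-missing."""
        n_ones = self.ones.sum(axis=1)
        n_zero = (~self.ones & ~self.missing).sum(axis=1)
        return (n_ones >= 2) & (n_zero >= 2)

    def select(self, char_indices: Sequence[int]) -> "CharacterMatrix":
        idx = list(char_indices)
        return CharacterMatrix(self.taxa, self.ones[idx], self.missing[idx])

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, CharacterMatrix)
            and self.taxa == other.taxa
            and self.ones.shape == other.ones.shape
            and bool(np.array_equal(self.ones, other.ones))
            and bool(np.array_equal(self.missing, other.missing))
        )

    def __repr__(self) -> str:
        return f"<CharacterMatrix n={self.n} k={self.k}>"
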