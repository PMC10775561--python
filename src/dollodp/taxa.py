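"""Taxon sets and clades as fixed-width bit masks.

Every structure in this package (clades, subtree bipartitions, constraint
sets, DP keys) refers to taxa through bit positions assigned by a
:class:`TaxonSet`.  The order of labels is fixed when the set is created --
typically when the character matrix is read -- and must be shared by all
objects participating in one analysis.

A *clade* is simply a Python ``int`` interpreted as a bit mask over the
taxon positions; the usual set operations are the bitwise operators.
"""

from __future__ import annotations

from typing import Iterable, Iterator, List, Sequence

__all__ = ["TaxonSet", "bits", "iter_bits"]


def iter_bits(mask: int) -> Iterator[int]:
    """Yield the set bit positions of ``mask`` in increasing order."""
    while mask:
        low = mask & -mask
        yield low.bit_length() - 1
        mask ^= low


def bits(mask: int) -> List[int]:
    """Return the set bit positions of ``mask`` as a list."""
    return list(iter_bits(mask))


class TaxonSet:
    """An ordered, immutable collection of unique taxon labels.

    Parameters
    ----------
    labels:
        Taxon names in the order that defines bit positions.

    Raises
    ------
    ValueError
        If labels are empty, duplicated, or contain an empty string.
    """

    __slots__ = ("labels", "index", "n", "full_mask")

    def __init__(self, labels: Sequence[str]):
        labels = tuple(labels)
        if not labels:
            raise ValueError("a TaxonSet needs at least one label")
        if any(not lab for lab in labels):
            raise ValueError("taxon labels must be nonempty strings")
        if len(set(labels)) != len(labels):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise ValueError(f"duplicate taxon labels: {dupes}")
        self.labels = labels
        self.index = {lab: i for i, lab in enumerate(labels)}
        self.n = len(labels)
        self.full_mask = (1 << self.n) - 1

    def mask(self, names: Iterable[str]) -> int:
        """Bit mask for a collection of taxon names."""
        m = 0
        for name in names:
            try:
                m |= 1 << self.index[name]
            except KeyError:
                raise KeyError(f"unknown taxon {name!r}") from None
        return m

    def names(self, mask: int) -> List[str]:
        """Labels of the taxa in ``mask``, in bit-position order."""
        return [self.labels[i] for i in iter_bits(mask)]

    def singleton_masks(self) -> List[int]:
        return [1 << i for i in range(self.n)]

    def __len__(self) -> int:
        return self.n

    def __iter__(self) -> Iterator[str]:
        return iter(self.labels)

    def __contains__(self, name: object) -> bool:
        return name in self.index

    def __eq__(self, other: object) -> bool:
        return isinstance(other, TaxonSet) and self.labels == other.labels

    def __hash__(self) -> int:
        return hash(self.labels)

    def __repr__(self) -> str:
        return f"TaxonSet({list(self.labels)!r})"
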