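"""Ancestral state assignment and fixed-tree scoring for Dollo and Camin-Sokal.

Under Dollo parsimony each character is gained (0->1) at most once and the
score counts the 1->0 losses.  The key structural fact exploited throughout
this package is that the optimal (and, with the missing-data convention
below, unique) state of an internal vertex is determined *locally*:

* Dollo: by the vertex's subtree bipartition X|Y alone.  With Z the taxa
  outside X u Y, the state is ``?`` when every taxon of X u Y is missing;
  otherwise it is 1 exactly when ones occur in at least two of the three
  sets X, Y, Z; otherwise 0.
* Camin-Sokal (losses prohibited, gains counted): by the vertex's clade A
  alone -- ``?`` when A is entirely missing, else 0 iff A contains a
  non-missing 0, else 1.

Substitutions are never counted on an edge with a ``?`` endpoint.  These
local rules are what allow the clade-constrained dynamic program in
:mod:`dollodp.solver` to decouple characters from topology.

State vectors over the k characters are stored as a pair of k-bit integers
(ones mask, missing mask) so they hash cheaply and transition counting is a
couple of popcounts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np

from .characters import CharacterMatrix
from .trees import Node, RootedTree

__all__ = [
    "StateVector",
    "get_state_dollo",
    "get_state_camsok",
    "count_transitions",
    "score_fixed_tree",
    "gains_constant",
]


@dataclass(frozen=True)
class StateVector:
    """States of k characters at one vertex: bit i of ``ones``/``missing``
    marks state 1 / state ``?`` for character i (else state 0)."""

    ones: int
    missing: int
    k: int

    def __post_init__(self) -> None:
        if self.ones & self.missing:
            raise ValueError("a character cannot be both 1 and ?")

    @classmethod
    def from_arrays(cls, ones: np.ndarray, missing: np.ndarray) -> "StateVector":
        return cls(_pack(ones), _pack(missing), len(ones))

    @classmethod
    def from_string(cls, states: str) -> "StateVector":
        ones = sum(1 << i for i, ch in enumerate(states) if ch == "1")
        miss = sum(1 << i for i, ch in enumerate(states) if ch == "?")
        if any(ch not in "01?" for ch in states):
            raise ValueError("states must be over {0,1,?}")
        return cls(ones, miss, len(states))

    def sort_key(self) -> Tuple[int, int]:
        return (self.ones, self.missing)

    def __str__(self) -> str:
        out = []
        for i in range(self.k):
            bit = 1 << i
            out.append("1" if self.ones & bit else "?" if self.missing & bit else "0")
        return "".join(out)


def _pack(arr: np.ndarray) -> int:
    packed = np.packbits(np.asarray(arr, dtype=bool), bitorder="little")
    return int.from_bytes(packed.tobytes(), "little")


# ---------------------------------------------------------------------- #
# GetState: per-vertex labeling from local information


def get_state_dollo(
    x: int,
    y: int,
    matrix: CharacterMatrix,
    universe: Optional[int] = None,
) -> StateVector:
    """Dollo state of the vertex inducing subtree bipartition ``x | y``.

    ``universe`` is the leaf set of the tree being labeled (defaults to the
    full taxon set); the outside set Z is taken within it.
    """
    if x & y:
        raise ValueError("bipartition sides overlap")
    if x == 0 or y == 0:
        raise ValueError("bipartition sides must be nonempty")
    if universe is None:
        universe = matrix.taxa.full_mask
    z = universe & ~x & ~y
    ox = matrix.any_ones(x)
    oy = matrix.any_ones(y)
    oz = matrix.any_ones(z)
    nonmiss = matrix.any_nonmissing(x | y)
    one = (ox & oy) | (ox & oz) | (oy & oz)
    return StateVector.from_arrays(one & nonmiss, ~nonmiss)


def get_state_camsok(
    a: int,
    matrix: CharacterMatrix,
    universe: Optional[int] = None,  # noqa: ARG001 - kept for API symmetry
) -> StateVector:
    """Camin-Sokal state of the vertex inducing clade ``a``."""
    if a == 0:
        raise ValueError("clade must be nonempty")
    zeros = matrix.any_zeros(a)
    nonmiss = matrix.any_nonmissing(a)
    return StateVector.from_arrays(~zeros & nonmiss, ~nonmiss)


def leaf_state(matrix: CharacterMatrix, taxon_index: int) -> StateVector:
    """The input character column of one taxon as a StateVector."""
    return StateVector.from_arrays(matrix.ones[:, taxon_index], matrix.missing[:, taxon_index])


# ---------------------------------------------------------------------- #
# CountLosses / CountGains


def count_transitions(
    parent: StateVector,
    left: StateVector,
    right: StateVector,
    kind: str = "loss",
) -> int:
    """Transitions on the two edges from a vertex to its children.

    ``loss`` counts parent 1 -> child 0; ``gain`` counts parent 0 -> child 1.
    Edges with a ``?`` endpoint never contribute.
    """
    if not (parent.k == left.k == right.k):
        raise ValueError("state vector lengths differ")
    full = (1 << parent.k) - 1
    if kind == "loss":
        src = parent.ones
        return (
            (src & ~left.ones & ~left.missing).bit_count()
            + (src & ~right.ones & ~right.missing).bit_count()
        )
    if kind == "gain":
        src = full & ~parent.ones & ~parent.missing
        return (src & left.ones).bit_count() + (src & right.ones).bit_count()
    raise ValueError(f"unknown transition kind {kind!r}")


# ---------------------------------------------------------------------- #
# fixed-tree scoring


def gains_constant(matrix: CharacterMatrix, within: Optional[int] = None) -> int:
    """Number of characters with at least one non-missing 1 (optionally
    restricted to the taxa in ``within``).

    Under Dollo each such character needs exactly one gain, on the tree or
    implied above its root; the quantity is an additive constant for any
    fixed matrix, independent of topology.
    """
    if within is None:
        within = matrix.taxa.full_mask
    return int(matrix.any_ones(within).sum())


def score_fixed_tree(
    tree: RootedTree,
    matrix: CharacterMatrix,
    criterion: str = "dollo",
    count_gains: bool = False,
    return_labels: bool = False,
) -> Tuple[int, Optional[Dict[Node, StateVector]]]:
    """Score a fixed rooted binary tree and optionally return its labeling.

    The labeling is computed in linear time per character via postorder
    one-counts, which is algebraically equivalent to evaluating the local
    Dollo conditions at every vertex (the equivalence is exercised by the
    test suite).  Taxa absent from the tree are ignored: the conditions use
    the tree's own leaf universe.

    Returns ``(score, labels)`` where ``labels`` maps every vertex to its
    StateVector (``None`` unless ``return_labels``).
    """
    if criterion not in ("dollo", "camsok"):
        raise ValueError(f"unknown criterion {criterion!r}")
    if not tree.is_binary():
        raise ValueError("scoring requires a binary tree")
    k = matrix.k
    # state codes per vertex: 0, 1, 2 (= ?)
    states: Dict[Node, np.ndarray] = {}
    ones_cnt: Dict[Node, np.ndarray] = {}
    nm_cnt: Dict[Node, np.ndarray] = {}
    zero_any: Dict[Node, np.ndarray] = {}

    order = list(tree.postorder())
    root = tree.root
    for v in order:
        if v.is_leaf:
            o = matrix.ones[:, v.taxon]
            m = matrix.missing[:, v.taxon]
            ones_cnt[v] = o.astype(np.int32)
            nm_cnt[v] = (~m).astype(np.int32)
            zero_any[v] = ~o & ~m
            st = np.zeros(k, dtype=np.int8)
            st[o] = 1
            st[m] = 2
            states[v] = st
        else:
            a, b = v.children
            ones_cnt[v] = ones_cnt[a] + ones_cnt[b]
            nm_cnt[v] = nm_cnt[a] + nm_cnt[b]
            zero_any[v] = zero_any[a] | zero_any[b]

    total_ones = ones_cnt[root]
    for v in order:
        if v.is_leaf:
            continue
        a, b = v.children
        if criterion == "dollo":
            inside = ones_cnt[v]
            one = ((ones_cnt[a] > 0) & (ones_cnt[b] > 0)) | (
                (inside > 0) & ((total_ones - inside) > 0)
            )
        else:
            one = ~zero_any[v]
        st = np.where(nm_cnt[v] == 0, np.int8(2), np.where(one, np.int8(1), np.int8(0)))
        states[v] = st

    score = 0
    for v in order:
        if v.is_leaf:
            continue
        sv = states[v]
        for ch in v.children:
            sc = states[ch]
            if criterion == "dollo":
                score += int(((sv == 1) & (sc == 0)).sum())
            else:
                score += int(((sv == 0) & (sc == 1)).sum())
    if count_gains and criterion == "dollo":
        score += gains_constant(matrix, within=tree.leaf_mask())

    labels: Optional[Dict[Node, StateVector]] = None
    if return_labels:
        labels = {
            v: StateVector.from_arrays(states[v] == 1, states[v] == 2) for v in order
        }
    return score, labels
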