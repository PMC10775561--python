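"""The clade-constrained dynamic program and a brute-force oracle.

Subproblems are pairs ``(A, st)`` of a clade ``A`` in Sigma and an allowed
root state ``st`` in ``Lab(A)``: the value is the minimum transition count
of any rooted binary tree on leaf set A drawing all clades from Sigma,
labeled by the local rule, with state ``st`` at its root.  Singletons cost
zero; larger clades minimize over allowed bipartitions X|Y of A that induce
``st`` and over the children's allowed states:

    best[A, st] = min over X|Y, St_X, St_Y of
                  best[X, St_X] + best[Y, St_Y] + transitions(st, St_X, St_Y)

Clades are processed in order of increasing cardinality.  The optimum is
the minimum of ``best[S, st]`` over the allowed root states of the full
taxon set; an optimal tree is recovered by backtracking.  Ties are broken
deterministically (smaller canonical bipartition, then smaller child
states) so repeated runs return byte-identical trees.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from .characters import CharacterMatrix
from .constraints import ConstraintSet, build_constraint_set, check_solvable, compute_labels
from .labeling import StateVector, count_transitions, score_fixed_tree
from .trees import Bip, Node, RootedTree, enumerate_rooted_trees

__all__ = ["DPTable", "solve", "solve_sigma", "traceback", "brute_force_best"]

_Key = Tuple[int, StateVector]


@dataclass
class DPTable:
    """Scores and backpointers of the dynamic program."""

    score: Dict[_Key, int] = field(default_factory=dict)
    back: Dict[_Key, Tuple[Bip, StateVector, StateVector]] = field(default_factory=dict)
    best_root: Optional[_Key] = None


def solve(
    cs: ConstraintSet,
    matrix: CharacterMatrix,
    criterion: str = "dollo",
    return_table: bool = False,
):
    """Solve the clade-constrained large Dollo (or Camin-Sokal) problem.

    Requires a solvable constraint set.  Returns ``(score, tree, root_state)``
    -- and the :class:`DPTable` as a fourth element when ``return_table``.
    The returned tree satisfies ``Clade(tree) <= Sigma`` and rescoring it
    with the fixed-tree scorer reproduces ``score``.
    """
    if cs.criterion != criterion or not cs.lab:
        compute_labels(cs, matrix, criterion)
    if not check_solvable(cs.sigma, cs.stb):
        raise ValueError("constraint set is unsolvable; no tree on S draws all clades from Sigma")
    kind = "loss" if criterion == "dollo" else "gain"
    full = cs.full_mask

    table = DPTable()
    score = table.score
    back = table.back
    for a in sorted(cs.sigma, key=lambda m: (m.bit_count(), m)):
        if a.bit_count() == 1:
            score[(a, cs.lab[a][0])] = 0
            continue
        for st in cs.lab[a]:
            best: Optional[int] = None
            best_bp: Optional[Tuple[Bip, StateVector, StateVector]] = None
            for bip in cs.stb_by_state[(a, st)]:
                x, y = bip
                for st_x in cs.lab[x]:
                    left = score.get((x, st_x))
                    if left is None:
                        continue
                    for st_y in cs.lab[y]:
                        right = score.get((y, st_y))
                        if right is None:
                            continue
                        val = left + right + count_transitions(st, st_x, st_y, kind)
                        if best is None or val < best:
                            best = val
                            best_bp = (bip, st_x, st_y)
            if best is not None:
                score[(a, st)] = best
                back[(a, st)] = best_bp  # type: ignore[assignment]

    root_candidates = [(score[(full, st)], st) for st in cs.lab[full] if (full, st) in score]
    if not root_candidates:
        raise ValueError("no allowed root state for the full taxon set")
    best_score = min(v for v, _ in root_candidates)
    best_st = min((st for v, st in root_candidates if v == best_score), key=StateVector.sort_key)
    table.best_root = (full, best_st)
    tree = traceback(table, cs)
    if return_table:
        return best_score, tree, best_st, table
    return best_score, tree, best_st


def traceback(table: DPTable, cs: ConstraintSet) -> RootedTree:
    """Rebuild an optimal tree from the backpointers (deterministic)."""
    if table.best_root is None:
        raise ValueError("solve the table before tracing back")

    def rec(key: _Key) -> Node:
        a, _st = key
        if a.bit_count() == 1:
            return Node(taxon=a.bit_length() - 1)
        entry = table.back.get(key)
        if entry is None:
            raise RuntimeError("dangling backpointer: DP invariant breached")
        (x, y), st_x, st_y = entry
        return Node(children=[rec((x, st_x)), rec((y, st_y))])

    return RootedTree(rec(table.best_root), cs.taxa).canonicalize()


def solve_sigma(
    sigma,
    matrix: CharacterMatrix,
    criterion: str = "dollo",
    outgroup: int = 0,
    allow_repair: bool = False,
):
    """Convenience wrapper: build the constraint structures, then solve."""
    cs, _ = build_constraint_set(
        set(sigma), matrix, criterion=criterion, outgroup=outgroup, allow_repair=allow_repair
    )
    return solve(cs, matrix, criterion)


def brute_force_best(
    matrix: CharacterMatrix,
    criterion: str = "dollo",
    n_cap: int = 9,
) -> Tuple[int, List[RootedTree]]:
    """Exhaustive minimum of the fixed-tree score over all rooted binary
    topologies; returns the optimum and every optimal tree.

    The independent oracle for the dynamic program: it never touches the
    constraint machinery.
    """
    n = matrix.taxa.n
    if n > n_cap or n_cap > 9:
        raise ValueError(f"brute force limited to {min(n_cap, 9)} taxa, got {n}")
    best: Optional[int] = None
    argmin: List[RootedTree] = []
    for tree in enumerate_rooted_trees(matrix.taxa):
        s, _ = score_fixed_tree(tree, matrix, criterion=criterion)
        if best is None or s < best:
            best = s
            argmin = [tree]
        elif s == best:
            argmin.append(tree)
    assert best is not None
    return best, argmin
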