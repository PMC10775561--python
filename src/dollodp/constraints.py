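"""Constraint-set construction: the clade set Sigma and derived structures.

The search space of the clade-constrained parsimony problems is a set Sigma
of clades (taxon subsets): a candidate tree may only use clades drawn from
Sigma.  From Sigma we derive

* ``stb[A]``   -- the allowed subtree bipartitions of clade A, i.e. pairs
  X|Y with X, Y, X u Y = A all in Sigma;
* ``lab[A]``   -- the allowed root states of a subtree on A, the image of
  ``stb[A]`` under the local labeling rule (for leaves: the input column);
* ``stb_by_state[A, st]`` -- the bipartitions of A whose induced state is st.

Sigma is *solvable* if at least one binary tree on the full taxon set draws
all its clades from it; builders in this module either guarantee that or
repair it by adding the clades of a deterministic greedy seed tree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np

from .characters import CharacterMatrix
from .labeling import StateVector, get_state_camsok, get_state_dollo, leaf_state, score_fixed_tree
from .taxa import TaxonSet, iter_bits
from .trees import Bip, Node, RootedTree, root_at_outgroup

__all__ = [
    "ConstraintSet",
    "sigma_from_trees",
    "characters_to_splits_trees",
    "sigma_from_characters",
    "import_clades",
    "seed_tree",
    "compute_stb",
    "build_constraint_set",
    "check_solvable",
]

log = logging.getLogger(__name__)


@dataclass
class ConstraintSet:
    """Sigma plus the precomputed STB / Lab maps for one criterion."""

    taxa: TaxonSet
    sigma: Set[int]
    stb: Dict[int, List[Bip]] = field(default_factory=dict)
    lab: Dict[int, List[StateVector]] = field(default_factory=dict)
    stb_by_state: Dict[Tuple[int, StateVector], List[Bip]] = field(default_factory=dict)
    criterion: Optional[str] = None

    @property
    def full_mask(self) -> int:
        return self.taxa.full_mask


# ---------------------------------------------------------------------- #
# Sigma builders


def _with_trivial(sigma: Set[int], taxa: TaxonSet) -> Set[int]:
    sigma = set(sigma)
    sigma.update(taxa.singleton_masks())
    sigma.add(taxa.full_mask)
    sigma.discard(0)
    return sigma


def _outgroup_filter(clades: Iterable[int], outgroup: int, taxa: TaxonSet) -> Set[int]:
    """Keep clades entirely inside the outgroup or entirely inside the ingroup."""
    ingroup = taxa.full_mask & ~outgroup
    return {c for c in clades if c and (c & ~outgroup == 0 or c & ~ingroup == 0)}


def sigma_from_trees(
    trees: Sequence[RootedTree], outgroup: int, taxa: TaxonSet
) -> Set[int]:
    """Union of clade sets of the input trees rooted at the outgroup.

    Clades straddling the outgroup/ingroup boundary are dropped; all
    singletons and the full taxon set are always included.  Trees on a leaf
    subset contribute their clades as masks over the full set.  With an
    empty outgroup the trees are used with their given rooting (they must
    be binary-rooted as read).
    """
    sigma: Set[int] = set()
    for tree in trees:
        if outgroup:
            rooted = root_at_outgroup(tree, outgroup & tree.leaf_mask() or outgroup)
        else:
            rooted = tree
        sigma.update(rooted.clades())
    sigma = _outgroup_filter(sigma, outgroup, taxa)
    return _with_trivial(sigma, taxa)


def characters_to_splits_trees(matrix: CharacterMatrix) -> List[RootedTree]:
    """Encode each parsimony-informative character as an unrooted split tree.

    The tree has one internal edge separating the character's ones from its
    zeros (each side a multifurcation); missing taxa are omitted.
    Non-informative characters are skipped.
    """
    out: List[RootedTree] = []
    flags = matrix.informative_flags()
    for i in range(matrix.k):
        if not flags[i]:
            continue
        ones, zeros, _ = matrix.char_triple(i)
        side1 = Node(children=[Node(taxon=j) for j in iter_bits(ones)])
        root = Node(children=[Node(taxon=j) for j in iter_bits(zeros)] + [side1])
        out.append(RootedTree(root, matrix.taxa))
    return out


def sigma_from_characters(
    matrix: CharacterMatrix, outgroup: int, seed: int = 0
) -> Set[int]:
    """Clade constraints harvested directly from character splits.

    Each informative character contributes both sides of its split
    (restricted to the ingroup) as clades over the full taxon set; the
    clades of one greedy seed tree are unioned in so the set is always
    solvable.  This is a deterministic, self-contained stand-in for feeding
    the split trees to an external clustering tool.
    """
    taxa = matrix.taxa
    sigma: Set[int] = set()
    flags = matrix.informative_flags()
    ingroup = taxa.full_mask & ~outgroup
    for i in range(matrix.k):
        if not flags[i]:
            continue
        ones, zeros, _ = matrix.char_triple(i)
        for side in (ones, zeros):
            c = side & ingroup
            if c:
                sigma.add(c)
    sigma |= seed_tree(matrix, outgroup, seed).clades()
    sigma = _outgroup_filter(sigma, outgroup, taxa)
    return _with_trivial(sigma, taxa)


def import_clades(path, taxa: TaxonSet) -> Set[int]:
    """Read clades from a text file, one per line, comma/whitespace separated."""
    sigma: Set[int] = set()
    for ln_no, ln in enumerate(Path(path).read_text().splitlines(), start=1):
        names = [x for x in ln.replace(",", " ").split() if x]
        if not names:
            log.debug("clade file line %d empty, skipped", ln_no)
            continue
        try:
            sigma.add(taxa.mask(names))
        except KeyError as exc:
            raise ValueError(f"clade file line {ln_no}: {exc.args[0]}") from None
    return sigma


def export_clades(sigma: Set[int], taxa: TaxonSet, path) -> None:
    lines = [",".join(taxa.names(c)) for c in sorted(sigma, key=lambda m: (bin(m).count("1"), m))]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------- #
# greedy seed tree (solvability guarantee / starting-tree stand-in)


def seed_tree(matrix: CharacterMatrix, outgroup: int, seed: int = 0) -> RootedTree:
    """Deterministic greedy stepwise-addition tree under the Dollo score.

    Taxa are shuffled by ``seed``; each is inserted at the placement that
    minimizes the Dollo score of the partial tree (first-best on ties, in
    canonical edge order).  The outgroup subtree (grown the same way when it
    has several taxa) becomes one child of the root.
    """
    taxa = matrix.taxa
    if taxa.n < 2:
        raise ValueError("need at least two taxa")
    rng = np.random.default_rng(seed)
    ingroup_mask = taxa.full_mask & ~outgroup

    def grow(members: List[int]) -> Node:
        if len(members) == 1:
            return Node(taxon=members[0])
        root = Node(children=[Node(taxon=members[0]), Node(taxon=members[1])])
        for tx in members[2:]:
            root = _best_insertion(root, tx, matrix)
        return root

    def shuffled(mask: int) -> List[int]:
        ids = list(iter_bits(mask))
        rng.shuffle(ids)
        return ids

    if outgroup and ingroup_mask:
        og = grow(shuffled(outgroup))
        ig = grow(shuffled(ingroup_mask))
        root = Node(children=[og, ig])
    else:
        root = grow(shuffled(taxa.full_mask))
    return RootedTree(root, taxa).canonicalize()


def _best_insertion(root: Node, taxon: int, matrix: CharacterMatrix) -> Node:
    """Try attaching ``taxon`` above every node (incl. the root) and keep the
    placement with the lowest Dollo score; mutate and return the new root."""
    tree = RootedTree(root, matrix.taxa)
    targets = list(tree.postorder())  # includes root: insertion above the root
    best: Tuple[int, int] | None = None
    for idx, tgt in enumerate(targets):
        new_leaf = Node(taxon=taxon)
        joint = Node()
        parent = tgt.parent
        if parent is not None:
            pos = parent.children.index(tgt)
            parent.children[pos] = joint
            joint.parent = parent
        joint.children = [tgt, new_leaf]
        tgt.parent = joint
        new_leaf.parent = joint
        score, _ = score_fixed_tree(
            RootedTree(joint if parent is None else root, matrix.taxa), matrix
        )
        # undo
        joint.children = []
        tgt.parent = parent
        if parent is not None:
            parent.children[pos] = tgt
        if best is None or score < best[0]:
            best = (score, idx)
    assert best is not None
    tgt = targets[best[1]]
    new_leaf = Node(taxon=taxon)
    joint = Node()
    parent = tgt.parent
    if parent is not None:
        pos = parent.children.index(tgt)
        parent.children[pos] = joint
        joint.parent = parent
    joint.children = [tgt, new_leaf]
    tgt.parent = joint
    new_leaf.parent = joint
    return root if parent is not None else joint


# ---------------------------------------------------------------------- #
# derived structures


def compute_stb(sigma: Set[int]) -> Dict[int, List[Bip]]:
    """All subtree bipartitions formable from Sigma, grouped by their clade.

    Straight pair scan over Sigma x Sigma with hashed masks; each unordered
    pair is counted once (canonical order: smaller mask first).
    """
    members = sorted(sigma)
    sset = set(members)
    stb: Dict[int, List[Bip]] = {a: [] for a in members}
    for i, x in enumerate(members):
        for y in members[i + 1 :]:
            if x & y:
                continue
            a = x | y
            if a in sset:
                stb[a].append((x, y))
    for a in stb:
        stb[a].sort()
    return stb


def compute_labels(
    cs: ConstraintSet, matrix: CharacterMatrix, criterion: str = "dollo"
) -> ConstraintSet:
    """Populate ``lab`` and ``stb_by_state`` for the given criterion.

    Leaves get the input character column.  For internal clades the state of
    each allowed bipartition is computed with the local labeling rule; under
    Camin-Sokal the state depends on the clade alone, so every bipartition
    of a clade shares one state.
    """
    if criterion not in ("dollo", "camsok"):
        raise ValueError(f"unknown criterion {criterion!r}")
    taxa = cs.taxa
    cs.lab = {}
    cs.stb_by_state = {}
    for a in cs.sigma:
        if a.bit_count() == 1:
            cs.lab[a] = [leaf_state(matrix, a.bit_length() - 1)]
            continue
        seen: Dict[StateVector, List[Bip]] = {}
        if criterion == "camsok":
            st_a = get_state_camsok(a, matrix)
            for bip in cs.stb.get(a, []):
                seen.setdefault(st_a, []).append(bip)
        else:
            for bip in cs.stb.get(a, []):
                st = get_state_dollo(bip[0], bip[1], matrix, universe=taxa.full_mask)
                seen.setdefault(st, []).append(bip)
        cs.lab[a] = sorted(seen, key=StateVector.sort_key)
        for st, bips in seen.items():
            cs.stb_by_state[(a, st)] = sorted(bips)
    cs.criterion = criterion
    return cs


def check_solvable(sigma: Set[int], stb: Optional[Dict[int, List[Bip]]] = None) -> bool:
    """True iff some binary tree on the full taxon set draws all clades from Sigma.

    A clade is *buildable* if it is a singleton or has an allowed bipartition
    into two buildable clades; Sigma is solvable iff the full set is
    buildable (computed bottom-up by cardinality).
    """
    if not sigma:
        return False
    full = max(sigma)  # the full set is the numerically largest mask iff present
    for c in sigma:
        full |= c
    if full not in sigma:
        return False
    if stb is None:
        stb = compute_stb(sigma)
    buildable: Set[int] = set()
    for a in sorted(sigma, key=lambda m: m.bit_count()):
        if a.bit_count() == 1:
            buildable.add(a)
        elif any(x in buildable and y in buildable for x, y in stb.get(a, [])):
            buildable.add(a)
    return full in buildable


def build_constraint_set(
    sigma: Set[int],
    matrix: CharacterMatrix,
    criterion: str = "dollo",
    outgroup: int = 0,
    repair_seed: int = 0,
    allow_repair: bool = True,
) -> Tuple[ConstraintSet, bool]:
    """Assemble a ready-to-solve ConstraintSet, repairing solvability if needed.

    If Sigma is unsolvable and ``allow_repair``, the clades of a greedy seed
    tree are unioned in (guaranteeing a solution) and a warning is logged.
    Returns ``(constraint_set, repaired)``.
    """
    taxa = matrix.taxa
    sigma = _with_trivial(sigma, taxa)
    repaired = False
    stb = compute_stb(sigma)
    if not check_solvable(sigma, stb):
        if not allow_repair:
            raise ValueError("constraint set is unsolvable")
        log.warning("constraint set unsolvable; adding greedy seed-tree clades")
        sigma = sigma | seed_tree(matrix, outgroup, repair_seed).clades()
        sigma = _with_trivial(sigma, taxa)
        stb = compute_stb(sigma)
        repaired = True
        if not check_solvable(sigma, stb):
            raise AssertionError("seed-tree repair failed to make Sigma solvable")
    cs = ConstraintSet(taxa=taxa, sigma=sigma, stb=stb)
    compute_labels(cs, matrix, criterion)
    return cs, repaired
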