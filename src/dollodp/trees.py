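"""Rooted phylogenetic trees over a TaxonSet, plus structural operations.

Trees are mutable linked structures of :class:`Node` objects.  Leaves carry
a taxon bit position; internal nodes carry a ``children`` list (binary trees
have exactly two children, but multifurcations are permitted for trees that
only serve as clade sources, e.g. characters encoded as split trees).

Clades are bit-mask ints (see :mod:`dollodp.taxa`); a subtree bipartition is
a canonical pair ``(x, y)`` with ``x < y`` numerically.
"""

from __future__ import annotations

from typing import Dict, Iterator, List, Optional, Sequence, Set, Tuple

from .taxa import TaxonSet, iter_bits

__all__ = [
    "Node",
    "RootedTree",
    "canonical_bip",
    "root_at_outgroup",
    "enumerate_rooted_trees",
    "random_rooted_tree",
    "num_rooted_trees",
]

Bip = Tuple[int, int]


def canonical_bip(x: int, y: int) -> Bip:
    """Order the two sides of a subtree bipartition (smaller mask first)."""
    if x == y or (x & y):
        raise ValueError("bipartition sides must be distinct and disjoint")
    return (x, y) if x < y else (y, x)


class Node:
    __slots__ = ("children", "parent", "taxon", "length")

    def __init__(
        self,
        children: Optional[List["Node"]] = None,
        taxon: Optional[int] = None,
        length: Optional[float] = None,
    ):
        self.children: List[Node] = children if children is not None else []
        self.parent: Optional[Node] = None
        self.taxon = taxon
        self.length = length
        for ch in self.children:
            ch.parent = self

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, node: "Node") -> None:
        node.parent = self
        self.children.append(node)

    def remove_child(self, node: "Node") -> None:
        self.children.remove(node)
        node.parent = None


class RootedTree:
    """A rooted tree whose leaves map bijectively to a subset of a TaxonSet."""

    def __init__(self, root: Node, taxa: TaxonSet):
        self.root = root
        self.taxa = taxa

    # ------------------------------------------------------------------ #
    # traversal

    def postorder(self) -> Iterator[Node]:
        stack: List[Tuple[Node, bool]] = [(self.root, False)]
        while stack:
            node, seen = stack.pop()
            if seen or node.is_leaf:
                yield node
            else:
                stack.append((node, True))
                for ch in reversed(node.children):
                    stack.append((ch, False))

    def leaves(self) -> List[Node]:
        return [v for v in self.postorder() if v.is_leaf]

    def leaf_mask(self) -> int:
        m = 0
        for v in self.leaves():
            m |= 1 << v.taxon
        return m

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    def is_binary(self) -> bool:
        return all(v.is_leaf or len(v.children) == 2 for v in self.postorder())

    # ------------------------------------------------------------------ #
    # clades and subtree bipartitions

    def clade_map(self) -> Dict[Node, int]:
        """Map every vertex to its clade mask (postorder accumulation)."""
        out: Dict[Node, int] = {}
        for v in self.postorder():
            if v.is_leaf:
                out[v] = 1 << v.taxon
            else:
                m = 0
                for ch in v.children:
                    m |= out[ch]
                out[v] = m
        return out

    def clades(self) -> Set[int]:
        return set(self.clade_map().values())

    def subtree_bipartitions(self) -> Set[Bip]:
        """One bipartition per internal vertex; requires a binary tree."""
        cm = self.clade_map()
        out: Set[Bip] = set()
        for v in cm:
            if v.is_leaf:
                continue
            if len(v.children) != 2:
                raise ValueError("subtree bipartitions require a binary tree")
            out.add(canonical_bip(cm[v.children[0]], cm[v.children[1]]))
        return out

    # ------------------------------------------------------------------ #
    # structural operations

    def copy(self) -> "RootedTree":
        def rec(node: Node) -> Node:
            new = Node(taxon=node.taxon, length=node.length)
            for ch in node.children:
                new.add_child(rec(ch))
            return new

        return RootedTree(rec(self.root), self.taxa)

    def canonicalize(self) -> "RootedTree":
        """Sort children by clade mask so output and traversal are stable."""
        cm = self.clade_map()
        for v in cm:
            if not v.is_leaf:
                v.children.sort(key=lambda ch: cm[ch])
        return self

    def restrict(self, mask: int) -> "RootedTree":
        """Restrict to the taxa in ``mask``: prune leaves, suppress unary nodes."""
        if mask == 0:
            raise ValueError("cannot restrict a tree to the empty taxon set")

        def rec(node: Node) -> Optional[Node]:
            if node.is_leaf:
                if (1 << node.taxon) & mask:
                    return Node(taxon=node.taxon, length=node.length)
                return None
            kept = [c for c in (rec(ch) for ch in node.children) if c is not None]
            if not kept:
                return None
            if len(kept) == 1:
                child = kept[0]
                if node.length is not None and child.length is not None:
                    child.length += node.length
                return child
            return Node(children=kept, length=node.length)

        root = rec(self.root)
        if root is None:
            raise ValueError("restriction mask shares no taxa with the tree")
        root.length = None
        return RootedTree(root, self.taxa)

    # ------------------------------------------------------------------ #
    # serialization

    def newick(self, lengths: bool = False) -> str:
        def rec(node: Node) -> str:
            if node.is_leaf:
                s = self.taxa.labels[node.taxon]
            else:
                s = "(" + ",".join(rec(ch) for ch in node.children) + ")"
            if lengths and node.length is not None:
                s += f":{node.length:g}"
            return s

        return rec(self.root) + ";"

    def __repr__(self) -> str:
        return f"<RootedTree {self.newick()}>"


# ---------------------------------------------------------------------- #
# outgroup rooting


def root_at_outgroup(tree: RootedTree, outgroup: int) -> RootedTree:
    """Re-root so the outgroup taxa form one child of the root.

    The input is interpreted as an unrooted topology (its current root is
    arbitrary).  The outgroup must be displayable as one side of some edge;
    otherwise a ``ValueError`` names the offending taxa.
    """
    if outgroup == 0:
        raise ValueError("outgroup must be nonempty")
    work = tree.copy()
    leaf_mask = work.leaf_mask()
    if outgroup & ~leaf_mask:
        missing = work.taxa.names(outgroup & ~leaf_mask)
        raise ValueError(f"outgroup taxa not in tree: {missing}")
    ingroup = leaf_mask & ~outgroup
    if ingroup == 0:
        raise ValueError("outgroup cannot contain every leaf of the tree")

    cm = work.clade_map()

    # Already rooted compatibly: some root child displays the outgroup side.
    for ch in work.root.children:
        if cm[ch] == outgroup and len(work.root.children) == 2:
            return work.canonicalize()

    # Find an edge (above `v`) whose below-set is the outgroup or its complement.
    target = None
    for v, m in cm.items():
        if v is work.root:
            continue
        if m == outgroup or m == (leaf_mask & ~outgroup):
            target = v
            break
    if target is None:
        raise ValueError(
            "outgroup is not monophyletic in the tree: "
            f"{tree.taxa.names(outgroup)}"
        )

    new_root = Node(children=[])
    parent = target.parent
    assert parent is not None
    parent.remove_child(target)
    other_side = _reorient(parent, work.root)
    for node in (target, other_side):
        node.parent = None
    new_root.add_child(target)
    new_root.add_child(other_side)
    out = RootedTree(new_root, work.taxa)
    # Present the outgroup side consistently, then canonical child order below.
    out.canonicalize()
    cm2 = out.clade_map()
    out.root.children.sort(key=lambda ch: (cm2[ch] != outgroup, cm2[ch]))
    return out


def _reorient(node: Node, old_root: Node) -> Node:
    """Turn the path from ``node`` up to the old root into descendants of ``node``."""
    if node is old_root:
        if len(node.children) == 1:
            # binary old root loses one side: suppress it
            child = node.children[0]
            node.remove_child(child)
            return child
        return node
    parent = node.parent
    assert parent is not None
    parent.remove_child(node)
    node.add_child(_reorient(parent, old_root))
    return node


# ---------------------------------------------------------------------- #
# exhaustive enumeration (oracle support)

_MAX_ENUM = 9


def num_rooted_trees(n: int) -> int:
    """(2n-3)!! rooted binary topologies on n labeled leaves."""
    if n < 1:
        raise ValueError("n must be positive")
    if n in (1, 2):
        return 1
    count = 1
    for m in range(3, 2 * n - 2, 2):
        count *= m
    return count


def _tuple_insertions(shape, x):
    # Attach leaf x above the root of `shape`, then recursively inside.
    yield (shape, x)
    if isinstance(shape, tuple):
        left, right = shape
        for l2 in _tuple_insertions(left, x):
            yield (l2, right)
        for r2 in _tuple_insertions(right, x):
            yield (left, r2)


def _tuple_trees(leaves: Sequence[int]):
    if len(leaves) == 1:
        yield leaves[0]
        return
    for sub in _tuple_trees(leaves[:-1]):
        yield from _tuple_insertions(sub, leaves[-1])


def _from_tuple(shape, taxa: TaxonSet) -> RootedTree:
    def rec(s) -> Node:
        if isinstance(s, tuple):
            return Node(children=[rec(s[0]), rec(s[1])])
        return Node(taxon=s)

    return RootedTree(rec(shape), taxa)


def enumerate_rooted_trees(taxa: TaxonSet, mask: Optional[int] = None) -> Iterator[RootedTree]:
    """Yield every rooted binary topology on the taxa in ``mask`` exactly once.

    Guarded to at most 9 leaves ((2n-3)!! grows too fast beyond that).
    """
    leaves = list(iter_bits(mask)) if mask is not None else list(range(taxa.n))
    n = len(leaves)
    if n < 1:
        raise ValueError("need at least one taxon")
    if n > _MAX_ENUM:
        raise ValueError(f"refusing to enumerate rooted trees on {n} > {_MAX_ENUM} leaves")
    for shape in _tuple_trees(leaves):
        yield _from_tuple(shape, taxa)


def random_rooted_tree(taxa: TaxonSet, rng, mask: Optional[int] = None) -> RootedTree:
    """Uniform random rooted binary topology (random sequential insertion)."""
    leaves = list(iter_bits(mask)) if mask is not None else list(range(taxa.n))
    order = list(leaves)
    rng.shuffle(order)
    if len(order) == 1:
        return RootedTree(Node(taxon=order[0]), taxa)
    shape = order[0]
    for x in order[1:]:
        spots = list(_tuple_insertions(shape, x))
        shape = spots[rng.integers(0, len(spots))]
    return _from_tuple(shape, taxa)
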