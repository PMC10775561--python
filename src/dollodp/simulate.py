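"""Coalescent simulation of retroelement-style presence/absence characters.

Each character is generated by (1) drawing one gene genealogy within a
species tree under the multispecies coalescent, sampling one haploid
lineage per species; (2) dropping a single insertion (0->1 mutation) on a
genealogy branch chosen with probability proportional to its length, so all
descendant species carry state 1 and the rest state 0; (3) optionally
masking cells to ``?`` independently at a fixed rate; and (4) keeping the
character only if it is parsimony-informative (at least two 0s and two 1s
among the non-missing states).  Incomplete lineage sorting is thus the only
source of homoplasy, which Dollo parsimony explains as losses.

Branch lengths of the species tree are in coalescent units (generations
divided by twice the effective population size); with all internal branches
long, genealogies match the species tree and every character's ones-set is
a species-tree clade.
"""

from __future__ import annotations

from typing import List, Optional, Tuple

import numpy as np

from .characters import CharacterMatrix
from .taxa import TaxonSet
from .trees import Node, RootedTree

__all__ = [
    "simulate_characters",
    "perfect_characters",
    "yule_species_tree",
]


# ---------------------------------------------------------------------- #
# one gene genealogy under the multispecies coalescent


def _node_ages(model: RootedTree) -> dict:
    """Age of each species-tree node above the leaves (leaves at age 0)."""
    ages = {}
    for v in model.postorder():
        if v.is_leaf:
            ages[v] = 0.0
        else:
            ages[v] = max(
                ages[ch] + (ch.length if ch.length is not None else 0.0)
                for ch in v.children
            )
    return ages


def _simulate_genealogy(
    model: RootedTree, ages: dict, rng: np.random.Generator
) -> Tuple[dict, List[Tuple[int, int]], List[float]]:
    """One MSC genealogy; one lineage sampled per species.

    Returns ``(leaf_of, edges, edge_lengths)`` where genealogy nodes are
    integers, ``leaf_of`` maps tip node ids to taxon bit positions, and
    each edge ``(child, parent)`` has a positive length in coalescent units.
    """
    leaf_of: dict = {}
    node_time: List[float] = []
    parent_of: dict = {}

    def new_leaf(taxon: int) -> int:
        node_time.append(0.0)
        nid = len(node_time) - 1
        leaf_of[nid] = taxon
        return nid

    def coalesce(lineages: List[int], t0: float, t_end: float) -> Tuple[List[int], float]:
        t = t0
        lin = list(lineages)
        while len(lin) > 1:
            m = len(lin)
            rate = m * (m - 1) / 2.0
            wait = rng.exponential() / rate
            if t + wait > t_end:
                return lin, t_end
            t += wait
            i = int(rng.random() * m)
            j = int(rng.random() * (m - 1))
            if j >= i:
                j += 1
            if j < i:
                i, j = j, i
            node_time.append(t)
            new = len(node_time) - 1
            parent_of[lin[i]] = new
            parent_of[lin[j]] = new
            lin[i] = new
            del lin[j]
        return lin, t_end

    def visit(v: Node) -> List[int]:
        if v.is_leaf:
            return [new_leaf(v.taxon)]
        lin: List[int] = []
        for ch in v.children:
            child_lin = visit(ch)
            length = ch.length if ch.length is not None else 0.0
            lin.extend(
                coalesce(child_lin, ages[ch], ages[ch] + length)[0]
                if len(child_lin) > 1
                else child_lin
            )
        return lin

    root_lin = visit(model.root)
    # above the species-tree root: coalesce to the MRCA without a time bound
    coalesce(root_lin, ages[model.root], np.inf)

    edges = [(c, p) for c, p in parent_of.items()]
    lengths = [node_time[p] - node_time[c] for c, p in edges]
    return leaf_of, edges, lengths


def _descendant_taxa(edge_child: int, edges: List[Tuple[int, int]], leaf_of: dict) -> List[int]:
    """Taxa at the genealogy tips below ``edge_child``."""
    children: dict = {}
    for c, p in edges:
        children.setdefault(p, []).append(c)
    out: List[int] = []
    stack = [edge_child]
    while stack:
        node = stack.pop()
        if node in leaf_of:
            out.append(leaf_of[node])
        else:
            stack.extend(children.get(node, []))
    return out


# ---------------------------------------------------------------------- #
# character generation


def simulate_characters(
    model: RootedTree,
    k_target: int,
    seed: int = 0,
    missing_rate: float = 0.0,
    max_attempts_per_char: int = 10_000,
) -> CharacterMatrix:
    """Simulate ``k_target`` parsimony-informative presence/absence characters.

    Deterministic given ``(model, k_target, seed, missing_rate)``.  Raises
    for fewer than four species (no binary character on <4 taxa can have two
    0s and two 1s) or if the informativeness filter keeps rejecting draws.
    """
    taxa = model.taxa
    n = model.n_leaves
    if n < 4:
        raise ValueError("parsimony-informative characters require at least 4 species")
    if k_target < 1:
        raise ValueError("k_target must be positive")
    if not (0.0 <= missing_rate < 1.0):
        raise ValueError("missing_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    ages = _node_ages(model)

    ones_rows: List[np.ndarray] = []
    miss_rows: List[np.ndarray] = []
    attempts = 0
    budget = max_attempts_per_char * k_target
    while len(ones_rows) < k_target:
        attempts += 1
        if attempts > budget:
            raise RuntimeError(
                f"gave up after {attempts - 1} draws: informative characters too rare"
            )
        leaf_of, edges, lengths = _simulate_genealogy(model, ages, rng)
        total = float(sum(lengths))
        if total <= 0.0:
            continue
        # pick a genealogy branch with probability proportional to its length
        r = rng.random() * total
        edge_idx = 0
        acc = 0.0
        for edge_idx, ln in enumerate(lengths):
            acc += ln
            if r <= acc:
                break
        carriers = _descendant_taxa(edges[edge_idx][0], edges, leaf_of)
        ones = np.zeros(taxa.n, dtype=bool)
        for tx in carriers:
            ones[tx] = True
        missing = np.zeros(taxa.n, dtype=bool)
        if missing_rate > 0.0:
            missing = rng.random(taxa.n) < missing_rate
        obs_ones = int((ones & ~missing).sum())
        obs_zeros = int((~ones & ~missing).sum())
        if obs_ones >= 2 and obs_zeros >= 2:
            ones_rows.append(ones & ~missing)
            miss_rows.append(missing)
    return CharacterMatrix(taxa, np.array(ones_rows), np.array(miss_rows))


def perfect_characters(tree: RootedTree) -> CharacterMatrix:
    """Homoplasy-free fixture: one character per non-trivial proper clade.

    The source tree scores zero losses on this matrix; it is (one of) the
    global optima.
    """
    taxa = tree.taxa
    full = tree.leaf_mask()
    clades = sorted(
        c for c in tree.clades() if c.bit_count() > 1 and c != full
    )
    ones = np.zeros((len(clades), taxa.n), dtype=bool)
    for i, c in enumerate(clades):
        for j in range(taxa.n):
            if c >> j & 1:
                ones[i, j] = True
    return CharacterMatrix(taxa, ones, np.zeros_like(ones))


# ---------------------------------------------------------------------- #
# model species trees for simulation studies


def yule_species_tree(
    n: int,
    seed: int = 0,
    height: float = 5.0,
    labels: Optional[List[str]] = None,
) -> RootedTree:
    """Clock-like pure-birth species tree scaled to a fixed root height.

    Splitting times are drawn under the Yule process (each extant lineage
    splits at unit rate) and then the whole tree is rescaled so the root
    sits ``height`` coalescent units above the tips.  The default height of
    5 coalescent units corresponds to a tree spanning two million
    generations with an effective population size of 200,000 (coalescent
    units = generations / (2 Ne)), a regime with a moderate level of
    incomplete lineage sorting concentrated on the short internal branches.
    """
    if n < 2:
        raise ValueError("need at least two species")
    if height <= 0:
        raise ValueError("height must be positive")
    if labels is None:
        labels = [f"t{i + 1}" for i in range(n)]
    taxa = TaxonSet(labels)
    rng = np.random.default_rng(seed)
    # grow forward in time, tracking pendant branch start times
    t = 0.0
    root = Node()
    a, b = Node(), Node()
    root.add_child(a)
    root.add_child(b)
    tips: List[Tuple[Node, float]] = [(a, 0.0), (b, 0.0)]
    while len(tips) < n:
        t += rng.exponential(1.0 / len(tips))
        idx = int(rng.integers(0, len(tips)))
        node, born = tips.pop(idx)
        node.length = t - born
        c1, c2 = Node(), Node()
        node.add_child(c1)
        node.add_child(c2)
        tips.append((c1, t))
        tips.append((c2, t))
    t += rng.exponential(1.0 / len(tips))  # final era sets the tip age
    order = rng.permutation(n)
    for (node, born), tx in zip(tips, order):
        node.length = t - born
        node.taxon = int(tx)
    scale = height / t
    tree = RootedTree(root, taxa)
    for v in tree.postorder():
        if v.length is not None:
            v.length *= scale
    return tree.canonicalize()
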