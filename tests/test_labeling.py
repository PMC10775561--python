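"""The labeling kernel: local state rules, transition counts, fixed-tree scores.

Independent oracles used here:

* an LCA-path labeler for Dollo (propagate 1 along paths from the LCA of
  the 1-leaves to each 1-leaf, 0 elsewhere);
* a maximal all-ones-subtree counter for Camin-Sokal.

Both work directly on the tree and never consult the local-condition code
they check.
"""

import numpy as np
import pytest

from dollodp import (
    CharacterMatrix,
    StateVector,
    TaxonSet,
    count_transitions,
    gains_constant,
    get_state_camsok,
    get_state_dollo,
    random_rooted_tree,
    score_fixed_tree,
)
from conftest import random_matrix


# --------------------------------------------------------------------- #
# oracles


def lca_path_dollo_labeling(tree, ones_mask):
    """Per-vertex 0/1 labels via the path rule (no missing values)."""
    cm = tree.clade_map()
    if ones_mask == 0:
        return {v: 0 for v in cm}
    # LCA of the 1-leaves: the smallest clade containing all of them
    ancestors = [v for v, c in cm.items() if ones_mask & ~c == 0]
    lca = min(ancestors, key=lambda v: bin(cm[v]).count("1"))
    labels = {v: 0 for v in cm}

    def mark_paths(v, inside_lca):
        inside_lca = inside_lca or (v is lca)
        has_one = bool(cm[v] & ones_mask)
        if inside_lca and has_one:
            labels[v] = 1
        for ch in v.children:
            mark_paths(ch, inside_lca)

    mark_paths(tree.root, False)
    return labels


def count_maximal_all_ones_subtrees(tree, ones_mask):
    """Camin-Sokal oracle: maximal subtrees whose leaves are all 1."""
    cm = tree.clade_map()

    def all_ones(v):
        return cm[v] & ~ones_mask == 0

    count = 0
    for v in cm:
        if all_ones(v) and (v.parent is None or not all_ones(v.parent)):
            count += 1
    return count


def dollo_losses_direct(tree, labels):
    """Count 1->0 edges given a vertex labeling (oracle-side)."""
    total = 0
    for v in tree.postorder():
        for ch in v.children:
            if labels[v] == 1 and labels[ch] == 0:
                total += 1
    return total


# --------------------------------------------------------------------- #
# local-state rules


class TestGetState:
    def test_state_one_from_outside_evidence(self):
        # X={A}, Y={B}: a 1 in Y and a 1 outside X u Y force state 1
        taxa = TaxonSet(["A", "B", "C", "D"])
        m = CharacterMatrix.from_rows(taxa, ["0", "1", "1", "0"])
        st = get_state_dollo(taxa.mask(["A"]), taxa.mask(["B"]), m)
        assert str(st) == "1"

    def test_all_zero_character_gives_zero(self, abcd):
        m = CharacterMatrix.from_rows(abcd, ["0", "0", "0", "0"])
        st = get_state_dollo(1, 2, m)
        assert str(st) == "0"

    def test_single_one_gives_zero(self, abcd):
        # ones={a} only: no second 1 anywhere, so every internal vertex is 0
        m = CharacterMatrix.from_rows(abcd, ["1", "0", "0", "0"])
        assert str(get_state_dollo(1, 2, m)) == "0"
        assert str(get_state_dollo(3, 4, m)) == "0"

    def test_condition_zero_missing(self, abcd):
        m = CharacterMatrix.from_rows(abcd, ["?", "?", "1", "1"])
        assert str(get_state_dollo(1, 2, m)) == "?"

    def test_overlapping_sides_error(self, abcd):
        m = CharacterMatrix.from_rows(abcd, ["0", "0", "0", "0"])
        with pytest.raises(ValueError):
            get_state_dollo(3, 1, m)

    def test_camsok_zero_dominates(self, abcd):
        m = CharacterMatrix.from_rows(abcd, ["0", "1", "1", "1"])
        assert str(get_state_camsok(3, m)) == "0"  # A={a,b} contains a 0
        assert str(get_state_camsok(12, m)) == "1"  # A={c,d} all ones

    def test_camsok_all_missing(self, abcd):
        m = CharacterMatrix.from_rows(abcd, ["?", "?", "0", "1"])
        assert str(get_state_camsok(3, m)) == "?"


class TestCountTransitions:
    def test_hand_counts(self):
        p = StateVector.from_string("110")
        l = StateVector.from_string("010")
        r = StateVector.from_string("10?")
        assert count_transitions(p, l, r, "loss") == 2
        assert count_transitions(p, p, p, "loss") == 0
        assert count_transitions(p, p, p, "gain") == 0

    def test_missing_edges_do_not_count(self):
        p = StateVector.from_string("?1")
        l = StateVector.from_string("0?")
        r = StateVector.from_string("00")
        assert count_transitions(p, l, r, "loss") == 1

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            count_transitions(
                StateVector.from_string("0"),
                StateVector.from_string("01"),
                StateVector.from_string("01"),
            )


# --------------------------------------------------------------------- #
# fixed-tree scoring


class TestScoreFixedTree:
    def test_quartet_example(self, abcd, quartet_tree):
        # ((a,b),(c,d)), ones={a,c}: root and both cherry vertices are 1,
        # so losses fall above b and d
        m = CharacterMatrix.from_rows(abcd, ["1", "0", "1", "0"])
        assert score_fixed_tree(quartet_tree, m)[0] == 2
        assert score_fixed_tree(quartet_tree, m, criterion="camsok")[0] == 2

    def test_constant_one_character(self, abcd, quartet_tree):
        m = CharacterMatrix.from_rows(abcd, ["1", "1", "1", "1"])
        assert score_fixed_tree(quartet_tree, m)[0] == 0

    def test_clade_character_zero_losses(self):
        rng = np.random.default_rng(5)
        taxa = TaxonSet([f"x{i}" for i in range(8)])
        tree = random_rooted_tree(taxa, rng)
        from dollodp import perfect_characters

        assert score_fixed_tree(tree, perfect_characters(tree))[0] == 0

    def test_labels_match_local_rule(self):
        # postorder one-count labeling == conditions evaluated per bipartition
        rng = np.random.default_rng(6)
        taxa = TaxonSet([f"x{i}" for i in range(7)])
        for _ in range(10):
            tree = random_rooted_tree(taxa, rng)
            m = random_matrix(taxa, 15, rng, missing_rate=0.2)
            _, labels = score_fixed_tree(tree, m, return_labels=True)
            cm = tree.clade_map()
            for v in cm:
                if v.is_leaf:
                    continue
                x, y = cm[v.children[0]], cm[v.children[1]]
                assert labels[v] == get_state_dollo(x, y, m)

    def test_dollo_labeling_equals_lca_path_oracle(self):
        rng = np.random.default_rng(7)
        for rep in range(100):
            n = int(rng.integers(4, 11))
            taxa = TaxonSet([f"x{i}" for i in range(n)])
            tree = random_rooted_tree(taxa, rng)
            m = random_matrix(taxa, 1, rng)
            ones_mask = m.char_triple(0)[0]
            _, labels = score_fixed_tree(tree, m, return_labels=True)
            oracle = lca_path_dollo_labeling(tree, ones_mask)
            got = {v: int(str(labels[v])) for v in oracle}
            assert got == oracle
            assert score_fixed_tree(tree, m)[0] == dollo_losses_direct(tree, oracle)

    def test_restriction_identity(self):
        # score is invariant under restricting away the missing taxa
        rng = np.random.default_rng(8)
        for rep in range(40):
            n = int(rng.integers(5, 11))
            taxa = TaxonSet([f"x{i}" for i in range(n)])
            tree = random_rooted_tree(taxa, rng)
            m = random_matrix(taxa, 1, rng, missing_rate=0.35)
            r = taxa.full_mask & ~m.char_triple(0)[2]
            if bin(r).count("1") < 2:
                continue
            full_score = score_fixed_tree(tree, m)[0]
            assert full_score == score_fixed_tree(tree.restrict(r), m)[0]

    def test_camsok_equals_maximal_subtree_count(self):
        rng = np.random.default_rng(9)
        for rep in range(40):
            n = int(rng.integers(4, 10))
            taxa = TaxonSet([f"x{i}" for i in range(n)])
            tree = random_rooted_tree(taxa, rng)
            m = random_matrix(taxa, 1, rng)
            ones_mask = m.char_triple(0)[0]
            want = count_maximal_all_ones_subtrees(tree, ones_mask)
            # edge gains miss the gain at the root when the root itself is 1
            root_all_ones = ones_mask == taxa.full_mask
            got = score_fixed_tree(tree, m, criterion="camsok")[0]
            assert got == want - (1 if root_all_ones else 0)

    def test_worked_example_scores(self, worked_example):
        tree, matrix, r_mask = worked_example
        assert score_fixed_tree(tree, matrix)[0] == 1
        assert score_fixed_tree(tree, matrix, count_gains=True)[0] == 2
        restricted = tree.restrict(r_mask)
        assert score_fixed_tree(restricted, matrix)[0] == 1


class TestGainsConstant:
    def test_counts_characters_with_observed_ones(self, abcd):
        m = CharacterMatrix.from_rows(abcd, ["10?", "00?", "10?", "01?"])
        # chars: {a,c}, {d}, all-? -> two have a non-missing 1... third is all-?
        assert gains_constant(m) == 2

    def test_informative_implies_counted(self):
        rng = np.random.default_rng(10)
        taxa = TaxonSet([f"x{i}" for i in range(6)])
        m = random_matrix(taxa, 40, rng)
        informative = m.select(list(np.where(m.informative_flags())[0]))
        assert gains_constant(informative) == informative.k


# --------------------------------------------------------------------- #
# algebraic properties of transition counting (hypothesis)

from hypothesis import given, settings, strategies as st


def _sv(ones: int, k: int) -> StateVector:
    return StateVector(ones & ((1 << k) - 1), 0, k)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.integers(0, 2**12 - 1), st.integers(0, 2**12 - 1), st.integers(0, 2**12 - 1))
def test_losses_plus_gains_equal_hamming_distance(p, l, r):
    """Without missing states every differing edge is a loss or a gain."""
    k = 12
    pv, lv, rv = _sv(p, k), _sv(l, k), _sv(r, k)
    losses = count_transitions(pv, lv, rv, "loss")
    gains = count_transitions(pv, lv, rv, "gain")
    hamming = bin((p ^ l) & (2**k - 1)).count("1") + bin((p ^ r) & (2**k - 1)).count("1")
    assert losses + gains == hamming


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.text(alphabet="01?", min_size=0, max_size=40))
def test_state_vector_string_round_trip(s):
    assert str(StateVector.from_string(s)) == s
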