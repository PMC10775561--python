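"""Shared fixtures: small taxon sets, random instances, and the worked example."""

from __future__ import annotations

import numpy as np
import pytest

from dollodp import CharacterMatrix, TaxonSet
from dollodp.trees import Node, RootedTree


@pytest.fixture
def abcd() -> TaxonSet:
    return TaxonSet(list("abcd"))


@pytest.fixture
def quartet_tree(abcd) -> RootedTree:
    """((a,b),(c,d))"""
    return RootedTree(
        Node(
            children=[
                Node(children=[Node(taxon=0), Node(taxon=1)]),
                Node(children=[Node(taxon=2), Node(taxon=3)]),
            ]
        ),
        abcd,
    )


def random_matrix(
    taxa: TaxonSet, k: int, rng: np.random.Generator, missing_rate: float = 0.0,
    p_one: float = 0.4,
) -> CharacterMatrix:
    """Random i.i.d. character matrix (not coalescent-shaped; stress fixture)."""
    ones = rng.random((k, taxa.n)) < p_one
    miss = rng.random((k, taxa.n)) < missing_rate
    ones = ones & ~miss
    return CharacterMatrix(taxa, ones, miss)


@pytest.fixture
def make_random_matrix():
    return random_matrix


# --------------------------------------------------------------------- #
# A constructed missing-data worked example (synthetic reconstruction).
#
# Eleven taxa; six of them ambiguous for the single character.  Restricting
# to the unambiguously-scored taxa R = {A, C, G, J, Out} gives the caterpillar
# (Out,(J,(G,(A,C)))) with ones {C, G}: the unique Dollo labeling places one
# gain (below the vertex splitting J from the rest) and exactly one loss on
# the edge leading to A.  The full tree must give the same count.

WORKED_LABELS = ["A", "B", "C", "D", "E", "F", "G", "H", "I", "J", "Out"]
WORKED_NEWICK = "(Out,((H,I),(J,((B,D),(G,(E,(A,(F,C))))))));"
WORKED_STATES = {
    "A": "0", "B": "?", "C": "1", "D": "?", "E": "?", "F": "?",
    "G": "1", "H": "?", "I": "?", "J": "0", "Out": "0",
}


@pytest.fixture
def worked_example(tmp_path):
    """(tree, matrix, restriction mask) for the ambiguous-states example."""
    import dollodp.io as dio

    taxa = TaxonSet(WORKED_LABELS)
    path = tmp_path / "worked.nwk"
    path.write_text(WORKED_NEWICK + "\n")
    (tree,), _ = dio.read_newick_trees(path, taxa)
    matrix = CharacterMatrix.from_rows(taxa, [WORKED_STATES[x] for x in WORKED_LABELS])
    r_mask = taxa.mask(["A", "C", "G", "J", "Out"])
    return tree, matrix, r_mask
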