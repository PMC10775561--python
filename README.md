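# dollodp

Exact clade-constrained **Dollo parsimony** (and Camin-Sokal parsimony) for
binary presence/absence characters, with a multispecies-coalescent
character simulator.

## What problem this solves

Low-homoplasy genomic markers — retroelement insertions such as SINEs and
LINEs are the canonical case — are scored as ordered binary characters:
`0` the insertion is absent (ancestral), `1` present (derived), `?` not
callable.  An insertion at an orthologous locus is gained essentially once;
apparent reversals arise through incomplete lineage sorting.  The natural
optimality criterion is **Dollo parsimony**: find a rooted binary tree `T`
on the taxon set `S` minimizing

    sum over characters c of  Dollo(T, c)

where `Dollo(T, c)` is the number of `1 -> 0` losses needed to explain `c`
on `T` with at most one `0 -> 1` gain.  The unconstrained problem is
NP-hard.  This package solves the *clade-constrained* variant exactly and
in polynomial time: given a clade set `Sigma` (built from candidate trees,
from the characters themselves, or from an imported cluster file), it
returns a tree with `Clade(T) ⊆ Sigma` of provably minimum score within
that space, by dynamic programming over `(clade, root-state)` subproblems.
The key structural fact is that the optimal ancestral state of a vertex is
determined by its subtree bipartition alone (for Camin-Sokal, by its clade
alone), so the per-character labeling decouples from the rest of the
topology.  See `docs/methods.md` for the model, algorithm and design
choices.

Intended users: phylogeneticists working with retroelement or similar
presence/absence matrices who want an optimality guarantee beyond
hill-climbing, and methods developers who need a correct, well-tested
small-scale reference for Dollo/Camin-Sokal scoring and search.

## Worked example

Simulate 200 informative characters within a 6-taxon species tree (branch
lengths in coalescent units), then search:

```bash
# write a clock-like model tree and simulate characters within it
python -c "import dollodp as d; print(d.yule_species_tree(6, seed=3).newick(lengths=True))" > species.nwk
dollodp simulate -t species.nwk -k 200 --seed 7 -o chars.phy
# characters      200
# taxa            6

# score the model tree itself
dollodp score -i chars.phy -t species.nwk
# tree 1  dollo   13

# search the space constrained by the model tree's clades
dollodp search -i chars.phy -t species.nwk --seed 1
# score   13
# sigma   11
# ((t4,t5),((t2,t3),(t1,t6)));

# widen the space with clades harvested from the characters' splits
dollodp search -i chars.phy -t species.nwk --char-trees --seed 1
# score   13
# sigma   17
# ((t2,t3),((t4,t5),(t1,t6)));
```

Reading the output: the 200 simulated characters need 13 losses on the
true tree — lineage-sorting discordance, since without it every character
would fit a clade exactly (score 0).  Constrained to the true tree's own
11 clades, the search returns that tree at the same score (a single-tree
space is a degenerate but useful sanity check).  Widening `Sigma` to 17
clades with the character-split harvest cannot increase the optimum — here
it confirms 13 is still the best score, and the returned topology is the
same tree up to child rotation.  Scores count losses only; add
`--count-gains` to include the one-gain-per-character constant that makes
totals comparable with tools that count both.

The same operations are available as a library (`dollodp.solve_sigma`,
`dollodp.score_fixed_tree`, `dollodp.simulate_characters`, ...), which is
the comfortable route for simulation studies.

## Scope

In scope: Dollo and Camin-Sokal criteria, rooted trees, missing data,
outgroup rooting, constraint construction from trees / characters / clade
files, exact DP within `Sigma`, exhaustive search at small n, coalescent
simulation of presence/absence characters.  Out of scope: Fitch
(unordered) parsimony — its vertex states are not locally determined, so
the approach does not extend; heuristic tree search (TBR/NNI); consensus
of all optimal trees; bootstrap support.
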