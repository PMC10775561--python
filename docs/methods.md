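# Methods

## Problem

Given a set `S` of `n` taxa and `k` ordered binary characters (states `0` =
ancestral/absent, `1` = derived/present, `?` = missing or ambiguous), the
*large Dollo parsimony* problem asks for a rooted binary tree on `S`
minimizing the total number of `1 -> 0` losses when each character is
allowed at most one `0 -> 1` gain.  The problem is NP-hard in general; this
package solves the *clade-constrained* variant exactly: the search space is
restricted to trees whose every clade belongs to a supplied clade set
`Sigma`.  The same machinery handles Camin-Sokal parsimony (losses
prohibited, gains counted).  The intended data are low-homoplasy
presence/absence markers such as retroelement insertions, where a gain at
an orthologous locus happens essentially once and apparent reversals are
produced by incomplete lineage sorting (ILS) rather than by excision.

## Local labeling theory

The algorithm rests on a locality property of the optimal ancestral
labeling.  For a character without missing values, the unique minimum-loss
labeling assigns 1 to exactly the vertices on paths from the LCA of the
1-leaves to the 1-leaves.  Equivalently, for an internal vertex inducing
subtree bipartition `X|Y` (with `Z` the remaining taxa), the state is 1 iff
1-states occur in at least two of `X`, `Y`, `Z` — a rule that depends only
on `X|Y`, not on the rest of the topology.  With missing data we use the
canonical extension: the state is `?` iff every taxon of `X u Y` is
missing, else the two-of-three rule is applied to the non-missing entries;
transitions on edges with a `?` endpoint are not counted.  This canonical
labeling attains the optimum, which equals the Dollo score of the tree and
character restricted to the non-missing taxa (the *restriction identity*,
verified as a property test).  For Camin-Sokal the state depends only on
the clade `A`: `?` if `A` is all-missing, else 0 iff `A` contains a
non-missing 0, else 1.

Because the optimal vertex state is a function of the subtree bipartition
(clade) alone, characters decouple from topology and the constrained
optimum decomposes over clades.

## Dynamic program

From `Sigma` we precompute, for each clade `A`, its allowed subtree
bipartitions `STB(A) = {X|Y : X, Y, X u Y = A in Sigma}` (a hashed pair
scan over `Sigma x Sigma` with bit-mask clades), the induced state vectors
`Lab(A)`, and the bipartitions grouped by induced state.  The table entry
`best[A, st]` is the minimum transition count of any binary tree on `A`
drawing all clades from `Sigma` whose canonical labeling gives `st` at the
root; singletons cost 0 and larger clades minimize over `X|Y` inducing
`st` and over the children's allowed states, adding the transitions on the
two new edges.  Clades are processed in order of cardinality; the optimum
is `min over st of best[S, st]` and a tree is rebuilt by backtracking.
State vectors are stored as pairs of k-bit integers (ones mask, missing
mask), so hashing is cheap and transition counting is two popcounts.

Scores count losses only (gains under Camin-Sokal): each character with at
least one observed 1 needs exactly one gain, on the tree or implied above
the root, so the gain total is a per-matrix additive constant that cannot
change the argmin.  The fixed-tree scorer exposes a `count_gains` flag that
adds this constant for comparability with tools that report gains.

Ties are broken deterministically (smaller canonical bipartition mask,
then smaller child state vectors, root state with the smallest sort key),
so repeated runs return byte-identical trees.  This pins one tree out of a
potentially large optimal set; enumerating or consensus-summarizing all
optima is out of scope.

`Sigma` is *solvable* if some binary tree on `S` draws all clades from it,
decided bottom-up (a clade is buildable if it is a singleton or splits
into two buildable clades).  Builders guarantee solvability: clade sets
harvested from rooted input trees always contain a witness tree, and the
character-split builder unions in the clades of a greedy seed tree.  If an
imported clade set is unsolvable, the same seed-tree repair is applied and
reported.

## Fixed-tree scoring

Scoring a given tree does not need the quadratic bipartition machinery:
a single postorder pass per matrix accumulates, per character, the number
of 1-leaves and non-missing leaves below each vertex, from which the local
rule follows algebraically (ones in both child subtrees, or ones both
inside and outside the clade).  The equivalence of this linear-time path
and the per-bipartition rule is itself a test.  Trees on a leaf subset are
scored in their own leaf universe (taxa absent from the tree are ignored),
which makes the restriction identity hold exactly.

## Constraint sources

* **Input trees** (`sigma_from_trees`): trees are rooted at the designated
  outgroup (the outgroup must be displayable as one side of an edge;
  non-monophyletic outgroups are an error, not a silent fallback).  Clades
  lying entirely within the outgroup or entirely within the ingroup are
  kept; anything straddling the boundary (possible when a tree lacks part
  of the outgroup) is dropped.  Singletons and `S` are always included.
* **Characters as splits** (`characters_to_splits_trees`,
  `sigma_from_characters`): each parsimony-informative character encodes an
  unrooted tree with one internal edge separating its 1-taxa from its
  0-taxa (missing taxa omitted).  The built-in constraint harvest promotes
  both sides of each split (restricted to the ingroup) to clades and adds
  one greedy seed tree for solvability.  Feeding the split trees to an
  external clustering tool and importing its clusters via a clade file is
  the supported alternative; no external program is bundled or invoked.
* **Clade files** (`import_clades`): one clade per line, comma or
  whitespace separated.
* **Seed trees** (`seed_tree`): deterministic greedy stepwise addition
  under the Dollo score, taxa shuffled by seed, outgroup subtree grown
  separately and placed at the root.  On character sets compatible with a
  single tree the greedy tree attains score 0 (tested).

## Simulator

`simulate_characters` emulates retroelement presence/absence evolving under
the infinite-sites + neutral Wright-Fisher model: per character, one gene
genealogy is drawn under the multispecies coalescent within the species
tree (one haploid lineage sampled per species — the minimal choice giving
one presence/absence call per species); one mutation lands on a genealogy
branch chosen proportionally to branch length (no stem above the genealogy
root); descendant species get 1.  Cells are then masked to `?`
independently at `missing_rate`, and the character is kept only if
parsimony-informative (at least two 0s and two 1s among non-missing
states).  Species-tree branch lengths are in coalescent units
(generations / 2Ne).  The default model-tree generator draws clock-like
Yule topologies rescaled to a root height of 5 coalescent units,
corresponding to a tree spanning two million generations at an effective
population size of 200,000 — short internal branches near the tips then
carry substantial ILS.

What the simulator does *not* emulate: multiple lineages per species,
ascertainment other than the informativeness filter, correlated missing
data (masking is i.i.d. per cell), insertion hotspots or precise excision
(no homoplasy beyond lineage sorting), and non-ultrametric population
histories (branch lengths are treated as per-branch durations; genealogy
node times assume a clock).  Passing tests therefore show correctness of
the optimizer and the expected behavior of Dollo parsimony under clean
ILS-only data, not robustness to the messier error processes of real
retroelement calls.

## Problem sizes and numerical choices

The test and acceptance runs use desk-scale instances chosen to exercise
every code path while keeping the suite fast: exhaustive-search
cross-checks at n = 5-6 (105 and 945 rooted topologies) with k = 20,
labeling-theory property tests at n <= 10, constraint properties on
Sigma built from up to 100 random 10-taxon trees, and simulation studies
at n = 8-10 with k up to 1000 and 25 replicates.  Brute-force enumeration
refuses n > 9 and the all-subsets oracle mode refuses n > 12; these
guards are hard errors, not configuration.

Degenerate inputs: characters that are all-`?` over a tree's leaves
contribute 0 to every score and are excluded from the gains constant;
all-zero characters are labeled 0 everywhere; zero-length species-tree
branches are valid (star coalescent within the branch); a 0-character
matrix is legal and every tree scores 0.

## Known limitations

* One tree per run: the optimal set is not enumerated and no consensus is
  offered.
* The DP explores `Sigma` as given; its quality entirely determines the
  quality of the constrained optimum.  The guarantee relative to input
  trees is: never worse than any input tree *as rooted at the outgroup*
  (rooting changes Dollo scores, so unrooted comparisons are not
  meaningful).
* Statistical accuracy is bounded by the criterion itself: with strong ILS
  and finite characters the minimum-loss tree can differ from the true
  species tree, in which case an exact solver must return the
  better-scoring wrong tree.  On 10-taxon trees 5 coalescent units tall
  with 1000 characters the true topology is recovered in roughly
  two-thirds to three-quarters of replicates; the misses are strictly
  better-scoring alternatives, not optimizer failures.
* Fitch (unordered) parsimony is intentionally unsupported: its optimal
  vertex states are not determined by the local bipartition, so the
  decomposition used here does not apply.
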