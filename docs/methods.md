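# Methods

## Model and definitions

A split system S on a taxa set X (|X| = n ≥ 2) is any set of bipartitions
A|B of X into non-empty parts. The size of A|B is min(|A|, |B|); size-1
splits are trivial. Two splits A|B, C|D are compatible when at least one
of A∩C, A∩D, B∩C, B∩D is empty; a pairwise compatible system containing
all trivial splits is exactly the split system of one phylogenetic tree
(unique up to isomorphism), which is the bridge between trees and splits
used everywhere below.

Every split is stored canonically by the part not containing taxon 1
(`Split.side`), which makes a bipartition and its mirror image a single
hashable value and gives all algorithms a deterministic total order on
splits: by size, then lexicographically by small side, then by canonical
side.

## κ as graph colouring

κ(S), the minimal number of trees displaying every split of S, equals the
minimum number of pairwise compatible classes partitioning the nontrivial
splits of S: any cover by trees induces such a partition (assign each
split to one tree displaying it), and conversely each class plus the
trivial splits is one tree. That minimum is the chromatic number of the
*incompatibility graph* (vertices: nontrivial splits; edges: incompatible
pairs). Trivial splits are displayed by every tree, so they never affect
κ; a non-empty all-trivial system has κ = 1 (the star tree), and the
empty system has κ = 0, in which case the solution carries no trees.

The solver computes, in order:

1. **Clique bound** — the k-compatibility level, via an exact
   branch-and-bound maximum clique (networkx `max_weight_clique`).
2. **Capacity bound** — counting arguments on what one tree can display:
   at most one split of size m = n/2 for even n, at most two of size
   m = (n−1)/2 for odd n ≥ 5, and at most n−3 nontrivial splits overall.
   With c central-size splits present, κ ≥ max(c or ⌈c/2⌉,
   ⌈|nontrivial|/(n−3)⌉). Both central-capacity facts are also colouring
   facts (a pairwise compatible class obeys the same caps), so the bound
   is sound for the chromatic number; it can exceed the clique bound —
   the worked five-split example has clique 2 but capacity (and κ) 3.
3. **Greedy upper bound** — largest-degree-first colouring.
4. **Exact search** — if the bounds disagree, a DSATUR-ordered
   backtracking k-colouring search runs for k = lb, lb+1, … until a
   colouring is found (then κ = k, certified) or the budget is exhausted
   (then the greedy partition is returned with `optimal=False` and the
   honest interval). Branching always colours the uncoloured vertex with
   the most distinct neighbouring colours (ties: higher degree, then
   lower index), and at each vertex only one previously unused colour is
   tried, which removes colour-permutation symmetry. Vertex order is the
   canonical split order, so results are bit-for-bit reproducible.

The default budget is unlimited for systems with ≤ 25 nontrivial splits;
larger systems get a 5·10⁶-node cap (and optionally a wall-clock budget,
exposed as `--budget` seconds on the CLI) with a bounds-only degraded
result rather than an error. Split weights parsed from NEXUS files are
retained but deliberately ignored: incompatibility is a property of the
bipartitions alone.

Norm(S) = κ(S)/U(n) is returned as an exact `fractions.Fraction` and is
refused when κ is not certified optimal; `norm_value(kappa, n)` computes
the same fraction from an externally known κ.

## U(n) and the constructive witness

U(n) = ⌈C(n, ⌊n/2⌋)/2⌉ for n ≥ 4; U(2) = 1 trivially, and U(3) = 1
because all splits on 3 taxa are trivial and the star tree displays them
all (the closed form would give 2 there, so n = 3 is special-cased and
documented as such).

`build_universal_tree_set` realizes the bound constructively:

1. **Symmetric chain decomposition.** The non-empty subsets of size ≤ m
   are partitioned into C(n, m) inclusion chains, one size-m set per
   chain, by the de Bruijn–Tengbergen–Kruyswijk bracket-matching rule
   over the taxa in index order: reading a subset's characteristic
   string with members as opening and non-members as closing brackets,
   the matched pairs are frozen and a chain steps down by removing the
   leftmost unmatched member. Chains are generated from their size-m
   tops in lexicographic order, so the decomposition is deterministic.
   (The existence argument via Sperner/Dilworth is non-constructive; the
   bracket rule is the standard explicit witness.)
2. **Gluing.** Mapping a subset A to the split A|(X∖A) sends each chain
   to a nested, hence pairwise compatible, split family. For even n the
   map identifies complementary size-m sets, gluing chains in
   complementary pairs: C(n,m)/2 components. For odd n the size-m splits
   form a compatibility graph — two distinct equal-size splits are
   compatible iff their small sides are disjoint, so this is the
   (m+1)-regular Kneser-type graph — and a maximum matching glues chains
   in pairs, leaving one singleton component exactly when C(n, m) is
   odd, i.e. when n = 2^k − 1 (Kummer's theorem in base 2, exposed as
   `carries` and `central_binomial_is_odd`).
3. **Trees.** Each component's splits are pairwise compatible (nested or
   separated by the central splits' disjointness) and become one tree via
   `tree_from_splits`. The count ⌈C(n,m)/2⌉ meets the capacity lower
   bound, so minimality needs no search; the builder asserts both the
   count and the per-tree central-split caps and raises on any violation.

The matcher is a blossom-contraction augmenting-path implementation with
a greedy initial matching. networkx's general matcher is an O(V³)
pure-Python weighted algorithm that does not scale to the C(13,6) = 1716
or C(15,7) = 6435 vertex graphs exercised here, and no other installed
library offers general-graph maximum cardinality matching; the
implementation is cross-checked against networkx on small random graphs
in the test suite. On the 6435-vertex graph the matcher certifies the
defect-1 matching in a few seconds.

`tree_from_splits` builds the unique tree by viewing canonical sides as
clusters relative to taxon 1: pairwise compatibility makes them a laminar
family, each cluster becomes an interior vertex attached to the smallest
cluster strictly containing it, singletons are leaves, and taxon 1 hangs
off the root cluster X∖{1}. No refinement beyond the input splits is
introduced, so `splits_of_tree ∘ tree_from_splits` is the identity on
(system ∪ trivial). n = 2 yields the single-edge tree, accepted although
both labelled vertices have degree 1.

## Synthetic data

`generate_split_system(n, n_trees, extra_incompatible, seed)` emulates
conflicting phylogenetic signal at a controlled level of incompatibility:
the union of the nontrivial splits of `n_trees` random binary trees
(κ ≤ n_trees by construction) plus up to `extra_incompatible` splits
drawn uniformly from the remaining split space. Trees grow by seeded
sequential leaf attachment — every topology is reachable, but the
distribution is not uniform over topologies, and the extra splits carry
no weights or phylogenetic correlation structure. Passing tests therefore
demonstrate correctness of the combinatorial machinery on reproducible
inputs spanning compatible through highly incompatible regimes, not
distributional claims about real alignments or Neighbor-Net output. All
randomness flows from a single `random.Random(seed)`, so identical
arguments give byte-identical serialized output.

## Problem sizes and numerical choices

Everything here is exact integer/fraction arithmetic; there are no
tolerances. The test suite exercises the construction exhaustively for
n = 2..12 (462 trees covering all 2047 splits at n = 12), matching
defects for n ∈ {5, 7, 9, 11, 13, 15}, the carries/valuation identity on
the full grid a, b ≤ 64 for p ∈ {2, 3, 5}, and the exact solver against
a brute-force partition oracle on 200 seeded systems with ≤ 8 nontrivial
splits — sizes chosen so the whole suite runs in seconds while still
covering both parity classes, the defect-1 cases and all special cases
(n = 2, 3, empty and all-trivial systems).

## Known limitations

- κ is exact but worst-case exponential; beyond the node cap the solver
  degrades to honest bounds rather than running forever. Systems from
  networks on a few dozen taxa with many high-conflict splits may land
  there.
- Only splits are modelled: no split weights in any computation, no
  circular/affine system classes, no network drawing, and no consensus
  thresholding.
- The NEXUS reader targets the SplitsTree4 `st_splits` dialect (bracket
  comments, optional FORMAT flags, CYCLE, trailing commas, `end;`/
  `endblock;`, quoted labels). Exotic NEXUS extensions are ignored, not
  round-tripped.
- Universal tree sets are highly non-unique; the builder returns one
  deterministic representative (unrefined component trees, which need
  not be binary).
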