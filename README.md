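# splitcover

Quantifying the incompatibility of phylogenetic split systems by the
number of trees needed to display them.

Conflicting signal — measurement error, incomplete lineage sorting,
lateral gene transfer — produces sets of splits (bipartitions of the taxa)
that no single tree can display. Tools like SplitsTree represent such data
as split networks, which carry exactly the information of a weighted split
list. `splitcover` answers: **how many trees would it take?** It computes

- **κ(S)**, the *minimal tree set size*: the least number of phylogenetic
  trees whose displayed splits cover every split of a system S. Since a
  set of splits fits on one tree exactly when it is pairwise compatible
  under the Buneman four-intersection condition (splits equivalence
  theorem), κ(S) is the minimum number of pairwise-compatible classes
  partitioning the nontrivial splits of S — the chromatic number of S's
  incompatibility graph. The solver is exact, with clique and counting
  lower bounds and a branch-and-bound colouring search.
- **k-compatibility**: the size of the largest pairwise-incompatible
  subset of S (a maximum clique of the same graph). This lower-bounds κ
  but can be strictly smaller: the five-split system
  {12|345, 23|145, 34|125, 45|123, 15|234} is 2-compatible yet needs
  3 trees.
- **U(n)**, the *universal incompatibility*: the worst case κ over all
  systems on n taxa, attained by the full split space 𝒮(X). With
  m = ⌊n/2⌋,

      U(n) = ⌈ C(n, m) / 2 ⌉        (n ≥ 4;  U(2) = U(3) = 1)

  and `splitcover` also *constructs* a minimal universal tree set
  witnessing the bound, via a symmetric chain decomposition of the subset
  lattice and, for odd n, a maximum matching on the compatibility graph of
  the ⌊n/2⌋-size splits (defect 1 exactly when n = 2^k − 1, by Kummer's
  carry-counting theorem, else perfect).
- **Norm(S) = κ(S) / U(n)**, the normalized tree set size — an exact
  fraction that makes incompatibility comparable across different taxon
  counts, e.g. κ=4 on 13 taxa (4/858) is *less* incompatible relative to
  the worst case than κ=3 on 12 taxa (3/462).

## Worked example

The five-split system above, shipped as `tests/data/example21.nex`:

```sh
$ splitcover kcompat tests/data/example21.nex
2
$ splitcover kappa tests/data/example21.nex
kappa = 3 (exact)
$ splitcover norm tests/data/example21.nex
3/5
```

No two trees suffice (each tree on 5 leaves displays at most two of the
five size-2 splits), even though no three of the splits are mutually
incompatible — the gap between k-compatibility (2) and κ (3). The
normalized value 3/5 compares κ=3 against U(5)=5.

Universal tree sets:

```sh
$ splitcover usize 13
858
$ splitcover construct 5 -o u5.nwk
wrote 5 trees (U(5) = 5) to u5.nwk
$ splitcover verify-universal u5.nwk -n 5
universal: true, size 5 = U(5) = 5
```

The same from Python:

```python
from splitcover import (TaxaSet, SplitSystem, make_split, min_tree_set,
                        build_universal_tree_set)

taxa = TaxaSet.range(5)
S = SplitSystem(taxa, [make_split(side, taxa) for side in
                       [{"1","2"}, {"2","3"}, {"3","4"}, {"4","5"}, {"1","5"}]])
sol = min_tree_set(S)
sol.k, sol.clique_bound, sol.optimal   # (3, 2, True)
len(build_universal_tree_set(taxa))    # 5
```

Other commands: `splitcover gen` writes reproducible synthetic split
systems (NEXUS), and `splitcover kappa FILE --json -` emits a full machine
readable report (bounds, witness classes, witness trees as Newick). Input
formats: SplitsTree-style NEXUS (TAXA + SPLITS blocks), Newick tree files
(κ of the union of their splits), and plain split lists.

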