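"""Universal tree sets: U(n) and a minimal constructive witness.

U(n), the minimal number of trees displaying every split on n taxa, equals
``ceil(C(n, m) / 2)`` with ``m = floor(n/2)`` (n = 3 is the lone special
case: all splits on 3 taxa are trivial, so the star tree alone suffices).

The constructive route mirrors the bound's proof:

1. decompose the non-empty subsets of size <= m into C(n, m) symmetric
   inclusion chains (de Bruijn–Tengbergen–Kruyswijk bracket matching), one
   size-m subset per chain;
2. map subsets to splits via ``gamma(A) = A | X\\A``; for even n this glues
   complementary chains in pairs, for odd n chains are glued along a
   maximum matching of the compatibility graph of the size-m splits;
3. each glued component is a pairwise compatible split set, hence one tree.

Per-tree capacities (at most one size-m split on even n, at most two on
odd n) certify minimality without any search.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb
from typing import Dict, FrozenSet, Iterable, List, Sequence, Tuple

import networkx as nx

from .core import Split, SplitSystem, TaxaSet, are_compatible
from .matching import maximum_matching
from .trees import PhyloTree, TreeSet, tree_from_splits

__all__ = [
    "universal_size",
    "carries",
    "central_binomial_is_odd",
    "ChainDecomposition",
    "symmetric_chain_decomposition",
    "gamma",
    "CompatibilityGraph",
    "bip_compatibility_graph",
    "Matching",
    "max_matching",
    "intersection_stat",
    "build_universal_tree_set",
]


def universal_size(n: int) -> int:
    """Minimal size of a universal tree set on n taxa.

    ``ceil(C(n, floor(n/2)) / 2)`` for n >= 4; 1 for n in {2, 3}.
    """
    if n < 2:
        raise ValueError(f"need n >= 2 taxa, got {n}")
    if n <= 3:
        # n=3: every split is trivial, the star tree displays them all.
        return 1
    return (comb(n, n // 2) + 1) // 2


def _check_prime(p: int) -> None:
    if p < 2 or any(p % d == 0 for d in range(2, int(p**0.5) + 1)):
        raise ValueError(f"base must be prime, got {p}")


def carries(a: int, b: int, p: int) -> int:
    """Number of carries when adding a and b in base p.

    Digit-by-digit from the right: a carry occurs at position i when the
    digit sum plus the incoming carry reaches p. By Kummer's theorem this
    equals the exponent of p in C(a+b, a).
    """
    if a < 1 or b < 1:
        raise ValueError("a and b must be positive")
    _check_prime(p)
    total = 0
    phi = 0
    while a or b or phi:
        phi = 1 if a % p + b % p + phi >= p else 0
        total += phi
        a //= p
        b //= p
        if not a and not b and not phi:
            break
    return total


def central_binomial_is_odd(n: int) -> bool:
    """Whether C(n, m) is odd for odd n = 2m+1: true iff n = 2^i - 1."""
    if n < 3 or n % 2 == 0:
        raise ValueError(f"need odd n = 2m+1 with m >= 1, got {n}")
    return (n + 1) & n == 0


# ---------------------------------------------------------------------------
# Symmetric chain decomposition (bracket matching)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChainDecomposition:
    """Partition of the non-empty subsets of size <= m into inclusion chains.

    Each chain is ascending by size with consecutive sizes, contains
    exactly one size-m subset (its last member), and every non-empty
    subset of size <= m appears in exactly one chain; there are C(n, m)
    chains in total.
    """

    taxa: TaxaSet
    m: int
    chains: Tuple[Tuple[FrozenSet[int], ...], ...]

    def chain_of(self) -> Dict[FrozenSet[int], int]:
        """Map each member subset to its chain index."""
        out: Dict[FrozenSet[int], int] = {}
        for i, chain in enumerate(self.chains):
            for sub in chain:
                out[sub] = i
        return out

    def validate(self) -> None:
        n = self.taxa.n
        if len(self.chains) != comb(n, self.m):
            raise AssertionError("chain count != C(n, m)")
        seen: set[FrozenSet[int]] = set()
        for chain in self.chains:
            sizes = [len(s) for s in chain]
            if sizes != list(range(sizes[0], self.m + 1)):
                raise AssertionError("chain sizes not consecutive up to m")
            for lo, hi in zip(chain, chain[1:]):
                if not lo < hi:
                    raise AssertionError("chain not ordered by strict inclusion")
            if seen & set(chain):
                raise AssertionError("subset appears in two chains")
            seen |= set(chain)
        expect = sum(comb(n, k) for k in range(1, self.m + 1))
        if len(seen) != expect:
            raise AssertionError("decomposition does not cover all subsets")

    def to_index_lists(self) -> List[List[List[int]]]:
        """JSON-friendly dump: chains as lists of sorted index lists."""
        return [[sorted(s) for s in chain] for chain in self.chains]


def _unmatched_ones(subset: FrozenSet[int], n: int) -> List[int]:
    """Positions of unmatched members under bracket matching.

    Reading positions 1..n with members as '(' and non-members as ')',
    matching brackets leaves some non-members then some members unmatched;
    the unmatched member positions are returned in increasing order.
    """
    stack: List[int] = []
    for i in range(1, n + 1):
        if i in subset:
            stack.append(i)
        elif stack:
            stack.pop()
    return stack


def symmetric_chain_decomposition(taxa: TaxaSet) -> ChainDecomposition:
    """Deterministic symmetric chain decomposition, truncated to sizes 1..m.

    Each chain is generated from its unique size-m member by repeatedly
    removing the leftmost unmatched member, which preserves the bracket
    matching and walks one level down the chain.
    """
    n = taxa.n
    m = n // 2
    chains: List[Tuple[FrozenSet[int], ...]] = []
    for combo in itertools.combinations(range(1, n + 1), m):
        member = frozenset(combo)
        chain = [member]
        while len(chain[-1]) > 1:
            free = _unmatched_ones(chain[-1], n)
            if not free:
                break
            chain.append(chain[-1] - {free[0]})
        chain.reverse()
        chains.append(tuple(chain))
    return ChainDecomposition(taxa=taxa, m=m, chains=tuple(chains))


def gamma(subset: Iterable[int], taxa: TaxaSet) -> Split:
    """The split A | X\\A for a non-empty proper subset A (by index)."""
    return Split(taxa, subset)


# ---------------------------------------------------------------------------
# Compatibility graph of the size-m splits and its matchings
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CompatibilityGraph:
    """Compatibility graph of all size-m splits on a taxa set.

    Vertices are the splits of size exactly m; edges join compatible
    distinct splits. For two distinct splits of equal size m <= n/2 the
    Buneman condition reduces to disjointness of the size-m parts, so for
    even n = 2m the graph has no edges, and for odd n = 2m+1 it is the
    (m+1)-regular Kneser-type graph the matching lemmas are about.
    """

    taxa: TaxaSet
    m: int
    graph: nx.Graph


def bip_compatibility_graph(taxa: TaxaSet, m: int) -> CompatibilityGraph:
    n = taxa.n
    if not 1 <= m <= n // 2:
        raise ValueError(f"need 1 <= m <= n/2, got m={m}, n={n}")
    g = nx.Graph()
    by_small: Dict[FrozenSet[int], Split] = {}
    for combo in itertools.combinations(range(1, n + 1), m):
        s = Split(taxa, combo)
        by_small[frozenset(combo)] = s
        g.add_node(s)
    for small, s in by_small.items():
        rest = sorted(taxa.indices - small)
        for combo in itertools.combinations(rest, m):
            t = by_small[frozenset(combo)]
            if t != s:
                g.add_edge(s, t)
    return CompatibilityGraph(taxa=taxa, m=m, graph=g)


@dataclass(frozen=True)
class Matching:
    """A matching on a compatibility graph with its defect."""

    edges: Tuple[Tuple[Split, Split], ...]
    unmatched: Tuple[Split, ...]

    @property
    def defect(self) -> int:
        return len(self.unmatched)


def max_matching(cg: CompatibilityGraph) -> Matching:
    """Maximum cardinality matching of the size-m compatibility graph.

    For odd n = 2m+1 with m >= 2 the defect must be 1 when n = 2^k - 1 and
    0 otherwise; a larger defect signals a construction bug and raises.
    """
    vertices = sorted(cg.graph.nodes)
    edges = [tuple(sorted(e)) for e in cg.graph.edges]
    edges.sort()
    mate = maximum_matching(vertices, edges)
    pairs = sorted(
        (v, mate[v]) for v in vertices if v in mate and v < mate[v]
    )
    unmatched = tuple(v for v in vertices if v not in mate)
    result = Matching(edges=tuple(pairs), unmatched=unmatched)
    n = cg.taxa.n
    if n % 2 == 1 and cg.m == n // 2 and cg.m >= 2:
        expected = 1 if central_binomial_is_odd(n) else 0
        if result.defect != expected:
            raise RuntimeError(
                f"matching defect {result.defect} violates the expected "
                f"defect {expected} for n={n}"
            )
    return result


def intersection_stat(s1: Split, s2: Split) -> int:
    """Overlap of the two (m+1)-element parts of size-m splits, odd n.

    Equals m+1 exactly when the splits coincide; strictly positive for any
    pair, which drives the connectivity argument for the compatibility
    graph.
    """
    n = s1.taxa.n
    if s1.taxa != s2.taxa or n % 2 == 0:
        raise ValueError("both splits must be on one odd-sized taxa set")
    m = n // 2
    if s1.size != m or s2.size != m:
        raise ValueError(f"both splits must have size m={m}")
    return len(s1.big_side & s2.big_side)


# ---------------------------------------------------------------------------
# The constructive universal tree set
# ---------------------------------------------------------------------------


def build_universal_tree_set(taxa: TaxaSet) -> TreeSet:
    """A minimal universal tree set on ``taxa``.

    Returns exactly ``universal_size(n)`` trees whose displayed splits
    cover the full split space S(X). Deterministic for a fixed taxa order.
    """
    n = taxa.n
    if n <= 3:
        return TreeSet([PhyloTree.star(taxa)])
    m = n // 2
    scd = symmetric_chain_decomposition(taxa)
    chains = scd.chains

    groups: List[Tuple[int, ...]]
    if n % 2 == 0:
        idx_of_top = {chain[-1]: i for i, chain in enumerate(chains)}
        groups = []
        seen: set[int] = set()
        for i, chain in enumerate(chains):
            if i in seen:
                continue
            j = idx_of_top[taxa.indices - chain[-1]]
            seen.update((i, j))
            groups.append((i, j))
    else:
        cg = bip_compatibility_graph(taxa, m)
        matching = max_matching(cg)
        idx_of_top = {chain[-1]: i for i, chain in enumerate(chains)}
        groups = [
            (idx_of_top[a.small_side], idx_of_top[b.small_side])
            for a, b in matching.edges
        ]
        groups += [(idx_of_top[s.small_side],) for s in matching.unmatched]

    trees: List[PhyloTree] = []
    for group in groups:
        splits = {gamma(sub, taxa) for i in group for sub in chains[i]}
        system = SplitSystem(taxa, splits)
        central = [s for s in system.splits if s.size == m]
        cap = 1 if n % 2 == 0 else 2
        if len(central) > cap:
            raise RuntimeError(
                f"component carries {len(central)} size-{m} splits (cap {cap})"
            )
        trees.append(tree_from_splits(system))

    expected = universal_size(n)
    if len(trees) != expected:
        raise RuntimeError(
            f"constructed {len(trees)} trees but U({n}) = {expected}"
        )
    trees.sort(key=_tree_sort_key)
    return TreeSet(trees)


def _tree_sort_key(tree: PhyloTree) -> List[tuple]:
    from .trees import splits_of_tree

    return sorted(s._key() for s in splits_of_tree(tree).splits if not s.trivial)
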