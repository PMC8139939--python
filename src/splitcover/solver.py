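"""Exact incompatibility quantification for split systems.

The minimal tree set size kappa(S) — the least number of trees whose
displayed splits cover S — equals the minimum number of pairwise
compatible classes partitioning the nontrivial splits of S (any class
plus the trivial splits is one tree), which is the chromatic number of
the *incompatibility graph*: vertices the nontrivial splits, edges the
incompatible pairs. k-compatibility is the clique number of the same
graph.

The solver sandwiches kappa between a lower bound (max of the clique
number and per-tree capacity counts) and a greedy colouring upper bound,
then closes the gap with a DSATUR-ordered branch-and-bound colouring
search. Split weights never enter: incompatibility is weight-agnostic.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from fractions import Fraction
from math import ceil
from typing import Dict, List, Optional, Sequence, Tuple

import networkx as nx

from .core import Split, SplitSystem, are_compatible
from .trees import TreeSet, tree_from_splits
from .universal import universal_size

__all__ = [
    "IncompatibilityGraph",
    "Solution",
    "incompatibility_graph",
    "max_incompatible_subset_size",
    "capacity_lower_bound",
    "min_tree_set",
    "normalized_tree_set_size",
    "norm_value",
]

# Unlimited exact search up to this many nontrivial splits; beyond it a
# node cap keeps the search finite unless the caller lifts it.
_FREE_SEARCH_SPLITS = 25
_DEFAULT_NODE_CAP = 5_000_000


@dataclass(frozen=True)
class IncompatibilityGraph:
    """Incompatibility relation on the nontrivial splits of a system."""

    system: SplitSystem
    graph: nx.Graph  # nodes: Split, edges: incompatible pairs


def incompatibility_graph(system: SplitSystem) -> IncompatibilityGraph:
    g = nx.Graph()
    splits = [s for s in system.sorted_splits() if not s.trivial]
    g.add_nodes_from(splits)
    for i, a in enumerate(splits):
        for b in splits[i + 1 :]:
            if not are_compatible(a, b):
                g.add_edge(a, b)
    return IncompatibilityGraph(system=system, graph=g)


def max_incompatible_subset_size(system: SplitSystem) -> int:
    """Size of the largest pairwise incompatible subset (clique number).

    A system containing no k+1 pairwise incompatible splits is
    k-compatible; this returns that threshold k. Zero for empty or
    all-trivial systems.
    """
    ig = incompatibility_graph(system)
    if ig.graph.number_of_nodes() == 0:
        return 0
    clique, weight = nx.max_weight_clique(ig.graph, weight=None)
    return int(weight)


def capacity_lower_bound(system: SplitSystem) -> int:
    """Counting lower bound on kappa from per-tree display capacities.

    A tree on n taxa displays at most one split of size m = n/2 when n is
    even, at most two of size m = (n-1)/2 when n is odd, and at most n-3
    nontrivial splits overall.
    """
    n = system.taxa.n
    nontrivial = [s for s in system.splits if not s.trivial]
    if not nontrivial:
        return 0
    if n == 3:
        return 1
    m = n // 2
    c = sum(1 for s in nontrivial if s.size == m)
    central = c if n % 2 == 0 else ceil(c / 2)
    overall = ceil(len(nontrivial) / (n - 3))
    return max(central, overall)


@dataclass
class Solution:
    """Result of the minimal tree set computation."""

    system: SplitSystem
    k: int
    classes: Tuple[Tuple[Split, ...], ...]
    trees: Optional[TreeSet]
    lower_bound: int
    upper_bound: int
    optimal: bool
    clique_bound: int
    capacity_bound: int
    search_nodes: int = 0

    def norm(self) -> Fraction:
        """kappa / U(n); requires a certified-optimal kappa."""
        if not self.optimal:
            raise ValueError(
                f"kappa not certified optimal (bounds {self.lower_bound}.."
                f"{self.upper_bound}); cannot normalize"
            )
        return Fraction(self.k, universal_size(self.system.taxa.n))

    def to_dict(self) -> dict:
        d = {
            "n": self.system.taxa.n,
            "n_splits": len(self.system),
            "n_nontrivial": sum(1 for s in self.system.splits if not s.trivial),
            "k": self.k,
            "lower_bound": self.lower_bound,
            "upper_bound": self.upper_bound,
            "optimal": self.optimal,
            "clique_bound": self.clique_bound,
            "capacity_bound": self.capacity_bound,
            "u_of_n": universal_size(self.system.taxa.n),
            "classes": [[str(s) for s in cls] for cls in self.classes],
        }
        if self.optimal and self.k > 0:
            frac = self.norm()
            d["norm"] = f"{frac.numerator}/{frac.denominator}"
        else:
            d["norm"] = None
        if self.trees is not None:
            from .io import newick_string

            d["trees"] = [newick_string(t) for t in self.trees]
        else:
            d["trees"] = []
        return d


class _SearchBudget:
    """Wall-clock and node budget shared across the colouring search."""

    def __init__(self, seconds: Optional[float], node_cap: Optional[int]):
        self.deadline = None if seconds is None else time.monotonic() + seconds
        self.node_cap = node_cap
        self.nodes = 0
        self.exhausted = False

    def tick(self) -> bool:
        self.nodes += 1
        if self.node_cap is not None and self.nodes > self.node_cap:
            self.exhausted = True
        elif self.deadline is not None and self.nodes % 1024 == 0:
            if time.monotonic() > self.deadline:
                self.exhausted = True
        return not self.exhausted


def _exact_k_coloring(
    neighbors: Sequence[Sequence[int]], k: int, budget: _SearchBudget
) -> Optional[List[int]]:
    """Branch-and-bound search for a proper k-colouring.

    DSATUR vertex selection (max saturation, then max degree, then index)
    with new-colour symmetry breaking. Returns a colour list, or None if
    no k-colouring exists or the budget ran out (check budget.exhausted).
    """
    nv = len(neighbors)
    colors: List[int] = [-1] * nv
    sat: List[set] = [set() for _ in range(nv)]
    degrees = [len(nb) for nb in neighbors]

    def pick() -> int:
        best, best_key = -1, None
        for v in range(nv):
            if colors[v] == -1:
                key = (len(sat[v]), degrees[v], -v)
                if best_key is None or key > best_key:
                    best, best_key = v, key
        return best

    def recurse(n_colored: int, used: int) -> bool:
        if n_colored == nv:
            return True
        if not budget.tick():
            return False
        v = pick()
        if len(sat[v]) >= k:
            return False
        limit = min(used + 1, k)  # first unused colour is interchangeable
        for c in range(limit):
            if c in sat[v]:
                continue
            colors[v] = c
            touched = []
            for u in neighbors[v]:
                if colors[u] == -1 and c not in sat[u]:
                    sat[u].add(c)
                    touched.append(u)
            if recurse(n_colored + 1, max(used, c + 1)):
                return True
            for u in touched:
                sat[u].discard(c)
            colors[v] = -1
            if budget.exhausted:
                return False
        return False

    return list(colors) if recurse(0, 0) else None


def min_tree_set(
    system: SplitSystem,
    budget_seconds: Optional[float] = None,
    node_cap: Optional[int] = None,
) -> Solution:
    """Exact minimal tree set size kappa(S) with a witness partition.

    Computes clique and capacity lower bounds, a greedy (largest-degree
    first) colouring upper bound, then runs the exact colouring search
    upward from the lower bound. If the budget is exhausted the best known
    partition is returned with ``optimal=False`` and honest bounds.

    Conventions: trivial splits are displayed by every tree and are
    excluded from the partition; an all-trivial non-empty system has
    kappa = 1, the empty system kappa = 0 (with no trees).
    """
    taxa = system.taxa
    ig = incompatibility_graph(system)
    splits = list(ig.graph.nodes)

    if not splits:
        k = 1 if len(system) else 0
        trees = (
            TreeSet([tree_from_splits(SplitSystem(taxa))]) if k else None
        )
        return Solution(
            system=system, k=k, classes=(), trees=trees,
            lower_bound=k, upper_bound=k, optimal=True,
            clique_bound=0, capacity_bound=0,
        )

    clique = max_incompatible_subset_size(system)
    capacity = capacity_lower_bound(system)
    lb = max(clique, capacity, 1)

    greedy = nx.greedy_color(ig.graph, strategy="largest_first")
    ub = max(greedy.values()) + 1
    best_colors: Dict[Split, int] = dict(greedy)

    if node_cap is None and len(splits) > _FREE_SEARCH_SPLITS:
        node_cap = _DEFAULT_NODE_CAP
    budget = _SearchBudget(budget_seconds, node_cap)

    index = {s: i for i, s in enumerate(splits)}
    neighbors = [
        sorted(index[u] for u in ig.graph.neighbors(s)) for s in splits
    ]

    optimal = lb == ub
    search_nodes = 0
    if not optimal:
        for k_try in range(lb, ub):
            coloring = _exact_k_coloring(neighbors, k_try, budget)
            search_nodes = budget.nodes
            if coloring is not None:
                best_colors = {s: coloring[index[s]] for s in splits}
                ub = k_try
                optimal = True
                break
            if budget.exhausted:
                break
            lb = k_try + 1  # proven: no k_try-colouring exists
        else:
            optimal = True  # greedy colouring already meets the final lb
        if lb == ub:
            optimal = True

    n_classes = max(best_colors.values()) + 1
    classes: List[List[Split]] = [[] for _ in range(n_classes)]
    for s in splits:
        classes[best_colors[s]].append(s)
    class_tuples = tuple(
        tuple(sorted(cls)) for cls in classes if cls
    )
    class_tuples = tuple(sorted(class_tuples))
    trees = TreeSet(
        [tree_from_splits(SplitSystem(taxa, cls)) for cls in class_tuples]
    )
    return Solution(
        system=system,
        k=len(class_tuples),
        classes=class_tuples,
        trees=trees,
        lower_bound=lb,
        upper_bound=ub,
        optimal=optimal,
        clique_bound=clique,
        capacity_bound=capacity,
        search_nodes=search_nodes,
    )


def normalized_tree_set_size(system: SplitSystem, **kwargs) -> Fraction:
    """Norm(S) = kappa(S) / U(n) as an exact fraction.

    Refuses (ValueError, showing the bounds) when the exact solver could
    not certify optimality within its budget.
    """
    return min_tree_set(system, **kwargs).norm()


def norm_value(kappa: int, n: int) -> Fraction:
    """Normalized tree set size from a known kappa and taxon count."""
    if kappa < 0:
        raise ValueError("kappa must be non-negative")
    return Fraction(kappa, universal_size(n))
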