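"""Unrooted phylogenetic trees and their interchange with split systems.

By the splits equivalence theorem a split system corresponds to a
phylogenetic tree exactly when it is pairwise compatible and contains all
trivial splits; the tree is then unique up to isomorphism. This module
realizes both directions: edge deletion (tree -> splits) and laminar
cluster assembly (splits -> tree).
"""

from __future__ import annotations

from typing import Dict, FrozenSet, Iterable, Iterator, List, Optional

import networkx as nx

from .core import (
    Split,
    SplitSystem,
    TaxaSet,
    are_compatible,
    find_incompatible_pair,
)

__all__ = [
    "PhyloTree",
    "TreeSet",
    "splits_of_tree",
    "tree_from_splits",
    "displays",
]


class PhyloTree:
    """An unrooted leaf-labelled tree.

    Interior vertices have degree >= 3; degree-1 vertices are bijectively
    labelled by the taxa (the sole exception is n = 2, a single edge whose
    two endpoints are both leaves). Nodes are opaque integers; leaves carry
    a ``taxon`` attribute holding the 1-based taxon index.
    """

    __slots__ = ("taxa", "graph", "_leaf_of")

    def __init__(self, taxa: TaxaSet, graph: nx.Graph):
        self.taxa = taxa
        self.graph = graph
        leaf_of: Dict[int, int] = {}
        for node, data in graph.nodes(data=True):
            t = data.get("taxon")
            if t is not None:
                if t in leaf_of:
                    raise ValueError(f"taxon index {t} labels two vertices")
                leaf_of[t] = node
        self._leaf_of = leaf_of
        self._validate()

    def _validate(self) -> None:
        g = self.graph
        n = self.taxa.n
        if g.number_of_nodes() == 0 or not nx.is_tree(g):
            raise ValueError("not a tree (connected and acyclic required)")
        if set(self._leaf_of) != set(range(1, n + 1)):
            raise ValueError("leaves are not bijectively labelled by the taxa")
        for t, node in self._leaf_of.items():
            if g.degree(node) != 1 and n > 2:
                raise ValueError(f"labelled vertex for taxon {t} has degree > 1")
        for node in g.nodes:
            if g.degree(node) == 2:
                raise ValueError(f"vertex {node} has forbidden degree 2")
            if g.degree(node) == 1 and node not in self._leaf_of.values():
                raise ValueError(f"unlabelled leaf vertex {node}")

    @classmethod
    def star(cls, taxa: TaxaSet) -> "PhyloTree":
        """The star tree: one interior vertex, only trivial splits."""
        g = nx.Graph()
        if taxa.n == 2:
            g.add_node(1, taxon=1)
            g.add_node(2, taxon=2)
            g.add_edge(1, 2)
            return cls(taxa, g)
        center = 0
        g.add_node(center)
        for i in range(1, taxa.n + 1):
            g.add_node(i, taxon=i)
            g.add_edge(center, i)
        return cls(taxa, g)

    def leaf(self, taxon_index: int) -> int:
        return self._leaf_of[taxon_index]

    @property
    def n_leaves(self) -> int:
        return self.taxa.n

    def edges(self):
        return self.graph.edges()

    def split_of_edge(self, u: int, v: int) -> Split:
        """The bipartition of the taxa induced by deleting edge (u, v)."""
        comp = _component_taxa(self.graph, u, v)
        return Split(self.taxa, comp)

    def is_binary(self) -> bool:
        return all(
            d == 1 or d == 3 for _, d in self.graph.degree()
        ) or self.taxa.n == 2

    def __eq__(self, other: object) -> bool:
        """Equality up to isomorphism, via canonical split systems."""
        return (
            isinstance(other, PhyloTree)
            and self.taxa == other.taxa
            and splits_of_tree(self) == splits_of_tree(other)
        )

    def __hash__(self) -> int:
        return hash((self.taxa, splits_of_tree(self).splits))

    def __repr__(self) -> str:
        return f"PhyloTree(n={self.taxa.n}, edges={self.graph.number_of_edges()})"


def _component_taxa(g: nx.Graph, u: int, v: int) -> FrozenSet[int]:
    """Taxon indices on the u-side of edge (u, v)."""
    seen = {u, v}
    stack = [u]
    taxa = []
    while stack:
        node = stack.pop()
        t = g.nodes[node].get("taxon")
        if t is not None:
            taxa.append(t)
        for nb in g.neighbors(node):
            if nb not in seen:
                seen.add(nb)
                stack.append(nb)
    return frozenset(taxa)


class TreeSet:
    """A non-empty list of phylogenetic trees on a common taxa set."""

    __slots__ = ("taxa", "trees")

    def __init__(self, trees: Iterable[PhyloTree]):
        trees = list(trees)
        if not trees:
            raise ValueError("a tree set must contain at least one tree")
        taxa = trees[0].taxa
        for t in trees:
            if t.taxa != taxa:
                raise ValueError("all trees in a set must share one taxa set")
        self.taxa = taxa
        self.trees = trees

    def displayed_splits(self) -> SplitSystem:
        """Union of the split systems of the member trees."""
        acc: set[Split] = set()
        for t in self.trees:
            acc |= splits_of_tree(t).splits
        return SplitSystem(self.taxa, acc)

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self) -> Iterator[PhyloTree]:
        return iter(self.trees)

    def __getitem__(self, i: int) -> PhyloTree:
        return self.trees[i]

    def __repr__(self) -> str:
        return f"TreeSet(n={self.taxa.n}, k={len(self.trees)})"


def splits_of_tree(tree: PhyloTree) -> SplitSystem:
    """The split system induced by a tree: one split per edge.

    Contains all n trivial splits (leaf edges) and at most n-3 nontrivial
    ones; pairwise compatible by the splits equivalence theorem.
    """
    splits = [tree.split_of_edge(u, v) for u, v in tree.graph.edges()]
    return SplitSystem(tree.taxa, splits)


def tree_from_splits(
    system: SplitSystem | Iterable[Split],
    taxa: Optional[TaxaSet] = None,
) -> PhyloTree:
    """The unique tree displaying a pairwise compatible split system.

    Trivial splits are implied and added automatically; no refinement
    beyond the input splits is introduced, so
    ``splits_of_tree(tree_from_splits(S)) == S + trivial``.

    Raises ``ValueError`` naming one offending pair if the input is
    incompatible.
    """
    if isinstance(system, SplitSystem):
        if taxa is not None and taxa != system.taxa:
            raise ValueError("taxa argument contradicts the system's taxa")
        taxa = system.taxa
    else:
        if taxa is None:
            raise ValueError("taxa required when passing a bare split iterable")
        system = SplitSystem(taxa, system)

    bad = find_incompatible_pair(system)
    if bad is not None:
        raise ValueError(f"splits are incompatible: {bad[0]} vs {bad[1]}")

    n = taxa.n
    if n == 2:
        return PhyloTree.star(taxa)

    # Compatible nontrivial splits, viewed from taxon 1, form a laminar
    # family of clusters (canonical sides never contain index 1).
    clusters: List[FrozenSet[int]] = sorted(
        {s.side for s in system.splits if not s.trivial}, key=lambda c: (len(c), sorted(c))
    )
    top = frozenset(taxa.indices - {1})
    nodes: List[FrozenSet[int]] = [frozenset({i}) for i in range(2, n + 1)]
    nodes += [c for c in clusters if 1 < len(c) < n - 1]
    if top not in nodes:
        nodes.append(top)

    g = nx.Graph()
    node_id: Dict[FrozenSet[int], int] = {}
    for i in range(1, n + 1):
        g.add_node(i, taxon=i)
    next_id = n + 1
    for c in nodes:
        if len(c) == 1:
            node_id[c] = next(iter(c))  # leaf vertex
        else:
            node_id[c] = next_id
            g.add_node(next_id)
            next_id += 1

    # Parent of a cluster = smallest cluster strictly containing it.
    internal = sorted((c for c in nodes if len(c) > 1), key=len)
    for c in nodes:
        if c == top:
            continue
        parent = min(
            (p for p in internal if len(p) > len(c) and c < p),
            key=len,
            default=top,
        )
        g.add_edge(node_id[c], node_id[parent])
    g.add_edge(1, node_id[top])  # taxon 1 hangs off the root cluster
    return PhyloTree(taxa, g)


def displays(tree_set: TreeSet, system: SplitSystem) -> bool:
    """True iff every split of ``system`` is displayed by some tree."""
    if tree_set.taxa != system.taxa:
        raise ValueError("tree set and split system are on different taxa sets")
    return system.splits <= tree_set.displayed_splits().splits
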