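"""Deterministic synthetic trees and split systems for testing and demos.

Random binary trees are grown by seeded sequential leaf attachment: start
from the three-leaf star and attach each further leaf to a uniformly
chosen existing edge. This is not the uniform distribution over
topologies, but it is simple, spans all topologies, and gives exact
reproducibility from the seed. Split systems built from t such trees have
minimal tree set size at most t by construction.
"""

from __future__ import annotations

import random
from typing import List, Optional

import networkx as nx

from .core import Split, SplitSystem, TaxaSet
from .trees import PhyloTree, TreeSet, splits_of_tree

__all__ = ["random_binary_tree", "random_tree_set", "generate_split_system"]


def random_binary_tree(taxa: TaxaSet, rng: random.Random) -> PhyloTree:
    """A random binary tree grown by sequential leaf attachment."""
    n = taxa.n
    if n == 2:
        return PhyloTree.star(taxa)
    g = nx.Graph()
    g.add_nodes_from([(i, {"taxon": i}) for i in (1, 2, 3)])
    if n == 3:
        g.add_node(0)
        g.add_edges_from([(0, 1), (0, 2), (0, 3)])
        return PhyloTree(taxa, g)
    center = n + 1
    g.add_node(center)
    g.add_edges_from([(center, 1), (center, 2), (center, 3)])
    next_interior = n + 2
    for leaf in range(4, n + 1):
        u, v = rng.choice(sorted(g.edges()))
        g.remove_edge(u, v)
        g.add_node(next_interior)
        g.add_node(leaf, taxon=leaf)
        g.add_edges_from([(u, next_interior), (v, next_interior), (leaf, next_interior)])
        next_interior += 1
    return PhyloTree(taxa, g)


def random_tree_set(
    n: int, n_trees: int, seed: int, taxa: Optional[TaxaSet] = None
) -> TreeSet:
    if taxa is None:
        taxa = TaxaSet.range(n)
    rng = random.Random(seed)
    return TreeSet([random_binary_tree(taxa, rng) for _ in range(n_trees)])


def generate_split_system(
    n: int, n_trees: int, extra_incompatible: int, seed: int
) -> SplitSystem:
    """Random split system with controlled minimal tree set size.

    The union of the nontrivial splits of ``n_trees`` random binary trees
    (hence kappa <= n_trees), optionally topped up with at most
    ``extra_incompatible`` further splits sampled uniformly from the
    remaining split space. Fully reproducible from the arguments.
    """
    if n < 4:
        raise ValueError("need n >= 4 taxa")
    if n_trees < 1:
        raise ValueError("need at least one tree")
    if extra_incompatible < 0:
        raise ValueError("extra_incompatible must be >= 0")
    taxa = TaxaSet.range(n)
    rng = random.Random(seed)
    acc: set[Split] = set()
    for _ in range(n_trees):
        tree = random_binary_tree(taxa, rng)
        acc |= {s for s in splits_of_tree(tree).splits if not s.trivial}
    rest = sorted(taxa.indices - {1})
    for _ in range(extra_incompatible):
        for _attempt in range(64):
            size = rng.randint(2, n - 2)
            side = frozenset(rng.sample(rest, size))
            if len(side) in (1, n - 1):
                continue
            split = Split(taxa, side)
            if not split.trivial and split not in acc:
                acc.add(split)
                break
    return SplitSystem(taxa, acc)
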