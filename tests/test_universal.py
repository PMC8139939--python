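"""U(n), carries/Kummer arithmetic, chain decompositions and construction."""

import itertools
from math import comb

import networkx as nx
import pytest

from splitcover import (
    SplitSystem,
    TaxaSet,
    are_compatible,
    bip_compatibility_graph,
    build_universal_tree_set,
    carries,
    central_binomial_is_odd,
    displays,
    gamma,
    intersection_stat,
    make_split,
    max_matching,
    splits_of_tree,
    symmetric_chain_decomposition,
    universal_size,
)


def p_adic_valuation(value: int, p: int) -> int:
    """Independent oracle: exponent of p in value by repeated division."""
    e = 0
    while value % p == 0:
        value //= p
        e += 1
    return e


class TestUniversalSize:
    def test_five_taxa(self):
        assert universal_size(5) == 5

    def test_archaeal_comparison_sizes(self):
        assert universal_size(13) == 858
        assert universal_size(12) == 462

    def test_sequence_from_four(self):
        assert [universal_size(n) for n in range(4, 10)] == [3, 5, 10, 18, 35, 63]

    def test_small_special_cases(self):
        assert universal_size(2) == 1
        assert universal_size(3) == 1  # star tree displays all (trivial) splits

    def test_rejects_below_two(self):
        with pytest.raises(ValueError):
            universal_size(1)

    def test_matches_half_central_binomial(self):
        for n in range(4, 20):
            assert universal_size(n) == -(-comb(n, n // 2) // 2)

    def test_non_decreasing_from_three(self):
        values = [universal_size(n) for n in range(3, 20)]
        assert values == sorted(values)


class TestCarries:
    def test_printed_binary_example(self):
        assert carries(15, 4, 2) == 2

    def test_one_plus_one_carries_once(self):
        assert carries(1, 1, 2) == 1

    def test_rejects_non_prime_base(self):
        with pytest.raises(ValueError):
            carries(3, 4, 6)

    @pytest.mark.parametrize("p", [2, 3, 5])
    def test_kummer_theorem_on_exhaustive_grid(self, p):
        for a in range(1, 65):
            for b in range(1, 65):
                assert carries(a, b, p) == p_adic_valuation(comb(a + b, a), p)


class TestCentralBinomialParity:
    @pytest.mark.parametrize("n,odd", [(3, True), (5, False), (7, True),
                                       (9, False), (11, False), (13, False),
                                       (15, True)])
    def test_odd_iff_power_of_two_minus_one(self, n, odd):
        assert central_binomial_is_odd(n) is odd
        assert (comb(n, n // 2) % 2 == 1) is odd

    def test_rejects_even_n(self):
        with pytest.raises(ValueError):
            central_binomial_is_odd(8)


class TestSymmetricChainDecomposition:
    @pytest.mark.parametrize("n", range(2, 9))
    def test_invariants_hold_exhaustively(self, n):
        scd = symmetric_chain_decomposition(TaxaSet.range(n))
        scd.validate()  # chain count, one size-m set, full disjoint cover

    def test_four_taxa_chain_count(self):
        scd = symmetric_chain_decomposition(TaxaSet.range(4))
        assert len(scd.chains) == 6
        assert all(len(chain[-1]) == 2 for chain in scd.chains)

    def test_five_taxa_chain_lengths(self):
        scd = symmetric_chain_decomposition(TaxaSet.range(5))
        lengths = sorted(len(c) for c in scd.chains)
        assert lengths == [1] * 5 + [2] * 5

    def test_deterministic(self):
        a = symmetric_chain_decomposition(TaxaSet.range(7))
        b = symmetric_chain_decomposition(TaxaSet.range(7))
        assert a.chains == b.chains

    def test_json_dump_shape(self):
        scd = symmetric_chain_decomposition(TaxaSet.range(4))
        dump = scd.to_index_lists()
        assert len(dump) == 6
        assert all(isinstance(s, list) for chain in dump for s in chain)


class TestGamma:
    def test_maps_subset_to_its_split(self, taxa5):
        assert gamma({1, 2}, taxa5) == make_split({"1", "2"}, taxa5)

    def test_non_injective_on_even_half(self):
        t4 = TaxaSet.range(4)
        assert gamma({1, 2}, t4) == gamma({3, 4}, t4)

    def test_injective_for_odd_n(self, taxa5):
        images = set()
        for r in (1, 2):
            for combo in itertools.combinations(range(1, 6), r):
                images.add(gamma(combo, taxa5))
        assert len(images) == 5 + 10


class TestBipCompatibilityGraph:
    def test_ten_vertices_on_five_taxa(self, taxa5):
        cg = bip_compatibility_graph(taxa5, 2)
        assert cg.graph.number_of_nodes() == 10

    def test_connected_and_regular_odd_case(self, taxa5):
        g = bip_compatibility_graph(taxa5, 2).graph
        assert nx.is_connected(g)
        degrees = {d for _, d in g.degree()}
        assert degrees == {3}  # m + 1 with m = 2

    @pytest.mark.parametrize("n", [4, 6])
    def test_even_half_splits_are_pairwise_incompatible(self, n):
        g = bip_compatibility_graph(TaxaSet.range(n), n // 2).graph
        assert g.number_of_edges() == 0
        assert g.number_of_nodes() == comb(n, n // 2) // 2

    def test_edges_agree_with_pairwise_buneman_check(self):
        taxa = TaxaSet.range(7)
        cg = bip_compatibility_graph(taxa, 3)
        nodes = list(cg.graph.nodes)
        for a, b in itertools.combinations(nodes, 2):
            assert cg.graph.has_edge(a, b) == are_compatible(a, b)


class TestMaxMatching:
    def test_five_taxa_perfect_matching(self, taxa5):
        m = max_matching(bip_compatibility_graph(taxa5, 2))
        assert m.defect == 0
        assert len(m.edges) == 5
        for a, b in m.edges:
            assert are_compatible(a, b)

    def test_seven_taxa_defect_one(self):
        m = max_matching(bip_compatibility_graph(TaxaSet.range(7), 3))
        assert m.defect == 1

    def test_nine_taxa_perfect(self):
        m = max_matching(bip_compatibility_graph(TaxaSet.range(9), 4))
        assert m.defect == 0
        assert len(m.edges) == comb(9, 4) // 2

    def test_paper_pairing_is_a_valid_perfect_matching(self, taxa5):
        # the five printed pairs partition Bip(5,2) into compatible pairs
        pairs = [({"1", "2"}, {"3", "4"}), ({"1", "3"}, {"2", "5"}),
                 ({"1", "4"}, {"3", "5"}), ({"1", "5"}, {"2", "4"}),
                 ({"2", "3"}, {"4", "5"})]
        seen = set()
        for a, b in pairs:
            sa, sb = make_split(a, taxa5), make_split(b, taxa5)
            assert are_compatible(sa, sb)
            seen |= {sa, sb}
        assert len(seen) == 10


class TestIntersectionStat:
    def test_self_overlap_is_m_plus_one(self, taxa5):
        s = make_split({"1", "2"}, taxa5)
        assert intersection_stat(s, s) == 3

    def test_direct_set_intersection(self, taxa5):
        s1 = make_split({"1", "2"}, taxa5)
        s2 = make_split({"3", "4"}, taxa5)
        assert intersection_stat(s1, s2) == len({"3", "4", "5"} & {"1", "2", "5"})

    def test_rejects_wrong_sizes(self, taxa5):
        with pytest.raises(ValueError):
            intersection_stat(make_split({"2"}, taxa5), make_split({"1", "2"}, taxa5))

    def test_connectivity_walk_replay(self, taxa5):
        # the constructive connectivity argument: from any source one can
        # walk to any target along graph edges so that the big-part
        # overlap with the target strictly increases every one or two
        # steps, terminating when the splits coincide
        from splitcover import Split

        cg = bip_compatibility_graph(taxa5, 2)
        g = cg.graph
        m = 2
        for source in g.nodes:
            for target in g.nodes:
                s, steps = source, 0
                while s != target:
                    k = intersection_stat(s, target)
                    x = min(s.big_side - target.big_side)
                    s1 = Split(taxa5, s.big_side - {x})
                    assert g.has_edge(s, s1)
                    if intersection_stat(s1, target) > k:
                        s = s1
                    else:
                        y = min(s.small_side & target.big_side)
                        s2 = Split(taxa5, (s.big_side - {x}) | {y})
                        assert g.has_edge(s1, s2)
                        assert intersection_stat(s2, target) == k + 1
                        s = s2
                    steps += 1
                    assert steps <= 4 * (m + 1), "walk failed to terminate"


class TestBuildUniversalTreeSet:
    @pytest.mark.parametrize("n", range(2, 10))
    def test_size_and_exhaustive_coverage(self, n):
        taxa = TaxaSet.range(n)
        ts = build_universal_tree_set(taxa)
        assert len(ts) == universal_size(n)
        assert ts.displayed_splits() == SplitSystem.all_splits(taxa)

    def test_three_taxa_is_single_star(self):
        ts = build_universal_tree_set(TaxaSet.range(3))
        assert len(ts) == 1
        assert all(s.trivial for s in splits_of_tree(ts[0]))

    @pytest.mark.parametrize("n", [6, 7, 8, 9])
    def test_per_tree_central_split_capacity(self, n):
        cap = 1 if n % 2 == 0 else 2
        for tree in build_universal_tree_set(TaxaSet.range(n)):
            central = [s for s in splits_of_tree(tree).splits if s.size == n // 2]
            assert len(central) <= cap

    def test_five_taxa_pairs_partition_the_size_two_splits(self, taxa5):
        ts = build_universal_tree_set(taxa5)
        seen = []
        for tree in ts:
            pair = [s for s in splits_of_tree(tree).splits if s.size == 2]
            assert len(pair) == 2
            seen += pair
        assert len(set(seen)) == 10

    @pytest.mark.parametrize("n", [6, 8])
    def test_even_trees_have_laminar_small_sides(self, n):
        # chain construction: small sides pairwise nested or disjoint
        for tree in build_universal_tree_set(TaxaSet.range(n)):
            parts = [s.small_side for s in splits_of_tree(tree).nontrivial()]
            for a, b in itertools.combinations(parts, 2):
                assert a <= b or b <= a or not (a & b)

    def test_deterministic_output(self, taxa5):
        a = build_universal_tree_set(taxa5)
        b = build_universal_tree_set(taxa5)
        assert [splits_of_tree(t) for t in a] == [splits_of_tree(t) for t in b]
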