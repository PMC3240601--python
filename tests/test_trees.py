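"""Tree structures, Newick I/O, bipartitions, enumeration, rearrangements."""
from __future__ import annotations

import itertools

import dendropy
import numpy as np
import pytest

from phylopbs.trees import (Bipartition, NewickParseError, PhyloTree,
                            TreeError, double_factorial_topology_count,
                            enumerate_unrooted_topologies,
                            iter_nested_topologies, majority_rule_consensus,
                            nested_canonical, parse_newick,
                            rearrangement_neighbors, restrict_to_leaves)

from conftest import random_binary_tree


class TestParseNewick:
    def test_three_leaf_rooted(self):
        t = parse_newick("(A,(B,C));")
        assert t.leaf_labels == ("A", "B", "C")
        internals = [n for n in t.postorder() if not n.is_leaf]
        assert len(internals) == 2

    def test_quartet_single_nontrivial_bipartition(self):
        t = parse_newick("((A,B),(C,D));")
        assert t.bipartitions() == frozenset(
            {Bipartition.of({"A", "B"}, {"C", "D"})})

    def test_two_leaves_rejected(self):
        with pytest.raises(TreeError):
            parse_newick("(A,B);")

    @pytest.mark.parametrize("bad", ["((A,B,;", "", "(A,(B,C)", ")(,;"])
    def test_malformed_raises_parse_error(self, bad):
        with pytest.raises(NewickParseError):
            parse_newick(bad)

    def test_duplicate_labels_rejected(self):
        with pytest.raises(TreeError, match="duplicate"):
            parse_newick("((A,A),(B,C));")

    def test_underscores_and_lengths_preserved(self):
        t = parse_newick("((G01_s01:0.1,G01_s02:0.2):0.05,(B:1,C:2));")
        assert "G01_s01" in t.leaf_labels
        leaf = t.find_leaf("G01_s01")
        assert leaf.length == pytest.approx(0.1)


class TestRoundTrip:
    def test_newick_round_trip_random_trees(self):
        """Write-then-parse preserves topology and labels (1,000 trees)."""
        rng = np.random.default_rng(20240917)
        for _ in range(1000):
            n = int(rng.integers(4, 12))
            t = random_binary_tree(rng, n)
            back = parse_newick(t.newick())
            assert back.leaf_labels == t.leaf_labels
            assert back.bipartitions() == t.bipartitions()

    def test_quoted_labels_round_trip(self):
        t = parse_newick("(('sp one','sp two'),(C,D));")
        back = parse_newick(t.newick())
        assert back.leaf_labels == ("C", "D", "sp one", "sp two")


class TestBipartition:
    def test_canonical_orientation(self):
        b = Bipartition.of({"Z", "Y"}, {"A", "B"})
        assert "A" in b.side1

    def test_from_string_round_trip(self):
        b = Bipartition.of({"A", "B"}, {"C", "D"})
        assert Bipartition.from_string(str(b)) == b

    def test_overlap_rejected(self):
        with pytest.raises(TreeError):
            Bipartition.of({"A", "B"}, {"B", "C"})

    def test_count_is_n_minus_3(self):
        rng = np.random.default_rng(5)
        for n in range(4, 11):
            t = random_binary_tree(rng, n)
            assert len(t.bipartitions()) == n - 3


class TestEnumeration:
    @pytest.mark.parametrize("n", [4, 5, 6, 7, 8])
    def test_counts_match_double_factorial(self, n):
        count = sum(1 for _ in iter_nested_topologies(n))
        assert count == double_factorial_topology_count(n)

    def test_no_duplicate_topologies(self):
        seen = {nested_canonical(t) for t in iter_nested_topologies(6)}
        assert len(seen) == 105

    def test_public_api_returns_trees(self):
        trees = enumerate_unrooted_topologies(["A", "B", "C", "D"])
        assert len(trees) == 3
        fingerprints = {t.bipartitions() for t in trees}
        assert len(fingerprints) == 3

    def test_above_cap_refused(self):
        with pytest.raises(TreeError, match="cap"):
            enumerate_unrooted_topologies([f"t{i}" for i in range(10)])


def _spr_oracle(tree: PhyloTree):
    """Independent SPR neighborhood via networkx graph surgery.

    Brute force over all (pruned subtree, regraft edge) pairs; results are
    deduplicated by split fingerprint.
    """
    import networkx as nx
    g = nx.Graph()
    counter = itertools.count()
    ids = {}

    def build(node, parent_id):
        i = next(counter)
        ids[i] = node.label
        g.add_node(i)
        if parent_id is not None:
            g.add_edge(parent_id, i)
        for c in node.children:
            build(c, i)
    build(tree.root, None)
    # unroot: splice out degree-2 nodes
    for v in [v for v in list(g) if g.degree(v) == 2]:
        a, b = g.neighbors(v)
        g.remove_node(v)
        g.add_edge(a, b)

    def fingerprint(graph):
        leaves = {v for v in graph if ids.get(v)}
        fps = set()
        for (u, v) in list(graph.edges):
            h = graph.copy()
            h.remove_edge(u, v)
            comp = nx.node_connected_component(h, u)
            side = frozenset(ids[x] for x in comp if ids.get(x))
            other = frozenset(ids[x] for x in leaves if x not in comp)
            if 2 <= len(side) <= len(leaves) - 2:
                fps.add(frozenset({side, other}))
        return frozenset(fps)

    base_fp = fingerprint(g)
    neighbors = set()
    for (p, s) in [(a, b) for a, b in g.edges] + [(b, a) for a, b in g.edges]:
        if g.degree(p) != 3:
            continue
        h = g.copy()
        h.remove_edge(p, s)
        a, b = [x for x in h.neighbors(p)]
        h.remove_node(p)
        h.add_edge(a, b)
        comp = nx.node_connected_component(h, a)
        if s in comp:
            continue
        for (x, y) in list(h.subgraph(comp).edges):
            if {x, y} == {a, b}:
                continue
            h2 = h.copy()
            h2.remove_edge(x, y)
            h2.add_node(p)
            h2.add_edge(x, p)
            h2.add_edge(y, p)
            h2.add_edge(p, s)
            fp = fingerprint(h2)
            if fp != base_fp:
                neighbors.add(fp)
    return neighbors


class TestRearrangements:
    def test_nni_on_quartet_gives_other_two(self):
        t = parse_newick("((A,B),(C,D));")
        nbrs = rearrangement_neighbors(t, "NNI")
        fps = {n.bipartitions() for n in nbrs}
        assert fps == {
            frozenset({Bipartition.of({"A", "C"}, {"B", "D"})}),
            frozenset({Bipartition.of({"A", "D"}, {"B", "C"})})}

    @pytest.mark.parametrize("newick", ["((A,B),(C,(D,E)));",
                                        "(((A,B),(C,D)),(E,F));"])
    def test_spr_contains_nni(self, newick):
        t = parse_newick(newick)
        nni = {n.bipartitions() for n in rearrangement_neighbors(t, "NNI")}
        spr = {n.bipartitions() for n in rearrangement_neighbors(t, "SPR")}
        assert nni <= spr

    @pytest.mark.parametrize("newick", ["((A,B),(C,(D,E)));",
                                        "(((A,B),C),((D,E),F));",
                                        "((A,(B,C)),((D,E),F));"])
    def test_spr_matches_brute_force_oracle(self, newick):
        t = parse_newick(newick)
        mine = {frozenset(frozenset({b.side1, b.side2})
                          for b in n.bipartitions())
                for n in rearrangement_neighbors(t, "SPR")}
        oracle = _spr_oracle(t)
        assert mine == oracle

    def test_nonbinary_rejected(self):
        t = parse_newick("(A,B,C,D,E);")
        with pytest.raises(TreeError):
            rearrangement_neighbors(t, "NNI")

    def test_input_not_in_neighbors(self):
        t = parse_newick("((A,B),(C,(D,E)));")
        for n in rearrangement_neighbors(t, "SPR"):
            assert n.bipartitions() != t.bipartitions()


class TestConsensus:
    def test_unanimous_trees(self):
        trees = [parse_newick("((A,B),(C,(D,E)));") for _ in range(10)]
        cons = majority_rule_consensus(trees, 0.5)
        assert cons.bipartitions() == trees[0].bipartitions()
        freqs = [n.support for n in cons.preorder() if n.support is not None]
        assert all(f == 100.0 for f in freqs)

    def test_sixty_percent_split(self):
        trees = ([parse_newick("((A,B),(C,D),E);")] * 6
                 + [parse_newick("((A,C),(B,D),E);")] * 4)
        cons = majority_rule_consensus(trees, 0.5)
        ab = Bipartition.of({"A", "B"}, {"C", "D", "E"})
        assert ab in cons.bipartitions()
        freqs = {n.support for n in cons.preorder() if n.support is not None}
        assert freqs == {60.0}

    def test_all_conflicting_gives_star(self):
        trees = [parse_newick(s) for s in
                 ["((A,B),(C,D),E);", "((A,C),(B,D),E);",
                  "((A,D),(B,C),E);"]]
        cons = majority_rule_consensus(trees, 0.5)
        assert cons.bipartitions() == frozenset()

    def test_exact_half_excluded(self):
        trees = ([parse_newick("((A,B),(C,D),E);")] * 5
                 + [parse_newick("((A,C),(B,D),E);")] * 5)
        cons = majority_rule_consensus(trees, 0.5)
        assert cons.bipartitions() == frozenset()

    def test_mismatched_taxa_rejected(self):
        with pytest.raises(TreeError, match="difference"):
            majority_rule_consensus([parse_newick("((A,B),(C,D));"),
                                     parse_newick("((A,B),(C,E));")])

    def test_agrees_with_dendropy(self):
        """Dual-route check against dendropy's majority-rule consensus."""
        rng = np.random.default_rng(77)
        for rep in range(10):
            trees = [random_binary_tree(rng, 7) for _ in range(9)]
            cons = majority_rule_consensus(trees, 0.5)
            tns = dendropy.TaxonNamespace()
            dtl = dendropy.TreeList(
                [dendropy.Tree.get(data=t.newick(), schema="newick",
                                   taxon_namespace=tns,
                                   preserve_underscores=True)
                 for t in trees])
            dcons = dtl.consensus(min_freq=0.5000001)
            mine = {frozenset({b.side1, b.side2}) for b in cons.bipartitions()}
            theirs = set()
            taxa = set(trees[0].leaf_labels)
            dcons.encode_bipartitions()
            for edge in dcons.preorder_edge_iter():
                if edge.head_node is None or edge.head_node.parent_node is None:
                    continue
                side = frozenset(l.taxon.label for l in
                                 edge.head_node.leaf_iter())
                if 2 <= len(side) <= len(taxa) - 2:
                    theirs.add(frozenset({side, frozenset(taxa - side)}))
            assert mine == theirs


class TestRestrict:
    def test_restrict_preserves_topology(self):
        t = parse_newick("(((A,B),C),((D,E),F));")
        r = restrict_to_leaves(t, ["A", "B", "D", "E"])
        assert r.leaf_labels == ("A", "B", "D", "E")
        assert Bipartition.of({"A", "B"}, {"D", "E"}) in r.bipartitions()

    def test_restrict_to_one_leaf_is_none(self):
        t = parse_newick("((A,B),(C,D));")
        assert restrict_to_leaves(t, ["A"]) is None
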