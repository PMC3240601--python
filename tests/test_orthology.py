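"""Family assignment, EST ordering and placement, ortholog-set extraction,
co-ortholog sampling."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from phylopbs.matrix import CharacterMatrix
from phylopbs.orthology import (GeneFamily, OrthologyError, assign_families,
                                extract_ortholog_sets, order_ests, place_est,
                                root_at_center, sample_co_orthologs)
from phylopbs.simulate import (SimConfig, sim_gene_family, sim_sequences,
                               sim_species_tree, _leaves_under)
from phylopbs.trees import Node, PhyloTree, parse_newick, restrict_to_leaves


def hits_frame(rows):
    return pd.DataFrame(rows, columns=["query", "family", "evalue"])


class TestAssignFamilies:
    def test_best_hit_wins(self):
        fa = assign_families(hits_frame([("q", "famA", 1e-50),
                                         ("q", "famB", 1e-30)]))
        assert fa.assigned["q"] == "famA"

    def test_cutoff_excludes_weak_hits(self):
        fa = assign_families(hits_frame([("q", "famA", 1e-10)]),
                             cutoff=1e-20)
        assert fa.unassigned == ["q"] and "q" not in fa.assigned

    def test_tie_resolves_lexicographically_and_is_logged(self):
        fa = assign_families(hits_frame([("q", "famB", 1e-40),
                                         ("q", "famA", 1e-40)]))
        assert fa.assigned["q"] == "famA"
        assert fa.ties == ["q"]


class TestOrderEsts:
    @pytest.fixture
    def family(self):
        aln = CharacterMatrix.from_dict(
            {"g1|S1": "AAAA", "g2|S2": "AACA", "x|E1": "AAAA",
             "y|E2": "AACA", "z|E3": "CCCC"})
        return GeneFamily("fam", aln,
                          {g: g.split("|")[1] for g in aln.taxa},
                          parse_newick("(g1|S1,(g2|S2,x|E1));", min_leaves=3))

    def test_sorted_by_ascending_evalue(self, family):
        hits = hits_frame([("x|E1", "fam", 1e-40), ("y|E2", "fam", 1e-60),
                           ("z|E3", "fam", 1e-5)])
        assert order_ests(family, hits) == ["y|E2", "x|E1", "z|E3"]

    def test_singleton(self, family):
        hits = hits_frame([("x|E1", "fam", 1e-40)])
        assert order_ests(family, hits) == ["x|E1"]

    def test_equal_evalues_lexicographic(self, family):
        hits = hits_frame([("y|E2", "fam", 1e-40), ("x|E1", "fam", 1e-40)])
        assert order_ests(family, hits) == ["x|E1", "y|E2"]

    def test_missing_hit_is_an_error(self, family):
        hits = hits_frame([("x|E1", "fam", 1e-40)])
        with pytest.raises(OrthologyError, match="z"):
            order_ests(family, hits, ests=["x|E1", "z|E3"])


class TestPlaceEst:
    def test_identical_est_joins_its_twin(self):
        rows = {"A": "AAAAG", "B": "ACCAC", "C": "CCCCG", "D": "CCGGG",
                "E": "ACCAC"}
        m = CharacterMatrix.from_dict(rows)
        placed, score = place_est(parse_newick("((A,B),(C,D));"), m, "E")
        sib = placed.find_leaf("E").parent
        assert {n.label for n in sib.children} == {"B", "E"}

    def test_score_equals_brute_force_minimum(self):
        """The reported placement score matches trying every branch by hand."""
        from phylopbs.parsimony import fitch_length
        rng = np.random.default_rng(6)
        rows = {t: "".join(rng.choice(list("ACGT"), 12)) for t in "ABCDEF"}
        rows["Q"] = "".join(rng.choice(list("ACGT"), 12))
        m = CharacterMatrix.from_dict(rows)
        guide = parse_newick("(((A,B),C),((D,E),F));")
        placed, score = place_est(guide, m, "Q")
        # oracle: rebuild each augmented tree from newick surgery
        candidates = []
        for target_label_set in _all_edge_subsets(guide):
            candidates.append(
                _attach_newick(guide, target_label_set, "Q"))
        oracle = min(fitch_length(parse_newick(nwk), m)
                     for nwk in candidates)
        assert score == oracle

    def test_clade_signal_pulls_est_into_clade(self):
        """An EST ambiguous everywhere except a column carrying the {C,D}
        synapomorphy attaches within (or on the stem of) that clade."""
        rows = {"A": "AA", "B": "AA", "C": "GG", "D": "GG", "E": "AA",
                "Q": "G?"}
        m = CharacterMatrix.from_dict(rows)
        placed, _ = place_est(parse_newick("((A,B),((C,D),E));"), m, "Q")
        sib = placed.find_leaf("Q").parent
        below = set()
        for c in sib.children:
            below |= {l.label for l in _leaves_under(c)}
        assert below - {"Q"} <= {"C", "D"}

    def test_all_missing_est_rejected(self):
        m = CharacterMatrix.from_dict({"A": "AC", "B": "CC", "C": "AA",
                                       "Q": "??"})
        with pytest.raises(OrthologyError, match="missing"):
            place_est(parse_newick("(A,(B,C));"), m, "Q")

    def test_recovers_source_leaf_neighborhood(self):
        """ESTs copied from an existing leaf land next to it (>=95% of 200
        simulated families; score-tied placements inside the leaf's local
        clade count, since the data cannot distinguish them)."""
        rng = np.random.default_rng(9)
        cfg = SimConfig(seed=9)
        st = sim_species_tree(cfg, rng)
        recovered = total = 0
        while total < 200:
            truth = sim_gene_family(st, cfg, rng, f"p{total}")
            if truth.gene_tree.n_leaves < 4:
                continue
            aln = sim_sequences(truth.gene_tree, 60, rng=rng)
            leaves = sorted(truth.gene_tree.leaf_labels)
            src = leaves[int(rng.integers(len(leaves)))]
            rows = {g: aln.sequence(g) for g in leaves}
            rows["EST|x"] = rows[src]
            placed, _ = place_est(truth.gene_tree,
                                  CharacterMatrix.from_dict(rows), "EST|x")
            sib = placed.find_leaf("EST|x").parent
            below = set()
            for c in sib.children:
                below |= {l.label for l in _leaves_under(c)}
            total += 1
            if src in below:
                recovered += 1
        assert recovered >= 190


def _all_edge_subsets(tree):
    out = []
    for node in tree.preorder():
        if node.parent is None:
            continue
        out.append(frozenset(l.label for l in _leaves_under(node)))
    return out


def _attach_newick(tree, clade_labels, est):
    t = tree.copy()
    for node in t.preorder():
        if node.parent is None:
            continue
        labels = frozenset(l.label for l in _leaves_under(node))
        if labels == clade_labels:
            parent = node.parent
            pos = parent.children.index(node)
            joint = Node()
            joint.add(node)
            joint.add(Node(est))
            parent.children[pos] = joint
            joint.parent = parent
            return PhyloTree(t.root, rooted=t.rooted).newick()
    raise AssertionError("edge not found")


class TestExtractOrthologSets:
    def test_root_duplication_with_co_ortholog_pair(self, fig_gene_family_tree):
        """Root duplication plus a within-species pair: the pair stays with
        its orthologous partners, giving {A1,B1,C1} and {A2,A3,B2,C2}."""
        tree, species_of = fig_gene_family_tree
        sets = extract_ortholog_sets(tree, species_of, "fam")
        got = sorted(sorted(s.genes) for s in sets)
        assert got == [["A1", "B1", "C1"], ["A2", "A3", "B2", "C2"]]

    def test_all_species_distinct_single_set(self):
        t = parse_newick("((A1,B1),(C1,D1));")
        sets = extract_ortholog_sets(t, {g: g[0] for g in t.leaf_labels})
        assert len(sets) == 1
        assert sets[0].genes == frozenset({"A1", "B1", "C1", "D1"})

    def test_propagation_keeps_larger_context(self):
        t = parse_newick("(X1,((A1,B1),(A2,B2)));")
        sets = extract_ortholog_sets(
            t, {"X1": "X", "A1": "A", "B1": "B", "A2": "A", "B2": "B"})
        got = sorted(sorted(s.genes) for s in sets)
        assert got == [["A1", "B1", "X1"], ["A2", "B2"]]

    def test_unrooted_input_rejected(self):
        t = parse_newick("((A1,B1),(A2,B2),(C1,C2));")
        t.rooted = False
        with pytest.raises(OrthologyError, match="unrooted"):
            extract_ortholog_sets(t, {g: g[0] for g in t.leaf_labels})

    def test_sets_partition_the_gene_set(self):
        """Extraction conserves genes: disjoint sets covering everything."""
        cfg = SimConfig(seed=21, duplication_rate=0.8, loss_rate=0.4)
        rng = np.random.default_rng(21)
        st = sim_species_tree(cfg, rng)
        for i in range(50):
            truth = sim_gene_family(st, cfg, rng, f"f{i}")
            sets = extract_ortholog_sets(truth.gene_tree, truth.species_of)
            all_genes = [g for s in sets for g in s.genes]
            assert len(all_genes) == len(set(all_genes))
            assert set(all_genes) == set(truth.gene_tree.leaf_labels)

    def test_zero_duplication_families_give_one_set(self):
        cfg = SimConfig(seed=30, duplication_rate=0.0, loss_rate=0.3)
        rng = np.random.default_rng(30)
        st = sim_species_tree(cfg, rng)
        for i in range(30):
            truth = sim_gene_family(st, cfg, rng, f"f{i}")
            if truth.gene_tree.n_leaves == 0:
                continue
            sets = extract_ortholog_sets(truth.gene_tree, truth.species_of)
            assert len(sets) == 1

    def test_set_count_matches_event_log(self):
        """Without losses, each duplication on a branch spanning >= 2
        species adds one set (within-species duplications only create
        co-ortholog groups)."""
        cfg = SimConfig(seed=4, duplication_rate=0.5, loss_rate=0.0)
        rng = np.random.default_rng(4)
        st = sim_species_tree(cfg, rng)
        for i in range(100):
            truth = sim_gene_family(st, cfg, rng, f"f{i}")
            expected = 1 + sum(1 for e in truth.events
                               if e["type"] == "duplication"
                               and e["n_species"] >= 2)
            sets = extract_ortholog_sets(truth.gene_tree, truth.species_of)
            assert len(sets) == expected


class TestSampleCoOrthologs:
    def test_one_gene_per_species(self, fig_gene_family_tree):
        tree, species_of = fig_gene_family_tree
        big = extract_ortholog_sets(tree, species_of, "fam")[1]
        sampled = sample_co_orthologs(big, seed=5)
        assert max(sampled.species_counts.values()) == 1
        assert sampled.genes & {"A2", "A3"}
        assert {"B2", "C2"} <= sampled.genes

    def test_identity_when_already_unique(self):
        t = parse_newick("((A1,B1),(C1,D1));")
        s = extract_ortholog_sets(t, {g: g[0] for g in t.leaf_labels})[0]
        assert sample_co_orthologs(s, seed=1).genes == s.genes

    def test_deterministic_given_seed(self, fig_gene_family_tree):
        tree, species_of = fig_gene_family_tree
        big = extract_ortholog_sets(tree, species_of, "fam")[1]
        assert (sample_co_orthologs(big, seed=11).genes
                == sample_co_orthologs(big, seed=11).genes)


class TestRootAtCenter:
    def test_center_of_caterpillar(self):
        t = parse_newick("(A,(B,(C,(D,(E,F)))));")
        t.rooted = False
        rooted = root_at_center(t)
        assert rooted.rooted
        assert rooted.leaf_labels == t.leaf_labels
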