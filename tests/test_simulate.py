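"""Synthetic-data generator: species trees, duplication/loss gene families,
sequence evolution, EST sampling, annotations, and full-corpus determinism."""
from __future__ import annotations

import hashlib
import json
from collections import Counter

import numpy as np
import pytest
from scipy.stats import spearmanr

from phylopbs.matrix import CharacterMatrix
from phylopbs.simulate import (SimConfig, SimulationError,
                               choose_target_clade, sim_annotations,
                               sim_est_sampling, sim_gene_family,
                               sim_sequences, sim_species_tree,
                               simulate_dataset)
from phylopbs.trees import Bipartition


class TestSpeciesTree:
    def test_leaf_count_and_structure(self):
        cfg = SimConfig(seed=1, n_genera=2, species_per_genus=2)
        t = sim_species_tree(cfg)
        assert t.n_leaves == 4
        internals = [n for n in t.postorder() if not n.is_leaf]
        assert len(internals) == 3

    def test_same_seed_same_tree(self):
        cfg = SimConfig(seed=7)
        assert sim_species_tree(cfg).newick() == sim_species_tree(cfg).newick()

    def test_labels_match_genus_structure(self):
        cfg = SimConfig(seed=2, n_genera=3, species_per_genus=3)
        t = sim_species_tree(cfg)
        genera = Counter(l.split("_")[0] for l in t.leaf_labels)
        assert genera == {"G01": 3, "G02": 3, "G03": 3}

    def test_genera_are_monophyletic(self):
        cfg = SimConfig(seed=3, n_genera=4, species_per_genus=3)
        t = sim_species_tree(cfg)
        from phylopbs.simulate import _leaves_under
        for g in ("G01", "G02", "G03", "G04"):
            members = [l for l in t.leaf_labels if l.startswith(g)]
            clade = t.mrca(members)
            assert {l.label for l in _leaves_under(clade)} == set(members)


class TestGeneFamily:
    def test_zero_rates_give_congruent_tree(self):
        cfg = SimConfig(seed=5, duplication_rate=0, loss_rate=0)
        rng = np.random.default_rng(5)
        st = sim_species_tree(cfg, rng)
        truth = sim_gene_family(st, cfg, rng)
        assert truth.congruent
        assert truth.gene_tree.n_leaves == st.n_leaves
        sp_splits = {frozenset({b.side1, b.side2})
                     for b in st.bipartitions()}
        gt_splits = {
            frozenset({frozenset(g.rsplit("|", 1)[1] for g in b.side1),
                       frozenset(g.rsplit("|", 1)[1] for g in b.side2)})
            for b in truth.gene_tree.bipartitions()}
        assert gt_splits == sp_splits

    def test_forced_root_duplication_gives_two_groups(self):
        """A gene tree whose root is a duplication decomposes into exactly
        two ortholog groups."""
        from phylopbs.orthology import extract_ortholog_sets
        from phylopbs.trees import Node, PhyloTree
        cfg = SimConfig(seed=6, duplication_rate=0, loss_rate=0)
        rng = np.random.default_rng(6)
        st = sim_species_tree(cfg, rng)
        a = sim_gene_family(st, cfg, rng, family_id="copyA")
        b = sim_gene_family(st, cfg, rng, family_id="copyB")
        root = Node()
        root.add(a.gene_tree.root)
        root.add(b.gene_tree.root)
        joined = PhyloTree(root, rooted=True)
        species_of = {**a.species_of, **b.species_of}
        sets = extract_ortholog_sets(joined, species_of)
        assert len(sets) == 2

    def test_event_counts_poisson_consistent(self):
        """Mean event count over 500 replicates within 3 SE of
        rate x species-tree length (rates small enough that lineage-count
        feedback is negligible)."""
        cfg = SimConfig(seed=8, duplication_rate=0.05, loss_rate=0.05)
        rng = np.random.default_rng(8)
        st = sim_species_tree(cfg, rng)
        total_len = sum(n.length for n in st.postorder()
                        if n.parent is not None)
        lam = (cfg.duplication_rate + cfg.loss_rate) * total_len
        counts = []
        for i in range(500):
            truth = sim_gene_family(st, cfg, rng, f"f{i}")
            counts.append(truth.n_dup + truth.n_loss)
        se = np.std(counts, ddof=1) / np.sqrt(len(counts))
        assert abs(np.mean(counts) - lam) <= 3 * se + 0.02

    def test_all_lost_raises_after_retries(self):
        cfg = SimConfig(seed=9, duplication_rate=0.0, loss_rate=400.0)
        rng = np.random.default_rng(9)
        st = sim_species_tree(cfg, rng)
        with pytest.raises(SimulationError, match="lost"):
            sim_gene_family(st, cfg, rng, max_retries=5)


class TestSequences:
    def test_zero_length_branches_identical_sequences(self):
        cfg = SimConfig(seed=10, duplication_rate=0, loss_rate=0,
                        branch_length_range=(0.0, 0.0))
        rng = np.random.default_rng(10)
        st = sim_species_tree(cfg, rng)
        truth = sim_gene_family(st, cfg, rng)
        aln = sim_sequences(truth.gene_tree, 30, rng=rng)
        seqs = {aln.sequence(t) for t in aln.taxa}
        assert len(seqs) == 1

    def test_same_seed_identical_matrix(self):
        cfg = SimConfig(seed=11)
        rng = np.random.default_rng(11)
        st = sim_species_tree(cfg, rng)
        truth = sim_gene_family(st, cfg, rng)
        a = sim_sequences(truth.gene_tree, 40, seed=3)
        b = sim_sequences(truth.gene_tree, 40, seed=3)
        assert all(a.sequence(t) == b.sequence(t) for t in a.taxa)

    def test_divergence_tracks_branch_length(self):
        """Realized substitution counts correlate with branch lengths
        (rank correlation > 0 over ~100 branches)."""
        cfg = SimConfig(seed=12, n_genera=10, species_per_genus=3,
                        duplication_rate=0, loss_rate=0,
                        branch_length_range=(0.005, 0.4))
        rng = np.random.default_rng(12)
        st = sim_species_tree(cfg, rng)
        truth = sim_gene_family(st, cfg, rng)
        aln, subs = sim_sequences(truth.gene_tree, 200, rng=rng,
                                  return_branch_subs=True)
        lengths, counts = [], []
        below = {}
        for node in truth.gene_tree.postorder():
            if node.is_leaf:
                below[id(node)] = frozenset([node.label])
            else:
                below[id(node)] = frozenset().union(
                    *(below[id(c)] for c in node.children))
            if node.parent is not None:
                key = below[id(node)]
                if key in subs:
                    lengths.append(node.length)
                    counts.append(subs[key])
        assert len(lengths) >= 50
        rho, _ = spearmanr(lengths, counts)
        assert rho > 0


class TestEstSampling:
    def test_zero_missingness_is_identity(self):
        m = CharacterMatrix.from_dict({"a": "ACGT", "b": "ACGT"},
                                      {"p1": range(0, 2), "p2": range(2, 4)})
        out = sim_est_sampling(m, 0.0, seed=1)
        assert (out.data == m.data).all()

    def test_retention_fraction_binomial(self):
        """At 60% missingness the retained fraction of (taxon, partition)
        blocks is within 3 SE of 0.4 (1,000 partitions)."""
        rows = {f"t{i}": "AC" * 1000 for i in range(4)}
        parts = {f"p{j}": range(2 * j, 2 * j + 2) for j in range(1000)}
        m = CharacterMatrix.from_dict(rows, parts)
        out = sim_est_sampling(m, 0.6, seed=2)
        n_blocks = 4 * 1000
        retained = sum(
            not out.is_missing_row(t, out.partitions[p])
            for t in out.taxa for p in out.partitions)
        frac = retained / n_blocks
        se = np.sqrt(0.4 * 0.6 / n_blocks)
        assert abs(frac - 0.4) <= 3 * se

    def test_same_seed_same_pattern(self):
        rows = {f"t{i}": "ACGT" * 5 for i in range(6)}
        parts = {f"p{j}": range(4 * j, 4 * j + 4) for j in range(5)}
        m = CharacterMatrix.from_dict(rows, parts)
        a = sim_est_sampling(m, 0.5, seed=4)
        b = sim_est_sampling(m, 0.5, seed=4)
        assert (a.data == b.data).all()


class TestAnnotations:
    def test_full_planting_no_background(self):
        cfg = SimConfig(seed=13, planted_fraction=1.0,
                        background_term_freq=0.0)
        ann = sim_annotations([("a", True), ("b", False), ("c", True)],
                              cfg, np.random.default_rng(0))
        assert ann.terms("a") == {cfg.planted_term}
        assert ann.terms("c") == {cfg.planted_term}
        assert not ann.annotated("b")

    def test_background_rate_roughly_respected(self):
        cfg = SimConfig(seed=14, planted_fraction=0.0,
                        background_term_freq=0.2, n_background_terms=10)
        parts = [(f"p{i}", False) for i in range(500)]
        ann = sim_annotations(parts, cfg, np.random.default_rng(1))
        total = sum(len(ann.terms(p)) for p, _ in parts)
        assert abs(total / (500 * 10) - 0.2) < 0.03


class TestDataset:
    def test_end_to_end_byte_determinism(self, tmp_path):
        """Two runs with the same master seed write identical files."""
        cfg = SimConfig(seed=17, n_families=10, partition_length=30)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        simulate_dataset(cfg, outdir=d1)
        simulate_dataset(SimConfig(seed=17, n_families=10,
                                   partition_length=30), outdir=d2)
        files1 = sorted(p.relative_to(d1) for p in d1.rglob("*")
                        if p.is_file())
        files2 = sorted(p.relative_to(d2) for p in d2.rglob("*")
                        if p.is_file())
        assert files1 == files2
        for rel in files1:
            h1 = hashlib.sha256((d1 / rel).read_bytes()).hexdigest()
            h2 = hashlib.sha256((d2 / rel).read_bytes()).hexdigest()
            assert h1 == h2, rel

    def test_truth_log_supports_ground_truth_orthology(self, tmp_path):
        cfg = SimConfig(seed=18, n_families=8)
        ds = simulate_dataset(cfg, outdir=tmp_path)
        truth = json.loads((tmp_path / "truth.json").read_text())
        assert truth["seed"] == 18
        assert len(truth["families"]) == 8
        for fid, info in truth["families"].items():
            assert {"n_dup", "n_loss", "congruent",
                    "supports_target"} <= set(info)

    def test_target_clade_is_rooted_and_deterministic(self):
        cfg = SimConfig(seed=19)
        st = sim_species_tree(cfg)
        b1, side1 = choose_target_clade(st)
        b2, side2 = choose_target_clade(st)
        assert b1 == b2 and side1 == side2
        assert st.mrca(side1) is not None
        from phylopbs.simulate import _leaves_under
        clade = {l.label for l in _leaves_under(st.mrca(side1))}
        assert clade == set(side1)
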