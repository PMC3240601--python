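"""Synthetic data with the statistical structure the pipeline assumes.

The generator produces a genus-structured species tree, gene families
evolving inside it under a duplication/loss birth-death process, aligned
sequences evolved along the gene trees under an equal-rates (Jukes-Cantor
style) substitution model, EST-style incomplete sampling, BLAST-like hit
tables with E-values monotone in sequence identity, and functional-term
annotations with a planted enrichment among families congruent with a
target clade.  Every stage is driven by one master seed and an event log
sufficient to recover ground-truth ortholog sets independently of the
orthology module.

Defaults describe a desk-scale analogue of a large EST phylogenomics
study: 10 species in 5 genera, 200 gene families of 60 aligned residues,
20% missingness, a planted term carried by half of the congruent families
against a 10% background term frequency.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .matrix import CharacterMatrix, MISSING, write_fasta
from .orthology import GeneFamily
from .support import preorder_node_ids
from .trees import Bipartition, Node, PhyloTree, TreeError, restrict_to_leaves

PROTEIN = "ACDEFGHIKLMNPQRSTVWY"
DNA = "ACGT"


class SimulationError(RuntimeError):
    """Simulation could not produce valid output (e.g. all genes lost)."""


@dataclass
class SimConfig:
    """Study conditions for the synthetic corpus.

    Rates are per unit branch length, which is calibrated in expected
    substitutions per site; ``branch_length_range`` bounds the uniform draw
    per species-tree branch.
    """
    n_genera: int = 5
    species_per_genus: int = 2
    n_families: int = 200
    partition_length: int = 60
    alphabet: str = "protein"
    tree_shape: str = "yule"            # or "uniform"
    branch_length_range: tuple = (0.04, 0.12)
    duplication_rate: float = 0.4
    loss_rate: float = 0.2
    est_missingness: float = 0.2
    n_genome_per_genus: int = 1
    target_stem_scale: float = 0.2
    target_stem_min_subs: int = 2
    planted_term: str = "T_planted"
    planted_fraction: float = 0.5
    background_term_freq: float = 0.1
    n_background_terms: int = 20
    seed: int = 0

    def __post_init__(self):
        if self.n_genera * self.species_per_genus < 4:
            raise SimulationError("need at least 4 species")
        if not 0 <= self.est_missingness < 1:
            raise SimulationError("est_missingness must be in [0, 1)")
        for r in (self.duplication_rate, self.loss_rate):
            if r < 0 or not np.isfinite(r):
                raise SimulationError("rates must be finite and >= 0")

    @property
    def states(self) -> str:
        return PROTEIN if self.alphabet == "protein" else DNA

    @property
    def species(self) -> list[str]:
        return [f"G{g:02d}_s{s:02d}"
                for g in range(1, self.n_genera + 1)
                for s in range(1, self.species_per_genus + 1)]

    @property
    def genus_map(self) -> dict[str, str]:
        return {sp: sp.split("_")[0] for sp in self.species}

    @property
    def genome_species(self) -> list[str]:
        per_genus: dict[str, list[str]] = {}
        for sp in self.species:
            per_genus.setdefault(self.genus_map[sp], []).append(sp)
        out = []
        for genus in sorted(per_genus):
            out.extend(sorted(per_genus[genus])[: self.n_genome_per_genus])
        return out


# ---------------------------------------------------------------------------
# Species tree
# ---------------------------------------------------------------------------

def _random_rooted_topology(labels: Sequence[str], shape: str,
                            rng: np.random.Generator) -> Node:
    labels = list(labels)
    if len(labels) == 1:
        return Node(labels[0])
    root = Node()
    root.add(Node(labels[0]))
    root.add(Node(labels[1]))
    nodes = list(root.children)
    for label in labels[2:]:
        if shape == "uniform":
            target = nodes[int(rng.integers(len(nodes)))]
        else:  # pure birth: split a uniformly chosen current leaf
            leaves = [n for n in nodes if n.is_leaf]
            target = leaves[int(rng.integers(len(leaves)))]
        parent = target.parent
        joint = Node()
        pos = parent.children.index(target)
        parent.children[pos] = joint
        joint.parent = parent
        joint.add(target)
        leaf = joint.add(Node(label))
        nodes.extend([joint, leaf])
    return root


def sim_species_tree(config: SimConfig,
                     rng: Optional[np.random.Generator] = None) -> PhyloTree:
    """Random rooted binary species tree with genus-monophyletic structure.

    Leaves are labeled ``G<genus>_s<species>``; branch lengths (expected
    substitutions per site) are uniform draws from
    ``config.branch_length_range``.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    genera = sorted({g for g in config.genus_map.values()})
    per_genus: dict[str, list[str]] = {}
    for sp in config.species:
        per_genus.setdefault(config.genus_map[sp], []).append(sp)
    root = _random_rooted_topology(genera, config.tree_shape, rng)
    tree = PhyloTree(root, rooted=True)
    for leaf in list(tree.leaf_nodes()):
        members = sorted(per_genus[leaf.label])
        if len(members) == 1:
            leaf.label = members[0]
        else:
            sub = _random_rooted_topology(members, config.tree_shape, rng)
            leaf.label = None
            if sub.is_leaf:
                leaf.label = sub.label
            else:
                for c in sub.children:
                    leaf.add(c)
    tree = PhyloTree(tree.root, rooted=True)
    lo, hi = config.branch_length_range
    for node in tree.postorder():
        if node.parent is not None:
            node.length = float(rng.uniform(lo, hi))
    return tree


# ---------------------------------------------------------------------------
# Gene families (duplication/loss birth-death inside the species tree)
# ---------------------------------------------------------------------------

@dataclass
class GeneFamilyTruth:
    """A simulated family: gene tree plus its full event log."""
    family_id: str
    gene_tree: PhyloTree
    species_of: dict[str, str]
    events: list[dict]
    n_dup: int
    n_loss: int

    @property
    def congruent(self) -> bool:
        """True when the family evolved without duplications or losses."""
        return self.n_dup == 0 and self.n_loss == 0


def _prune_and_suppress(node: Node) -> Optional[Node]:
    kids = [k for k in (_prune_and_suppress(c) for c in node.children)
            if k is not None]
    node.children = []
    if not kids:
        return node if node.label is not None else None
    if len(kids) == 1 and node.label is None:
        only = kids[0]
        only.length = (only.length or 0.0) + (node.length or 0.0)
        only.parent = None
        return only
    for k in kids:
        node.add(k)
    return node


def sim_gene_family(species_tree: PhyloTree, config: SimConfig,
                    rng: Optional[np.random.Generator] = None,
                    family_id: str = "fam",
                    max_retries: int = 20) -> GeneFamilyTruth:
    """Evolve one gene family along the species tree.

    A single ancestral gene enters at the species-tree root; along each
    branch every gene lineage independently duplicates (rate
    ``duplication_rate``) or dies (rate ``loss_rate``) as a Poisson process
    in branch-length time.  With both rates zero the gene tree is exactly
    congruent with the species tree, one gene per species.  Families losing
    every gene are re-simulated up to ``max_retries``.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    d, l = config.duplication_rate, config.loss_rate
    total = d + l

    for _ in range(max_retries):
        events: list[dict] = []
        counter = {"n": 0}

        def along_branch(g: Node, remaining: float, branch: str,
                         n_species: int) -> list[Node]:
            while True:
                wait = (rng.exponential(1.0 / total)
                        if total > 0 else np.inf)
                if wait >= remaining:
                    g.length = (g.length or 0.0) + remaining
                    return [g]
                g.length = (g.length or 0.0) + wait
                remaining -= wait
                if rng.random() < (l / total if total else 0.0):
                    events.append({"type": "loss", "branch": branch,
                                   "n_species": n_species})
                    return []
                events.append({"type": "duplication", "branch": branch,
                               "n_species": n_species})
                survivors = []
                rest = remaining
                for _ in range(2):
                    child = Node(length=0.0)
                    g.add(child)
                    survivors.extend(along_branch(child, rest, branch,
                                                  n_species))
                return survivors

        def process(snode: Node, lineages: list[Node]) -> None:
            if snode.is_leaf:
                for g in lineages:
                    counter["n"] += 1
                    g.label = f"{family_id}.g{counter['n']:03d}|{snode.label}"
                return
            for child in snode.children:
                leaves = _leaves_under(child)
                branch = min(l.label for l in leaves)
                n_branch_species = len(leaves)
                arrivals = []
                for g in lineages:
                    stub = Node(length=0.0)
                    g.add(stub)
                    arrivals.extend(along_branch(stub, child.length, branch,
                                                 n_branch_species))
                process(child, arrivals)

        groot = Node(length=0.0)
        process(species_tree.root, [groot])
        pruned = _prune_and_suppress(groot)
        if pruned is None:
            continue
        # a single surviving gene is a valid (1-leaf) family tree
        tree = PhyloTree(pruned, rooted=True)
        species_of = {g: g.rsplit("|", 1)[1] for g in tree.leaf_labels}
        n_dup = sum(e["type"] == "duplication" for e in events)
        n_loss = sum(e["type"] == "loss" for e in events)
        return GeneFamilyTruth(family_id, tree, species_of, events,
                               n_dup, n_loss)
    raise SimulationError(
        f"family {family_id}: every gene was lost in {max_retries} attempts")


def _leaves_under(node: Node) -> list[Node]:
    out = []
    stack = [node]
    while stack:
        x = stack.pop()
        if x.is_leaf:
            out.append(x)
        stack.extend(x.children)
    return out


def true_ortholog_group_count(truth: GeneFamilyTruth) -> int:
    """Ground-truth group count from the event log: d duplications and no
    losses partition the family into d+1 speciation-related groups."""
    if truth.n_loss:
        raise SimulationError(
            "ground-truth group count is only defined for loss-free families")
    return truth.n_dup + 1


# ---------------------------------------------------------------------------
# Sequences
# ---------------------------------------------------------------------------

def sim_sequences(gene_tree: PhyloTree, length: int, states: str = PROTEIN,
                  rng: Optional[np.random.Generator] = None,
                  seed: Optional[int] = None,
                  return_branch_subs: bool = False):
    """Evolve an alignment along the gene tree (equal-rates model, no indels).

    The root sequence is uniform over the alphabet; each branch applies a
    Poisson(branch length) number of substitutions per site, each to a
    uniformly chosen different state.  With ``return_branch_subs`` the
    realized substitution count of every branch is also returned, keyed by
    the frozenset of leaf labels below it.
    """
    if length < 1:
        raise SimulationError("length must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(seed or 0)
    k = len(states)
    state_arr = np.array(list(states))
    rows: dict[str, str] = {}
    branch_subs: dict[frozenset, int] = {}

    def evolve(seq: np.ndarray, bl: float) -> tuple[np.ndarray, int]:
        out = seq.copy()
        hits = rng.poisson(max(bl, 0.0), size=length)
        for i in np.nonzero(hits)[0]:
            for _ in range(int(hits[i])):
                out[i] = (out[i] + 1 + rng.integers(k - 1)) % k
        return out, int(hits.sum())

    def walk(node: Node, seq: np.ndarray) -> frozenset:
        if node.is_leaf:
            rows[node.label] = "".join(state_arr[seq])
            return frozenset([node.label])
        below: frozenset = frozenset()
        for c in node.children:
            child_seq, nsub = evolve(seq, c.length or 0.0)
            leaves = walk(c, child_seq)
            branch_subs[leaves] = nsub
            below |= leaves
        return below

    root_seq = rng.integers(k, size=length)
    walk(gene_tree.root, root_seq)
    matrix = CharacterMatrix.from_dict(rows)
    if return_branch_subs:
        return matrix, branch_subs
    return matrix


# ---------------------------------------------------------------------------
# EST-style incomplete sampling
# ---------------------------------------------------------------------------

def sim_est_sampling(matrix: CharacterMatrix, missingness: float,
                     rng: Optional[np.random.Generator] = None,
                     seed: Optional[int] = None) -> CharacterMatrix:
    """Independently blank each (taxon, partition) block with the given
    probability, emulating per-gene EST absence."""
    if not 0 <= missingness < 1:
        raise SimulationError("missingness must be in [0, 1)")
    rng = rng if rng is not None else np.random.default_rng(seed or 0)
    data = matrix.data.copy()
    for name in matrix.partitions:
        idx = matrix.partitions[name]
        for ti in range(matrix.n_taxa):
            if rng.random() < missingness:
                data[ti, idx] = MISSING
    return CharacterMatrix(matrix.taxa, data,
                           {k: v for k, v in matrix.partitions.items()})


# ---------------------------------------------------------------------------
# Annotations with a planted enrichment
# ---------------------------------------------------------------------------

def sim_annotations(partitions: Sequence[tuple[str, bool]],
                    config: SimConfig,
                    rng: Optional[np.random.Generator] = None):
    """Assign terms: the planted term to congruent partitions with
    probability ``planted_fraction``; every background term to every
    partition with probability ``background_term_freq``."""
    from .enrichment import AnnotationMap
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    bg_terms = [f"T{j:02d}" for j in range(1, config.n_background_terms + 1)]
    terms_of: dict[str, frozenset] = {}
    for part, congruent in partitions:
        terms = set()
        if congruent and rng.random() < config.planted_fraction:
            terms.add(config.planted_term)
        for t in bg_terms:
            if rng.random() < config.background_term_freq:
                terms.add(t)
        if terms:
            terms_of[part] = frozenset(terms)
    return AnnotationMap(terms_of)


# ---------------------------------------------------------------------------
# Target clade and positive-PBS profile (for power analyses)
# ---------------------------------------------------------------------------

def choose_target_clade(species_tree: PhyloTree) -> tuple[Bipartition, frozenset]:
    """A mid-depth rooted clade: size closest to half the taxa (ties:
    lexicographically smallest species list), preferring clades whose stem
    is a single internal branch (parent below the root) so that support for
    the node traces to change on one well-defined branch."""
    taxa = set(species_tree.leaf_labels)
    n = len(taxa)
    best = None
    for node in species_tree.postorder():
        if node.is_leaf or node.parent is None:
            continue
        side = frozenset(l.label for l in _leaves_under(node))
        if not 2 <= len(side) <= n - 2:
            continue
        root_child = node.parent is species_tree.root
        key = (root_child, abs(len(side) - n / 2), tuple(sorted(side)))
        if best is None or key < best[0]:
            best = (key, side)
    if best is None:
        raise SimulationError("species tree has no nontrivial clade")
    side = best[1]
    return Bipartition.of(side, taxa - side), side


def sim_positive_profile(species_tree: PhyloTree,
                         flags: Sequence[tuple[str, bool]],
                         target: Bipartition,
                         rng: np.random.Generator,
                         off_target_rate: float = 0.5
                         ) -> tuple[dict[int, list[str]], int]:
    """Simulated positive-PBS membership per node of the species tree.

    Congruent families are positive at the target node; at every other node
    each family is positive independently with ``off_target_rate``.
    Returns (node id -> positive partitions, target node id).
    """
    ids = preorder_node_ids(species_tree)
    target_id = ids[target]
    out: dict[int, list[str]] = {}
    for b, i in ids.items():
        if i == target_id:
            out[i] = [p for p, cong in flags if cong]
        else:
            out[i] = [p for p, _ in flags if rng.random() < off_target_rate]
    return out, target_id


def planted_enrichment_power(config: SimConfig, seed: int,
                             off_target_rate: float = 0.5):
    """One planted-enrichment recovery replicate (no sequence evolution).

    Families are simulated at the event level; duplication/loss-free
    families are the target-congruent ones, receive the planted term with
    ``planted_fraction``, and are the positives at the target node, while
    every other node draws positives at ``off_target_rate``.  Returns
    (enrichment results, target node id, planted term).
    """
    from .enrichment import enrich_positive_lists
    rng = np.random.default_rng(seed)
    st = sim_species_tree(config, rng)
    target, _side = choose_target_clade(st)
    flags = []
    for i in range(1, config.n_families + 1):
        fid = f"fam{i:04d}"
        truth = sim_gene_family(st, config, rng, family_id=fid)
        flags.append((fid, truth.congruent))
    ann = sim_annotations(flags, config, rng)
    profile, target_id = sim_positive_profile(st, flags, target, rng,
                                              off_target_rate)
    results = enrich_positive_lists(profile, ann, "benjamini-hochberg")
    return results, target_id, config.planted_term


# ---------------------------------------------------------------------------
# Whole-corpus simulation
# ---------------------------------------------------------------------------

def _identity(a: str, b: str) -> float:
    pairs = [(x, y) for x, y in zip(a, b)
             if x not in "?-" and y not in "?-"]
    if not pairs:
        return 0.0
    return sum(x == y for x, y in pairs) / len(pairs)


def _evalue_from_identity(identity: float) -> float:
    return 10.0 ** (-min(180, round(150 * identity)))


def _target_stem_info(truth: GeneFamilyTruth, retained: Sequence[str],
                      species_of: dict, target_species: set,
                      branch_subs: dict) -> tuple[bool, int]:
    """(clade sampled & monophyletic?, realized substitutions on its stem)."""
    retained_species = {species_of[g] for g in retained}
    if not target_species <= retained_species:
        return False, 0
    if len(retained_species - target_species) < 2:
        return False, 0
    clade_genes = [g for g in retained if species_of[g] in target_species]
    mrca = truth.gene_tree.mrca(clade_genes)
    leafset = frozenset(l.label for l in _leaves_under(mrca))
    inside_retained = leafset & set(retained)
    if any(species_of.get(g, truth.species_of[g]) not in target_species
           for g in inside_retained):
        return False, 0
    all_leaves = frozenset(truth.gene_tree.leaf_labels)
    if leafset == all_leaves:  # clade spans the whole tree: no stem branch
        return False, 0
    # on the unrooted view a root-adjacent clade's branch is the fusion of
    # both root edges, so realized change on either side counts
    stem = branch_subs.get(leafset, 0)
    if truth.gene_tree.mrca(leafset).parent is truth.gene_tree.root:
        stem += branch_subs.get(all_leaves - leafset, 0)
    return True, stem


def _supports_target(truth: GeneFamilyTruth, retained: Sequence[str],
                     species_of: dict, target_species: set,
                     branch_subs: dict, config: SimConfig) -> bool:
    """The simulator's own congruence flag for one family.

    A family genuinely supports the target node when (i) every target-clade
    species is sampled, (ii) at least two non-clade species are sampled,
    (iii) the sampled clade genes are monophyletic in the true gene tree,
    and (iv) the branch subtending them accumulated at least
    ``target_stem_min_subs`` realized substitutions — without change on the
    stem a gene carries no signal for the node.
    """
    ok, stem = _target_stem_info(truth, retained, species_of,
                                 target_species, branch_subs)
    return ok and stem >= config.target_stem_min_subs


@dataclass
class SimulatedDataset:
    config: SimConfig
    species_tree: PhyloTree
    target_clade: Bipartition
    target_side: frozenset
    families: list[GeneFamily]
    truths: dict[str, GeneFamilyTruth]
    hits: pd.DataFrame
    annotations: "object"          # AnnotationMap
    genus_map: dict[str, str]
    flags: list[tuple[str, bool]] = field(default_factory=list)
    stem_subs: dict[str, Optional[int]] = field(default_factory=dict)

    @property
    def est_genes(self) -> list[str]:
        genomes = set(self.config.genome_species)
        return [g for fam in self.families for g in fam.alignment.taxa
                if fam.species_of[g] not in genomes]


def simulate_dataset(config: SimConfig,
                     outdir: Optional[Path] = None) -> SimulatedDataset:
    """Generate the full synthetic corpus (optionally writing it to disk).

    Outputs mirror the formats the pipeline reads: per-family aligned FASTA
    with ``geneid|speciesid`` headers, rooted Newick guide trees over the
    designated genome species, a TSV hit table with synthetic E-values
    monotone in identity, an annotation TSV, and a ground-truth JSON.
    """
    rng = np.random.default_rng(config.seed)
    species_tree = sim_species_tree(config, rng)
    target, target_side = choose_target_clade(species_tree)
    # the target clade sits on a deliberately short stem (a rapid
    # radiation): only a minority of families pick up change there, and
    # those are the ones the planted term tracks
    stem_node = species_tree.mrca(target_side)
    stem_node.length = (stem_node.length or 0.0) * config.target_stem_scale
    genomes = set(config.genome_species)

    families: list[GeneFamily] = []
    truths: dict[str, GeneFamilyTruth] = {}
    hit_rows: list[dict] = []
    flags: list[tuple[str, bool]] = []
    stem_subs: dict[str, Optional[int]] = {}

    for i in range(1, config.n_families + 1):
        fid = f"fam{i:04d}"
        truth = sim_gene_family(species_tree, config, rng, family_id=fid)
        aln_full, branch_subs = sim_sequences(
            truth.gene_tree, config.partition_length, config.states, rng,
            return_branch_subs=True)
        # EST-style incomplete sampling: each non-genome gene is simply
        # never sequenced with probability est_missingness
        retained = [g for g in aln_full.taxa
                    if truth.species_of[g] in genomes
                    or rng.random() >= config.est_missingness]
        aln = aln_full.subset_taxa(retained)
        species_of = {g: truth.species_of[g] for g in retained}
        guide = restrict_to_leaves(
            truth.gene_tree,
            [g for g in retained if species_of[g] in genomes])
        families.append(GeneFamily(fid, aln, species_of, guide))
        truths[fid] = truth
        ok, stem = _target_stem_info(truth, retained, species_of,
                                     set(target_side), branch_subs)
        stem_subs[fid] = stem if ok else None
        flags.append((fid, ok and stem >= config.target_stem_min_subs))

    # hit table: each EST against its own family's guide members, plus two
    # decoy families for realism
    fam_by_id = {f.family_id: f for f in families}
    fam_ids = [f.family_id for f in families]
    for fam in families:
        guide_members = (list(fam.guide_tree.leaf_labels)
                         if fam.guide_tree is not None else [])
        for gene in fam.alignment.taxa:
            if fam.species_of[gene] in genomes:
                continue
            if guide_members:
                ident = max(_identity(fam.alignment.sequence(gene),
                                      fam.alignment.sequence(m))
                            for m in guide_members)
                hit_rows.append({"query": gene, "family": fam.family_id,
                                 "evalue": _evalue_from_identity(ident)})
            for _ in range(2):
                other = fam_ids[int(rng.integers(len(fam_ids)))]
                if other == fam.family_id:
                    continue
                om = fam_by_id[other]
                member = om.alignment.taxa[
                    int(rng.integers(len(om.alignment.taxa)))]
                ident = _identity(fam.alignment.sequence(gene),
                                  om.alignment.sequence(member))
                hit_rows.append({"query": gene, "family": other,
                                 "evalue": _evalue_from_identity(ident)})
    hits = pd.DataFrame(hit_rows, columns=["query", "family", "evalue"])
    annotations = sim_annotations(flags, config, rng)

    ds = SimulatedDataset(config, species_tree, target, target_side,
                          families, truths, hits, annotations,
                          config.genus_map, flags, stem_subs)
    if outdir is not None:
        _write_dataset(ds, Path(outdir))
    return ds


def _write_dataset(ds: SimulatedDataset, outdir: Path) -> None:
    fam_dir = outdir / "families"
    guide_dir = outdir / "guide_trees"
    fam_dir.mkdir(parents=True, exist_ok=True)
    guide_dir.mkdir(parents=True, exist_ok=True)
    for fam in ds.families:
        write_fasta({g: fam.alignment.sequence(g) for g in fam.alignment.taxa},
                    fam_dir / f"{fam.family_id}.fasta")
        if fam.guide_tree is not None:
            (guide_dir / f"{fam.family_id}.nwk").write_text(
                fam.guide_tree.newick() + "\n")
    ds.hits.to_csv(outdir / "hits.tsv", sep="\t", index=False)
    ds.annotations.write_tsv(outdir / "annotations.tsv")
    (outdir / "species_tree.nwk").write_text(ds.species_tree.newick() + "\n")
    pd.DataFrame([{"species_id": sp, "genus_id": g}
                  for sp, g in sorted(ds.genus_map.items())]).to_csv(
        outdir / "genus_map.tsv", sep="\t", index=False)
    truth = {
        "seed": ds.config.seed,
        "config": asdict(ds.config),
        "species_tree": ds.species_tree.newick(),
        "target_clade": sorted(ds.target_side),
        "planted_term": ds.config.planted_term,
        "families": {
            fid: {"n_dup": t.n_dup, "n_loss": t.n_loss,
                  "congruent": t.congruent,
                  "supports_target": flag,
                  "target_stem_subs": ds.stem_subs.get(fid),
                  "n_genes": t.gene_tree.n_leaves}
            for (fid, t), (_, flag) in zip(ds.truths.items(), ds.flags)},
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=1))
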