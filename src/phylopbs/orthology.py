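"""Tree-based ortholog delimitation from gene-family trees.

The pipeline mirrors an extended OrthologID workflow: EST sequences are
assigned to gene families by best similarity hit (E-value at or below a
cutoff), sorted by decreasing similarity, inserted one at a time into a
fixed guide tree at the most parsimonious attachment branch, and the
resulting gene-family tree is decomposed into the largest non-overlapping
ortholog sets by walking from the leaves toward the root until the species
sets of two descendant lineages overlap (a duplication).  Within-species
(co-ortholog) clades are first collapsed so that in-paralog pairs stay with
their orthologous partners; downstream, one co-ortholog per species is
sampled at random for the supermatrix.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .matrix import CharacterMatrix
from .parsimony import SearchConfig, fitch_length, search_mp
from .trees import Node, PhyloTree, TreeError, graph_to_tree, tree_to_graph


class OrthologyError(ValueError):
    """Invalid orthology input."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class GeneFamily:
    """A gene family: aligned member sequences plus an optional guide tree."""
    family_id: str
    alignment: CharacterMatrix              # rows keyed by gene id
    species_of: dict[str, str]              # gene id -> species id
    guide_tree: Optional[PhyloTree] = None

    def __post_init__(self):
        genes = set(self.alignment.taxa)
        missing = genes - set(self.species_of)
        if missing:
            raise OrthologyError(
                f"family {self.family_id}: no species for genes "
                f"{sorted(missing)[:5]}")
        if self.guide_tree is not None:
            extra = set(self.guide_tree.leaf_labels) - genes
            if extra:
                raise OrthologyError(
                    f"family {self.family_id}: guide-tree leaves not in "
                    f"alignment: {sorted(extra)[:5]}")


@dataclass(frozen=True)
class OrthologSet:
    """Genes related purely by speciation (per the gene-tree decomposition)."""
    set_id: str
    family_id: str
    genes: frozenset
    species_of: Mapping[str, str]

    def __post_init__(self):
        if not self.genes:
            raise OrthologyError("empty ortholog set")

    @property
    def species_counts(self) -> Counter:
        return Counter(self.species_of[g] for g in self.genes)

    @property
    def species(self) -> frozenset:
        return frozenset(self.species_counts)


# ---------------------------------------------------------------------------
# Family assignment from similarity hit tables
# ---------------------------------------------------------------------------

def read_hit_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"query", "family", "evalue"}
    if not need <= set(df.columns):
        raise OrthologyError(
            f"hit table must have columns {sorted(need)}; got "
            f"{list(df.columns)}")
    if (df["evalue"] <= 0).any():
        raise OrthologyError("E-values must be positive")
    return df


@dataclass
class FamilyAssignment:
    assigned: dict[str, str]
    unassigned: list[str]
    ties: list[str]


def assign_families(hits: pd.DataFrame,
                    cutoff: float = 1e-20) -> FamilyAssignment:
    """Map each query to the family of its best hit at or below the cutoff.

    Ties at identical best E-value resolve to the lexicographically smaller
    family id (and are reported).  Queries with no qualifying hit come back
    in ``unassigned``; that is a normal outcome, not an error.
    """
    if cutoff <= 0:
        raise OrthologyError("cutoff must be positive")
    assigned: dict[str, str] = {}
    unassigned: list[str] = []
    ties: list[str] = []
    for query, grp in hits.groupby("query", sort=True):
        ok = grp[grp["evalue"] <= cutoff]
        if ok.empty:
            unassigned.append(query)
            continue
        best = ok["evalue"].min()
        fams = sorted(ok.loc[ok["evalue"] == best, "family"])
        if len(fams) > 1:
            ties.append(query)
        assigned[query] = fams[0]
    return FamilyAssignment(assigned, unassigned, ties)


def order_ests(family: GeneFamily, hits: pd.DataFrame,
               ests: Optional[Sequence[str]] = None) -> list[str]:
    """ESTs of this family, most similar first (ascending best E-value).

    Ties break lexicographically by gene id.  Sorting happens once, up
    front, before any insertion.
    """
    fam_hits = hits[hits["family"] == family.family_id]
    best = fam_hits.groupby("query")["evalue"].min()
    if ests is None:
        ests = sorted(best.index)
    else:
        missing = [e for e in ests if e not in best.index]
        if missing:
            raise OrthologyError(
                f"ESTs without a hit to family {family.family_id}: {missing}")
    return sorted(ests, key=lambda e: (best[e], e))


# ---------------------------------------------------------------------------
# Most-parsimonious EST placement into a fixed guide tree
# ---------------------------------------------------------------------------

def place_est(tree: PhyloTree, matrix: CharacterMatrix,
              est: str) -> tuple[PhyloTree, int]:
    """Attach ``est`` on the branch minimizing the augmented tree's length.

    Existing leaves are never rearranged.  Candidate branches are scanned in
    preorder and the first minimal attachment wins, so placement is
    deterministic.  Returns (augmented tree, its Fitch length).
    """
    if matrix.is_missing_row(est):
        raise OrthologyError(f"EST {est!r} has an all-missing row")
    if est in tree.leaf_labels:
        raise OrthologyError(f"{est!r} is already a leaf of the tree")
    best_tree = None
    best_score = None
    base = tree.copy()
    targets = [n for n in base.preorder() if n.parent is not None]
    for target in targets:
        parent = target.parent
        pos = parent.children.index(target)
        joint = Node()
        joint.add(target)
        joint.add(Node(est))
        parent.children[pos] = joint
        joint.parent = parent
        cand = PhyloTree(base.root, rooted=tree.rooted)
        score = fitch_length(cand, matrix)
        if best_score is None or score < best_score:
            best_score = score
            best_tree = cand.copy()
        # undo the insertion
        parent.children[pos] = target
        target.parent = parent
    if best_tree is None:
        raise OrthologyError("tree has no insertion branch")
    return best_tree, int(best_score)


def insert_all_ests(family: GeneFamily, ordered_ests: Sequence[str]
                    ) -> tuple[PhyloTree, list[int]]:
    """Insert ESTs one at a time (in the given order) into the guide tree."""
    if family.guide_tree is None:
        raise OrthologyError(f"family {family.family_id} has no guide tree")
    tree = family.guide_tree.copy()
    scores = []
    for est in ordered_ests:
        tree, score = place_est(tree, family.alignment, est)
        scores.append(score)
    return tree, scores


# ---------------------------------------------------------------------------
# Ortholog-set extraction (duplication-aware decomposition)
# ---------------------------------------------------------------------------

def extract_ortholog_sets(gene_tree: PhyloTree,
                          species_of: Mapping[str, str],
                          family_id: str = "",
                          emit_both: bool = False) -> list[OrthologSet]:
    """Decompose a rooted gene-family tree into disjoint ortholog sets.

    Moving from the leaves toward the root, gene sets merge while the
    species sets of sibling lineages stay disjoint.  Where they overlap (a
    duplication), the lineage with fewer distinct species (ties: fewer
    genes, then the lexicographically greater gene list) is emitted as a
    finalized set and the other continues upward, so the surviving set is as
    large as possible.  Maximal single-species clades are first collapsed so
    that within-species co-ortholog groups travel together.  With
    ``emit_both`` the simpler variant emits both lineages at a duplication
    and propagates nothing.
    """
    if not gene_tree.rooted:
        raise OrthologyError(
            "gene tree is unrooted; root it (e.g. from the guide tree) "
            "before extracting ortholog sets")
    for leaf in gene_tree.leaf_labels:
        if leaf not in species_of:
            raise OrthologyError(f"no species mapping for gene {leaf!r}")

    emitted: list[frozenset] = []

    def species(genes: frozenset) -> frozenset:
        return frozenset(species_of[g] for g in genes)

    def walk(node) -> frozenset:
        if node.is_leaf:
            return frozenset([node.label])
        parts = sorted((walk(c) for c in node.children),
                       key=lambda s: min(s) if s else "")
        parts = [p for p in parts if p]
        if not parts:
            return frozenset()
        union = frozenset().union(*parts)
        if len(species(union)) == 1:
            return union           # single-species (co-ortholog) clade
        acc = parts[0]
        for nxt in parts[1:]:
            if not (species(acc) & species(nxt)):
                acc |= nxt
                continue
            if emit_both:
                emitted.extend([acc, nxt])
                acc = frozenset()
                continue
            # duplication: emit the smaller lineage, keep growing the larger
            ka = (len(species(acc)), len(acc))
            kb = (len(species(nxt)), len(nxt))
            if ka != kb:
                emit, keep = (acc, nxt) if ka < kb else (nxt, acc)
            else:  # full tie: emit the lexicographically greater gene list
                if tuple(sorted(acc)) > tuple(sorted(nxt)):
                    emit, keep = acc, nxt
                else:
                    emit, keep = nxt, acc
            emitted.append(emit)
            acc = keep
        return acc

    survivor = walk(gene_tree.root)
    if survivor:
        emitted.append(survivor)
    sets = [OrthologSet(f"{family_id}.set{i + 1}" if family_id else f"set{i + 1}",
                        family_id, genes,
                        {g: species_of[g] for g in genes})
            for i, genes in enumerate(emitted)]
    return sets


def sample_co_orthologs(oset: OrthologSet, seed: int) -> OrthologSet:
    """Keep one uniformly random gene per species (deterministic per seed)."""
    rng = np.random.default_rng(seed)
    keep = []
    by_species: dict[str, list[str]] = {}
    for g in sorted(oset.genes):
        by_species.setdefault(oset.species_of[g], []).append(g)
    for sp in sorted(by_species):
        genes = by_species[sp]
        keep.append(genes[int(rng.integers(len(genes)))]
                    if len(genes) > 1 else genes[0])
    return OrthologSet(oset.set_id, oset.family_id, frozenset(keep),
                       {g: oset.species_of[g] for g in keep})


# ---------------------------------------------------------------------------
# Guide-tree conveniences
# ---------------------------------------------------------------------------

def root_at_center(tree: PhyloTree) -> PhyloTree:
    """Root an unrooted tree at the topological center (longest-path midpoint)."""
    adj, leaf_of = tree_to_graph(tree)

    def bfs(src):
        dist = {src: 0}
        order = [src]
        for u in order:
            for v in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    order.append(v)
        far = max(dist, key=lambda k: (dist[k], k))
        return far, dist

    a, _ = bfs(min(adj))
    b, da = bfs(a)
    # walk back from b to a collecting the path
    _, db = bfs(b)
    path = [u for u in adj if da[u] + db[u] == da[b]]
    path.sort(key=lambda u: da[u])
    center = path[len(path) // 2]

    def build(i, parent):
        node = Node(leaf_of.get(i))
        for j in sorted(adj[i]):
            if j != parent:
                node.add(build(j, i))
        return node

    return PhyloTree(build(center, None), rooted=True)


def build_guide_tree(alignment: CharacterMatrix,
                     config: Optional[SearchConfig] = None) -> PhyloTree:
    """Build a rooted guide tree de novo by parsimony search on the family."""
    res = search_mp(alignment, config)
    return root_at_center(res.trees[0])


# ---------------------------------------------------------------------------
# TSV output
# ---------------------------------------------------------------------------

def write_ortholog_sets(osets: Sequence[OrthologSet], path) -> None:
    rows = [{"set_id": o.set_id, "gene_id": g,
             "species_id": o.species_of[g], "family_id": o.family_id}
            for o in osets for g in sorted(o.genes)]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
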