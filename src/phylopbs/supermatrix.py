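"""Partitioned supermatrix assembly and filtering.

Each surviving ortholog set becomes one gene partition of a concatenated
taxa x characters matrix, with ``?`` filling species absent from a
partition.  Filters: a minimum-taxon threshold per partition (the classic
"at least four taxa" rule) and an inclusive taxon-representation fraction
(the "at least 30% / 10% representation" submatrices).  Congeneric species
can be collapsed to genus-level taxa, represented per partition by the most
ancestral congener on a reference tree.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .matrix import (CharacterMatrix, MatrixError, MISSING, concat_matrices,
                     write_nexus)
from .orthology import OrthologSet
from .trees import PhyloTree, TreeError


class SupermatrixError(ValueError):
    """Invalid supermatrix operation."""


@dataclass
class PartitionedSupermatrix:
    """A CharacterMatrix plus per-partition provenance and representation."""
    matrix: CharacterMatrix
    provenance: pd.DataFrame   # partition, family, set_id, n_taxa, representation

    @property
    def taxa(self) -> list[str]:
        return self.matrix.taxa

    @property
    def partition_names(self) -> list[str]:
        return list(self.matrix.partitions)

    def representation(self, partition: str) -> float:
        row = self.provenance[self.provenance["partition"] == partition]
        return float(row["representation"].iloc[0])

    def recompute_provenance(self) -> None:
        rows = []
        total = self.matrix.n_taxa
        old = self.provenance.set_index("partition")
        for name, idx in self.matrix.partitions.items():
            present = self.matrix.present_taxa(idx)
            rows.append({
                "partition": name,
                "family": old.loc[name, "family"] if name in old.index else "",
                "set_id": old.loc[name, "set_id"] if name in old.index else "",
                "n_taxa": len(present),
                "representation": len(present) / total if total else 0.0,
            })
        self.provenance = pd.DataFrame(rows)

    def write(self, nexus_path=None, provenance_path=None,
              datatype: str = "protein") -> None:
        if nexus_path is not None:
            write_nexus(self.matrix, nexus_path, datatype=datatype)
        if provenance_path is not None:
            self.provenance.to_csv(provenance_path, sep="\t", index=False)


def build_supermatrix(osets: Sequence[OrthologSet],
                      alignments: Mapping[str, CharacterMatrix],
                      min_taxa: int = 4,
                      taxa: Optional[Sequence[str]] = None
                      ) -> PartitionedSupermatrix:
    """Concatenate sampled ortholog sets into one partitioned matrix.

    ``alignments`` maps family id -> aligned matrix over gene ids.  Ortholog
    sets must already be sampled to at most one gene per species; partitions
    with fewer than ``min_taxa`` represented species are excluded.
    """
    if min_taxa < 3:
        raise SupermatrixError("min_taxa must be >= 3")
    blocks = []
    prov = []
    for oset in osets:
        counts = oset.species_counts
        dup = [sp for sp, c in counts.items() if c > 1]
        if dup:
            raise SupermatrixError(
                f"ortholog set {oset.set_id} has multiple genes for species "
                f"{sorted(dup)}; apply co-ortholog sampling first")
        fam = alignments.get(oset.family_id)
        if fam is None:
            raise SupermatrixError(
                f"no alignment for family {oset.family_id!r}")
        genes = sorted(oset.genes)
        rows = {}
        for g in genes:
            if g not in fam.taxa:
                raise SupermatrixError(
                    f"gene {g!r} missing from alignment of family "
                    f"{oset.family_id!r}")
            rows[oset.species_of[g]] = fam.sequence(g)
        block = CharacterMatrix.from_dict(rows)
        present = block.present_taxa()
        if len(present) < min_taxa:
            continue
        blocks.append((oset.set_id, block))
        prov.append({"partition": oset.set_id, "family": oset.family_id,
                     "set_id": oset.set_id, "n_taxa": len(present)})
    if not blocks:
        raise SupermatrixError(
            f"no ortholog set passes the {min_taxa}-taxon filter")
    if taxa is None:
        taxa = sorted({t for _, b in blocks for t in b.taxa})
    matrix = concat_matrices(blocks, list(taxa))
    prov_df = pd.DataFrame(prov)
    prov_df["representation"] = prov_df["n_taxa"] / len(taxa)
    sm = PartitionedSupermatrix(matrix, prov_df)
    sm.recompute_provenance()
    return sm


def filter_min_taxa(sm: PartitionedSupermatrix,
                    min_taxa: int = 4) -> PartitionedSupermatrix:
    """Drop partitions represented by fewer than ``min_taxa`` taxa."""
    keep = [name for name, idx in sm.matrix.partitions.items()
            if len(sm.matrix.present_taxa(idx)) >= min_taxa]
    return _subset_partitions(sm, keep, f"min_taxa={min_taxa}")


def filter_by_representation(sm: PartitionedSupermatrix,
                             min_fraction: float) -> PartitionedSupermatrix:
    """Keep partitions with representation >= ``min_fraction`` (inclusive).

    Representation is the exact rational fraction of matrix taxa with at
    least one non-missing character in the partition.  Taxa left without any
    characters are dropped (and recorded in the provenance recompute).
    """
    if not 0 < min_fraction <= 1:
        raise SupermatrixError("min_fraction must be in (0, 1]")
    total = sm.matrix.n_taxa
    keep = [name for name, idx in sm.matrix.partitions.items()
            if len(sm.matrix.present_taxa(idx)) >= min_fraction * total
            or np.isclose(len(sm.matrix.present_taxa(idx)),
                          min_fraction * total)]
    return _subset_partitions(sm, keep, f"representation>={min_fraction}")


def _subset_partitions(sm: PartitionedSupermatrix, keep: Sequence[str],
                       why: str) -> PartitionedSupermatrix:
    if not keep:
        raise SupermatrixError(f"filter ({why}) removed every partition")
    cols = []
    partitions = {}
    at = 0
    for name in keep:
        idx = np.sort(sm.matrix.partitions[name])
        cols.append(idx)
        partitions[name] = range(at, at + len(idx))
        at += len(idx)
    data = sm.matrix.data[:, np.concatenate(cols)]
    matrix = CharacterMatrix(sm.taxa, data, partitions)
    # drop taxa with no characters left
    alive = [t for t in matrix.taxa if not matrix.is_missing_row(t)]
    if len(alive) < len(matrix.taxa):
        idx = [matrix.taxa.index(t) for t in alive]
        matrix = CharacterMatrix(alive, matrix.data[idx], partitions)
    out = PartitionedSupermatrix(matrix, sm.provenance)
    out.recompute_provenance()
    return out


# ---------------------------------------------------------------------------
# Genus collapse
# ---------------------------------------------------------------------------

def _genus_rank(reference_tree: PhyloTree, species: Sequence[str]
                ) -> dict[str, int]:
    """Edges from the root of the smallest clade containing the genus to
    each congener's attachment; fewer edges = more ancestral."""
    clade = reference_tree.mrca(species)
    depth = {}

    def walk(node, d):
        if node.is_leaf:
            if node.label in species:
                depth[node.label] = d
            return
        for c in node.children:
            walk(c, d + 1)

    walk(clade, 0)
    return depth


def collapse_genus(sm: PartitionedSupermatrix,
                   gmap: Mapping[str, str],
                   reference_tree: PhyloTree) -> PartitionedSupermatrix:
    """Collapse congeneric species into one genus-level taxon per genus.

    For every partition the representative is the most ancestral congener on
    the reference tree (fewest edges below the genus clade's root; ties go
    to the species with more non-missing characters in that partition, then
    lexicographic), falling back to the next-ranked congener where the
    chosen species lacks the gene.
    """
    for sp in sm.taxa:
        if sp not in gmap:
            raise SupermatrixError(f"species {sp!r} missing from the genus map")
        if sp not in reference_tree.leaf_labels:
            raise SupermatrixError(
                f"species {sp!r} absent from the reference tree")
    genera: dict[str, list[str]] = {}
    for sp in sm.taxa:
        genera.setdefault(gmap[sp], []).append(sp)
    base_depth = {}
    for genus, members in genera.items():
        if len(members) == 1:
            base_depth[genus] = {members[0]: 0}
        else:
            base_depth[genus] = _genus_rank(reference_tree, members)

    names = sorted(genera)
    data = np.full((len(names), sm.matrix.n_columns), MISSING, dtype="<U1")
    for gi, genus in enumerate(names):
        members = genera[genus]
        for pname, idx in sm.matrix.partitions.items():
            idx = np.asarray(idx)
            nonmiss = {sp: int((~np.isin(sm.matrix.row(sp)[idx],
                                         [MISSING, "-"])).sum())
                       for sp in members}
            ranked = sorted(members,
                            key=lambda s: (base_depth[genus].get(s, 10 ** 9),
                                           -nonmiss[s], s))
            for sp in ranked:
                if nonmiss[sp] > 0:
                    data[gi, idx] = sm.matrix.row(sp)[idx]
                    break
    matrix = CharacterMatrix(names, data, dict(sm.matrix.partitions))
    out = PartitionedSupermatrix(matrix, sm.provenance)
    out.recompute_provenance()
    return out
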