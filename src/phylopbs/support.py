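"""Branch support on the simultaneous-analysis (combined-matrix) tree:
bootstrap proportions, Bremer support, and Partitioned Bremer Support (PBS).

A "node" is a nontrivial bipartition of the unrooted best tree.  For a
bipartition *b* and gene partition *p*,

    PBS(b, p) = steps_p(shortest trees lacking b)
              - steps_p(shortest trees containing b)

Both constrained optima may be tied.  The decomposition of Bremer support
across partitions is not unique under ties, so three tie strategies are
offered:

* ``single`` (default): partition lengths are read off one deterministic
  (lexicographically canonical) optimum per constrained search.  PBS stays
  integral and the identity  sum_p PBS(b, p) == Bremer(b)  holds exactly.
* ``min``: the minimum partition length across all tied optima (the literal
  reading of the classical definition); the sum identity can fail under ties.
* ``average``: TreeRot-style mean across tied optima; identity holds exactly
  but PBS values may be fractional.

Searches are exhaustive (and the reported values provably exact) up to the
configured taxon cap; heuristic above it, flagged per node.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .matrix import CharacterMatrix
from .parsimony import (SearchConfig, SearchError, bipartition_to_mask,
                        exhaustive_partition_table, fitch_length, search_mp,
                        search_mp_constrained)
from .trees import (Bipartition, PhyloTree, TreeError, nested_canonical,
                    strict_consensus_splits)

TIE_STRATEGIES = ("single", "min", "average")


def _as_matrix(sm) -> CharacterMatrix:
    return sm.matrix if hasattr(sm, "matrix") else sm


def preorder_node_ids(best_tree: PhyloTree) -> dict[Bipartition, int]:
    """Number the nontrivial bipartitions 1..k by preorder on the best tree."""
    all_taxa = set(best_tree.leaf_labels)
    n = len(all_taxa)
    below: dict[int, frozenset] = {}
    for node in best_tree.postorder():
        if node.is_leaf:
            below[id(node)] = frozenset([node.label])
        else:
            below[id(node)] = frozenset().union(
                *(below[id(c)] for c in node.children))
    ids: dict[Bipartition, int] = {}
    k = 0
    for node in best_tree.preorder():
        if node.is_leaf or node.parent is None:
            continue
        side = below[id(node)]
        if 2 <= len(side) <= n - 2:
            b = Bipartition.of(side, all_taxa - side)
            if b not in ids:
                k += 1
                ids[b] = k
    return ids


@dataclass
class SupportTable:
    """Per-(node, partition) PBS plus per-node Bremer/bootstrap summaries."""
    best_tree: PhyloTree
    best_score: int
    node_ids: dict[Bipartition, int]
    pbs: pd.DataFrame        # node_id, bipartition, partition, pbs
    nodes: pd.DataFrame      # node_id, bipartition, bremer, bootstrap_pct,
                             # n_positive_partitions, exact
    tie_strategy: str

    @property
    def partitions(self) -> list[str]:
        return sorted(self.pbs["partition"].unique())

    def node_by_id(self, node_id: int) -> Bipartition:
        for b, i in self.node_ids.items():
            if i == node_id:
                return b
        raise KeyError(node_id)

    def pbs_value(self, node: Bipartition, partition: str) -> float:
        i = self.node_ids[node]
        sel = self.pbs[(self.pbs["node_id"] == i)
                       & (self.pbs["partition"] == partition)]
        return sel["pbs"].iloc[0]

    def bremer(self, node: Bipartition) -> float:
        i = self.node_ids[node]
        return self.nodes.loc[self.nodes["node_id"] == i, "bremer"].iloc[0]

    def write_tsv(self, pbs_path, nodes_path) -> None:
        self.pbs.to_csv(pbs_path, sep="\t", index=False)
        self.nodes.to_csv(nodes_path, sep="\t", index=False)


def load_support_table(pbs_path, nodes_path, best_tree: PhyloTree,
                       best_score: int = 0,
                       tie_strategy: str = "single") -> SupportTable:
    """Rebuild a SupportTable from its two TSV files and the best tree."""
    pbs_df = pd.read_csv(pbs_path, sep="\t")
    nodes_df = pd.read_csv(nodes_path, sep="\t")
    node_ids = {Bipartition.from_string(r["bipartition"]): int(r["node_id"])
                for _, r in nodes_df.iterrows()}
    return SupportTable(best_tree, best_score, node_ids, pbs_df, nodes_df,
                        tie_strategy)


def positive_pbs_partitions(table: SupportTable,
                            node: Bipartition) -> list[str]:
    """Partitions with strictly positive PBS at the node, sorted."""
    if node not in table.node_ids:
        raise TreeError(f"node {node} not in the support table")
    i = table.node_ids[node]
    sel = table.pbs[(table.pbs["node_id"] == i) & (table.pbs["pbs"] > 0)]
    return sorted(sel["partition"])


def bremer_support(sm, best_tree: PhyloTree, node: Bipartition,
                   best_score: int,
                   config: Optional[SearchConfig] = None) -> int:
    """Extra steps of the shortest tree lacking the node (decay index)."""
    if node not in best_tree.bipartitions():
        raise TreeError(f"node {node} is not a branch of the best tree")
    m = _as_matrix(sm)
    res = search_mp_constrained(m, node, "forbid", config,
                                start_trees=[best_tree])
    return int(res.score - best_score)


def _partition_lengths(tree: PhyloTree, m: CharacterMatrix,
                       part_names: Sequence[str]) -> np.ndarray:
    return np.array([fitch_length(tree, m, m.partitions[p])
                     for p in part_names], dtype=float)


def _combine(L: np.ndarray, strategy: str) -> np.ndarray:
    """Collapse tied-optima partition lengths (rows) per strategy."""
    if strategy == "single":
        return L[0]
    if strategy == "min":
        return L.min(axis=0)
    return L.mean(axis=0)


def pbs_table(sm, best_tree: PhyloTree,
              config: Optional[SearchConfig] = None,
              tie_strategy: str = "single",
              bootstrap_pct: Optional[Mapping[Bipartition, float]] = None
              ) -> SupportTable:
    """PBS for every (nontrivial node of the best tree, partition) pair.

    ``best_tree`` must be a most-parsimonious tree of the combined matrix.
    """
    if tie_strategy not in TIE_STRATEGIES:
        raise SearchError(f"tie_strategy must be one of {TIE_STRATEGIES}")
    config = config or SearchConfig()
    m = _as_matrix(sm)
    node_ids = preorder_node_ids(best_tree)
    part_names = sorted(m.partitions)
    n = len(m.taxa)
    exhaustive = n <= config.exhaustive_cap

    pbs_rows = []
    node_rows = []

    if exhaustive:
        tab = exhaustive_partition_table(m, cap=config.exhaustive_cap)
        best_total = int(tab.totals.min())
        score_check = fitch_length(best_tree, m)
        if score_check != best_total:
            raise SearchError(
                f"best_tree (length {score_check}) is not a most-parsimonious "
                f"tree (optimum {best_total})")
        canon_keys = [None] * len(tab.nesteds)

        def canon(i: int) -> str:
            if canon_keys[i] is None:
                canon_keys[i] = str(nested_canonical(tab.nesteds[i]))
            return canon_keys[i]

        for b, node_id in sorted(node_ids.items(), key=lambda kv: kv[1]):
            mask = bipartition_to_mask(b, tab.taxa)
            has = np.array([mask in s for s in tab.splits])
            sF = int(tab.totals[~has].min())
            sR = int(tab.totals[has].min())
            f_idx = sorted(np.nonzero(~has & (tab.totals == sF))[0],
                           key=canon)
            r_idx = sorted(np.nonzero(has & (tab.totals == sR))[0],
                           key=canon)
            f_len = _combine(tab.lengths[f_idx].astype(float), tie_strategy)
            r_len = _combine(tab.lengths[r_idx].astype(float), tie_strategy)
            vals = f_len - r_len
            bremer = sF - sR
            for p, v in zip(tab.part_names, vals):
                pbs_rows.append((node_id, str(b), p, _as_number(v)))
            node_rows.append((node_id, str(b), bremer, True))
        best_score = best_total
    else:
        best_score = fitch_length(best_tree, m)
        for b, node_id in sorted(node_ids.items(), key=lambda kv: kv[1]):
            forbid = search_mp_constrained(m, b, "forbid", config,
                                           start_trees=[best_tree])
            require = search_mp_constrained(m, b, "require", config,
                                            start_trees=[best_tree])
            LF = np.stack([_partition_lengths(t, m, part_names)
                           for t in forbid.trees])
            LR = np.stack([_partition_lengths(t, m, part_names)
                           for t in require.trees])
            vals = _combine(LF, tie_strategy) - _combine(LR, tie_strategy)
            bremer = int(forbid.score - min(require.score, best_score))
            for p, v in zip(part_names, vals):
                pbs_rows.append((node_id, str(b), p, _as_number(v)))
            node_rows.append((node_id, str(b), bremer, False))

    pbs_df = pd.DataFrame(pbs_rows,
                          columns=["node_id", "bipartition", "partition",
                                   "pbs"])
    nodes_df = pd.DataFrame(node_rows,
                            columns=["node_id", "bipartition", "bremer",
                                     "exact"])
    npos = (pbs_df[pbs_df["pbs"] > 0].groupby("node_id").size()
            .reindex(nodes_df["node_id"], fill_value=0).to_numpy())
    nodes_df["n_positive_partitions"] = npos
    if bootstrap_pct is not None:
        by_id = {node_ids[b]: v for b, v in bootstrap_pct.items()
                 if b in node_ids}
        nodes_df["bootstrap_pct"] = [by_id.get(i, np.nan)
                                     for i in nodes_df["node_id"]]
    return SupportTable(best_tree, int(best_score), node_ids, pbs_df,
                        nodes_df, tie_strategy)


def _as_number(v: float):
    return int(v) if float(v).is_integer() else float(v)


def bootstrap_support(sm, reference: PhyloTree, n_reps: int, seed: int,
                      config: Optional[SearchConfig] = None
                      ) -> dict[Bipartition, float]:
    """Nonparametric bootstrap percentages for the reference tree's nodes.

    Whole columns are resampled with replacement across partition
    boundaries; each pseudoreplicate is searched with ``config`` and
    contributes its strict consensus (of tied replicate MPTs) to the counts.
    """
    if n_reps < 1:
        raise SearchError("n_reps must be >= 1")
    config = config or SearchConfig()
    m = _as_matrix(sm)
    rng = np.random.default_rng(seed)
    ref_bips = reference.bipartitions()
    counts = {b: 0 for b in ref_bips}
    ncols = m.n_columns
    for _ in range(n_reps):
        weights = rng.multinomial(ncols, np.full(ncols, 1.0 / ncols))
        res = search_mp(m, config, weights=weights.astype(float))
        present = strict_consensus_splits(res.trees)
        for b in ref_bips:
            if b in present:
                counts[b] += 1
    return {b: 100.0 * c / n_reps for b, c in counts.items()}
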