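"""Per-node overrepresentation of functional terms among positive-PBS genes.

At each node of the best tree, the gene partitions contributing strictly
positive PBS form the study list; the background population is the union of
annotated partitions with positive PBS at one or more nodes.  Each term's
upper-tail hypergeometric probability P(X >= k) is computed exactly, and a
multiple-testing correction (Benjamini-Hochberg by default) is applied
jointly across all (node, term) pairs.  A tier report counts term-node
pairs below a ladder of p-value thresholds.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .support import SupportTable
from .trees import Bipartition

CORRECTIONS = {"benjamini-hochberg": "fdr_bh", "bonferroni": "bonferroni",
               "none": None}


class EnrichmentError(ValueError):
    """Invalid enrichment input."""


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------

@dataclass
class AnnotationMap:
    """Partition id -> set of functional-term ids (plus optional labels)."""
    terms_of: dict[str, frozenset]
    labels: dict[str, str] = field(default_factory=dict)
    parents: dict[str, set] = field(default_factory=dict)

    def __post_init__(self):
        for part, terms in self.terms_of.items():
            if any(not t for t in terms):
                raise EnrichmentError(
                    f"partition {part!r} carries an empty term id")

    def annotated(self, partition: str) -> bool:
        return bool(self.terms_of.get(partition))

    def terms(self, partition: str,
              propagate: bool = False) -> frozenset:
        base = set(self.terms_of.get(partition, frozenset()))
        if propagate and self.parents:
            frontier = list(base)
            while frontier:
                t = frontier.pop()
                for p in self.parents.get(t, ()):
                    if p not in base:
                        base.add(p)
                        frontier.append(p)
        return frozenset(base)

    @classmethod
    def read_tsv(cls, path, hierarchy_path=None) -> "AnnotationMap":
        df = pd.read_csv(path, sep="\t")
        need = {"partition_id", "term_id"}
        if not need <= set(df.columns):
            raise EnrichmentError(
                f"annotation TSV needs columns {sorted(need)}")
        terms_of: dict[str, set] = {}
        labels = {}
        for _, r in df.iterrows():
            terms_of.setdefault(str(r["partition_id"]), set()).add(
                str(r["term_id"]))
            if "term_label" in df.columns and pd.notna(r.get("term_label")):
                labels[str(r["term_id"])] = str(r["term_label"])
        parents: dict[str, set] = {}
        if hierarchy_path is not None:
            h = pd.read_csv(hierarchy_path, sep="\t")
            for _, r in h.iterrows():
                parents.setdefault(str(r["child"]), set()).add(str(r["parent"]))
        return cls({k: frozenset(v) for k, v in terms_of.items()},
                   labels, parents)

    def write_tsv(self, path) -> None:
        rows = [{"partition_id": p, "term_id": t,
                 "term_label": self.labels.get(t, "")}
                for p in sorted(self.terms_of)
                for t in sorted(self.terms_of[p])]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class EnrichmentResult:
    node_id: int
    term: str
    k: int          # positive-PBS genes at node carrying the term
    n: int          # annotated positive-PBS genes at the node
    K: int          # background genes carrying the term
    N: int          # background size
    p: float
    q: float


# ---------------------------------------------------------------------------
# Background and the exact test
# ---------------------------------------------------------------------------

def positive_by_node(table: SupportTable) -> dict[int, list[str]]:
    """Node id -> partitions with strictly positive PBS there."""
    pos = table.pbs[table.pbs["pbs"] > 0]
    out = {int(i): sorted(g["partition"]) for i, g in pos.groupby("node_id")}
    return out


def _background_from_parts(parts_by_node: Mapping[int, Sequence[str]],
                           ann: AnnotationMap, propagate: bool = False
                           ) -> tuple[list[str], dict[str, int]]:
    union: set = set()
    for parts in parts_by_node.values():
        union.update(parts)
    background = sorted(p for p in union if ann.annotated(p))
    if not background:
        raise EnrichmentError(
            "empty background: no annotated partition has positive PBS")
    K: dict[str, int] = {}
    for p in background:
        for t in ann.terms(p, propagate):
            K[t] = K.get(t, 0) + 1
    return background, K


def build_background(table: SupportTable, ann: AnnotationMap,
                     propagate: bool = False
                     ) -> tuple[list[str], dict[str, int]]:
    """Union of annotated positive-PBS partitions, with per-term K counts."""
    if table.pbs.empty:
        raise EnrichmentError("empty support table")
    return _background_from_parts(positive_by_node(table), ann, propagate)


def hypergeom_upper(k: int, K: int, n: int, N: int) -> float:
    """Exact upper tail P(X >= k), X ~ Hypergeometric(N, K, n)."""
    if not (0 <= k <= min(n, K) and k <= n <= N and 0 <= K <= N):
        raise EnrichmentError(
            f"invalid hypergeometric parameters k={k} K={K} n={n} N={N}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def enrich_nodes(table: SupportTable, ann: AnnotationMap,
                 correction: str = "benjamini-hochberg",
                 propagate: bool = False) -> list[EnrichmentResult]:
    """Test every (node, term with k >= 1) pair; correct across all jointly.

    Results are sorted by adjusted then raw p-value.
    """
    return enrich_positive_lists(positive_by_node(table), ann, correction,
                                 propagate)


def enrich_positive_lists(parts_by_node: Mapping[int, Sequence[str]],
                          ann: AnnotationMap,
                          correction: str = "benjamini-hochberg",
                          propagate: bool = False) -> list[EnrichmentResult]:
    """Enrichment from explicit per-node positive-partition lists."""
    if correction not in CORRECTIONS:
        raise EnrichmentError(
            f"correction must be one of {sorted(CORRECTIONS)}")
    background, K = _background_from_parts(parts_by_node, ann, propagate)
    bg = set(background)
    N = len(background)
    raw = []
    for node_id, parts in sorted(parts_by_node.items()):
        study = [p for p in parts if p in bg]
        n = len(study)
        if n == 0:
            continue
        counts: dict[str, int] = {}
        for p in study:
            for t in ann.terms(p, propagate):
                counts[t] = counts.get(t, 0) + 1
        for t in sorted(counts):
            k = counts[t]
            raw.append((node_id, t, k, n, K[t], N,
                        hypergeom_upper(k, K[t], n, N)))
    if not raw:
        return []
    pvals = np.array([r[-1] for r in raw])
    method = CORRECTIONS[correction]
    if method is None:
        qvals = pvals
    else:
        qvals = multipletests(pvals, method=method)[1]
    results = [EnrichmentResult(*r, q=float(q)) for r, q in zip(raw, qvals)]
    results.sort(key=lambda r: (r.q, r.p, r.node_id, r.term))
    return results


def tier_report(results: Sequence[EnrichmentResult],
                thresholds: Sequence[float] = (0.01, 0.05, 0.10),
                use: str = "raw") -> dict[float, int]:
    """Cumulative counts of term-node pairs below each p threshold.

    ``use`` selects raw (``"raw"``) or adjusted (``"adjusted"``) p-values.
    """
    if list(thresholds) != sorted(thresholds):
        raise EnrichmentError("thresholds must be ascending")
    if use not in ("raw", "adjusted"):
        raise EnrichmentError("use must be 'raw' or 'adjusted'")
    vals = [r.p if use == "raw" else r.q for r in results]
    return {float(t): sum(v < t for v in vals) for t in thresholds}


def results_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([{"node": r.node_id, "term": r.term, "k": r.k,
                          "n": r.n, "K": r.K, "N": r.N, "p": r.p, "q": r.q}
                         for r in results])
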