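"""Fitch parsimony scoring and most-parsimonious-tree search.

Characters are unordered multistate symbols (amino-acid or nucleotide
alike); ``?`` is fully ambiguous, and ``-`` is treated as missing by default
(optionally as an extra state).  Columns are encoded as per-taxon state
bitmasks so that the Fitch pass runs vectorized across all columns at once,
with duplicate column patterns collapsed into weights.

Search is exhaustive (stepwise-insertion enumeration of all unrooted binary
topologies, globally optimal) up to a configurable taxon cap, and heuristic
above it: random-addition starting trees followed by NNI/SPR hill-climbing,
with an optional parsimony ratchet.  Constrained searches (require or forbid
a bipartition) support the Bremer / partitioned-Bremer computations.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np

from .matrix import CharacterMatrix, MatrixError, MISSING, GAP
from .trees import (Bipartition, PhyloTree, TreeError, graph_to_tree,
                    iter_nested_topologies, nested_canonical, nested_splits,
                    nested_to_tree, tree_to_graph, tree_to_nested)


class SearchError(ValueError):
    """Invalid search input or configuration."""


# ---------------------------------------------------------------------------
# Encoding
# ---------------------------------------------------------------------------

def encode_columns(matrix: CharacterMatrix, taxa: Sequence[str],
                   columns: Optional[Sequence[int]] = None,
                   gap_as_state: bool = False) -> np.ndarray:
    """Encode selected columns as per-taxon state bitmasks (uint64).

    Rows follow the order of ``taxa``.  ``?`` (and ``-`` unless
    ``gap_as_state``) becomes the fully ambiguous mask.
    """
    for t in taxa:
        if t not in matrix.taxa:
            raise SearchError(f"taxon {t!r} has no row in the matrix")
    sub = np.stack([matrix.row(t) for t in taxa])
    if columns is not None:
        sub = sub[:, np.asarray(list(columns), dtype=int)]
    missing_symbols = {MISSING} if gap_as_state else {MISSING, GAP}
    observed = sorted(set(sub.ravel().tolist()) - {MISSING, GAP}
                      | ({GAP} if gap_as_state else set()))
    if len(observed) > 63:
        raise SearchError(f"alphabet too large ({len(observed)} states)")
    full = np.uint64((1 << max(len(observed), 1)) - 1)
    lut = {s: np.uint64(1 << i) for i, s in enumerate(observed)}
    for s in missing_symbols:
        lut[s] = full
    codes = np.empty(sub.shape, dtype=np.uint64)
    for s in set(sub.ravel().tolist()):
        codes[sub == s] = lut[s]
    return codes


def compress_columns(codes: np.ndarray,
                     weights: Optional[np.ndarray] = None
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Collapse duplicate column patterns; returns (unique codes, weights)."""
    if weights is None:
        weights = np.ones(codes.shape[1], dtype=float)
    uniq, inverse = np.unique(codes, axis=1, return_inverse=True)
    w = np.zeros(uniq.shape[1], dtype=float)
    np.add.at(w, inverse.ravel(), weights)
    return uniq, w


# ---------------------------------------------------------------------------
# Fitch scoring
# ---------------------------------------------------------------------------

_ZERO = np.uint64(0)


def _nested_changes(nested, codes: np.ndarray) -> np.ndarray:
    """Per-column Fitch change counts for a nested topology (handle = row 0)."""
    m = codes.shape[1]
    changes = np.zeros(m, dtype=np.int64)

    def rec(sub) -> np.ndarray:
        if not isinstance(sub, tuple):
            return codes[sub]
        a, b = rec(sub[0]), rec(sub[1])
        inter = a & b
        empty = inter == _ZERO
        changes[empty] += 1
        return np.where(empty, a | b, inter)

    state = rec(nested)
    changes[(state & codes[0]) == _ZERO] += 1
    return changes


def fitch_length(tree: PhyloTree, matrix: CharacterMatrix,
                 columns: Optional[Sequence[int]] = None,
                 gap_as_state: bool = False) -> int:
    """Minimum number of character state changes on the tree.

    Works on arbitrarily rooted trees; multifurcations are scored with a
    sequential Fitch fold (exact on binary trees, which is all the search
    ever produces).  Taxa absent from a column (``?``) are fully ambiguous.
    """
    taxa = list(tree.leaf_labels)
    codes = encode_columns(matrix, taxa, columns, gap_as_state)
    codes, w = compress_columns(codes)
    index = {t: i for i, t in enumerate(taxa)}
    changes = np.zeros(codes.shape[1], dtype=np.int64)
    state: dict = {}
    for node in tree.postorder():
        if node.is_leaf:
            state[id(node)] = codes[index[node.label]]
            continue
        acc = None
        for c in node.children:
            cs = state.pop(id(c))
            if acc is None:
                acc = cs
                continue
            inter = acc & cs
            empty = inter == _ZERO
            changes[empty] += 1
            acc = np.where(empty, acc | cs, inter)
        state[id(node)] = acc
    return int(changes @ w)


# ---------------------------------------------------------------------------
# Search configuration / results
# ---------------------------------------------------------------------------

@dataclass
class SearchConfig:
    """Parameters of the parsimony tree search.

    ``exhaustive_cap`` taxa or fewer triggers complete enumeration (globally
    optimal); above it, ``n_replicates`` random-addition starts are each
    refined by ``move`` hill-climbing.  The ratchet reweights a random
    fraction of columns for ``ratchet_iterations`` perturbation cycles.
    """
    n_replicates: int = 8
    move: str = "SPR"
    max_held: int = 1000
    seed: int = 0
    ratchet_iterations: int = 0
    ratchet_fraction: float = 0.25
    exhaustive_cap: int = 9

    def __post_init__(self):
        if self.n_replicates < 1:
            raise SearchError("n_replicates must be >= 1")
        if self.move not in ("NNI", "SPR"):
            raise SearchError(f"unknown move type {self.move!r}")


@dataclass
class SearchResult:
    trees: list[PhyloTree]
    score: int
    exact: bool
    seed: int


def _result_from_nesteds(nesteds: Iterable, taxa, score, exact, seed,
                         max_held) -> SearchResult:
    canon = sorted({nested_canonical(n) for n in nesteds}, key=str)[:max_held]
    return SearchResult([nested_to_tree(n, taxa) for n in canon],
                        int(score), exact, seed)


def bipartition_to_mask(bip: Bipartition, taxa: Sequence[str]) -> int:
    """Leaf-index bitmask of the bipartition side not containing ``taxa[0]``."""
    if bip.taxa != set(taxa):
        raise SearchError("bipartition is not over the matrix taxon set")
    index = {t: i for i, t in enumerate(taxa)}
    side = bip.side2 if taxa[0] in bip.side1 else bip.side1
    mask = 0
    for t in side:
        mask |= 1 << index[t]
    return mask


def mask_to_bipartition(mask: int, taxa: Sequence[str]) -> Bipartition:
    side = {t for i, t in enumerate(taxa) if mask >> i & 1}
    return Bipartition.of(side, set(taxa) - side)


# ---------------------------------------------------------------------------
# Heuristic machinery
# ---------------------------------------------------------------------------

def _graph_to_nested(adj, leaf_of, index):
    handle = next(i for i, lbl in leaf_of.items() if index[lbl] == 0)

    def build(node, parent):
        nbrs = [x for x in adj[node] if x != parent]
        if not nbrs:
            return index[leaf_of[node]]
        return (build(nbrs[0], node), build(nbrs[1], node))

    return build(next(iter(adj[handle])), handle)


def _neighbor_nesteds(nested, taxa, move: str):
    """Raw NNI/SPR neighbor topologies (may contain duplicates)."""
    tree = nested_to_tree(nested, taxa)
    adj, leaf_of = tree_to_graph(tree)
    index = {t: i for i, t in enumerate(taxa)}
    out = []
    if move == "NNI":
        for u in list(adj):
            if u in leaf_of:
                continue
            for v in list(adj[u]):
                if v in leaf_of or v < u:
                    continue
                others_u = sorted(x for x in adj[u] if x != v)
                b = others_u[1]
                for c in sorted(adj[v]):
                    if c == u:
                        continue
                    adj2 = {k: set(s) for k, s in adj.items()}
                    adj2[u].discard(b); adj2[b].discard(u)
                    adj2[v].discard(c); adj2[c].discard(v)
                    adj2[u].add(c); adj2[c].add(u)
                    adj2[v].add(b); adj2[b].add(v)
                    out.append(_graph_to_nested(adj2, leaf_of, index))
    else:
        for p in list(adj):
            if p in leaf_of:
                continue
            for s in list(adj[p]):
                adj2 = {k: set(x) for k, x in adj.items()}
                adj2[p].discard(s); adj2[s].discard(p)
                a, b = sorted(adj2[p])
                adj2[a].discard(p); adj2[b].discard(p)
                adj2[a].add(b); adj2[b].add(a)
                rest = dict(adj2); del rest[p]
                comp = set()
                stack = [a]
                while stack:
                    x = stack.pop()
                    if x in comp:
                        continue
                    comp.add(x)
                    stack.extend(rest[x] - comp)
                if s in comp:
                    continue
                redges = {(min(x, y), max(x, y))
                          for x in comp for y in rest[x] if y in comp}
                for (x, y) in sorted(redges):
                    if {x, y} == {a, b}:
                        continue
                    adj3 = {k: set(z) for k, z in rest.items()}
                    adj3[x].discard(y); adj3[y].discard(x)
                    adj3[p] = {x, y, s}
                    adj3[x].add(p); adj3[y].add(p)
                    adj3[s] = set(adj2[s]) | {p}
                    out.append(_graph_to_nested(adj3, leaf_of, index))
    return out


def _stepwise_addition(order, codes, w):
    """Greedy random-addition starting tree (nested form)."""
    from .trees import _nested_insert_positions
    order = [i for i in order if i != 0]
    nested = (order[0], order[1])
    for leaf in order[2:]:
        best = None
        best_score = None
        for cand in _nested_insert_positions(nested, leaf):
            sc = float(_nested_changes(cand, codes) @ w)
            if best_score is None or sc < best_score:
                best, best_score = cand, sc
        nested = best
    return nested


def _replace_none(nested, sub):
    """Substitute the ``None`` placeholder leaf by a subtree."""
    if nested is None:
        return sub
    if not isinstance(nested, tuple):
        return nested
    return (_replace_none(nested[0], sub), _replace_none(nested[1], sub))


def _random_subtree(indices, rng):
    """Random binary (sub)tree topology over the given leaf indices."""
    from .trees import _nested_insert_positions
    order = list(rng.permutation(np.asarray(indices)))
    if len(order) == 1:
        return int(order[0])
    sub = (int(order[0]), int(order[1]))
    for leaf in order[2:]:
        positions = list(_nested_insert_positions(sub, int(leaf)))
        sub = positions[rng.integers(len(positions))]
    return sub


def _hill_climb(nested, taxa, codes, w, move, accept=None,
                collect_ties=False, max_held=1000):
    score = float(_nested_changes(nested, codes) @ w)
    while True:
        improved = None
        improved_score = score
        ties = []
        for cand in _neighbor_nesteds(nested, taxa, move):
            if accept is not None and not accept(cand):
                continue
            sc = float(_nested_changes(cand, codes) @ w)
            if sc < improved_score:
                improved, improved_score = cand, sc
            elif collect_ties and sc == score:
                ties.append(cand)
        if improved is None:
            extras = ties[:max_held] if collect_ties else []
            return nested, score, extras
        nested, score = improved, improved_score


def _heuristic_search(codes, w, taxa, config: SearchConfig,
                      accept=None, start_nesteds=None,
                      start_factory=None) -> tuple[list, float]:
    n = len(taxa)
    rng = np.random.default_rng(config.seed)
    best_score = None
    held: dict = {}

    def consider(nested, score):
        nonlocal best_score
        if best_score is None or score < best_score:
            best_score = score
            held.clear()
        if score == best_score and len(held) < config.max_held:
            held[nested_canonical(nested)] = nested

    starts = list(start_nesteds or [])
    n_random = config.n_replicates if not starts else max(
        config.n_replicates - len(starts), 0)
    for _ in range(n_random):
        if start_factory is not None:
            s = start_factory(rng)
        else:
            order = list(rng.permutation(np.arange(1, n)))
            s = _stepwise_addition([0] + order, codes, w)
        if s is not None and (accept is None or accept(s)):
            starts.append(s)
    starts = [s for s in starts if accept is None or accept(s)]
    if not starts:
        raise SearchError("no admissible starting tree found")

    for start in starts:
        nested, score, ties = _hill_climb(
            start, taxa, codes, w, config.move, accept=accept,
            collect_ties=True, max_held=config.max_held)
        consider(nested, score)
        for t in ties:
            consider(t, score)
        for it in range(config.ratchet_iterations):
            wp = w.copy()
            hot = rng.random(len(w)) < config.ratchet_fraction
            wp[hot] *= 2.0
            pert, _, _ = _hill_climb(nested, taxa, codes, wp, config.move,
                                     accept=accept)
            cand, sc, ties = _hill_climb(
                pert, taxa, codes, w, config.move, accept=accept,
                collect_ties=True, max_held=config.max_held)
            consider(cand, sc)
            for t in ties:
                consider(t, sc)
            if sc <= score:
                nested, score = cand, sc
    return list(held.values()), float(best_score)


# ---------------------------------------------------------------------------
# Public searches
# ---------------------------------------------------------------------------

def _prepare(matrix: CharacterMatrix, columns, weights, gap_as_state):
    taxa = sorted(matrix.taxa)
    if len(taxa) < 3:
        raise SearchError("need at least 3 taxa")
    if matrix.n_columns == 0:
        raise SearchError("empty character matrix")
    codes = encode_columns(matrix, taxa, columns, gap_as_state)
    codes, w = compress_columns(codes, weights)
    return taxa, codes, w


def search_mp(matrix: CharacterMatrix,
              config: Optional[SearchConfig] = None,
              columns: Optional[Sequence[int]] = None,
              weights: Optional[np.ndarray] = None,
              gap_as_state: bool = False) -> SearchResult:
    """Find the shortest (most parsimonious) trees for the matrix."""
    config = config or SearchConfig()
    taxa, codes, w = _prepare(matrix, columns, weights, gap_as_state)
    n = len(taxa)
    if n <= config.exhaustive_cap:
        best_score = None
        best: list = []
        for nested in iter_nested_topologies(n):
            sc = float(_nested_changes(nested, codes) @ w)
            if best_score is None or sc < best_score:
                best_score, best = sc, [nested]
            elif sc == best_score and len(best) < config.max_held:
                best.append(nested)
        return _result_from_nesteds(best, taxa, best_score, True,
                                    config.seed, config.max_held)
    nesteds, score = _heuristic_search(codes, w, taxa, config)
    return _result_from_nesteds(nesteds, taxa, score, False, config.seed,
                                config.max_held)


def search_mp_constrained(matrix: CharacterMatrix,
                          bipartition: Bipartition,
                          mode: str,
                          config: Optional[SearchConfig] = None,
                          columns: Optional[Sequence[int]] = None,
                          weights: Optional[np.ndarray] = None,
                          gap_as_state: bool = False,
                          start_trees: Optional[Sequence[PhyloTree]] = None
                          ) -> SearchResult:
    """Shortest trees that contain (``require``) or lack (``forbid``) a split."""
    config = config or SearchConfig()
    if mode not in ("require", "forbid"):
        raise SearchError(f"mode must be 'require' or 'forbid', got {mode!r}")
    if bipartition.is_trivial:
        raise SearchError("constraint bipartition is trivial (singleton side)")
    taxa, codes, w = _prepare(matrix, columns, weights, gap_as_state)
    mask = bipartition_to_mask(bipartition, taxa)
    n = len(taxa)

    def admissible(nested):
        has = mask in nested_splits(nested, n)
        return has if mode == "require" else not has

    if n <= config.exhaustive_cap:
        best_score = None
        best: list = []
        for nested in iter_nested_topologies(n):
            if not admissible(nested):
                continue
            sc = float(_nested_changes(nested, codes) @ w)
            if best_score is None or sc < best_score:
                best_score, best = sc, [nested]
            elif sc == best_score and len(best) < config.max_held:
                best.append(nested)
        if best_score is None:
            raise SearchError("no topology satisfies the constraint")
        return _result_from_nesteds(best, taxa, best_score, True,
                                    config.seed, config.max_held)

    starts = []
    if start_trees:
        for t in start_trees:
            nst = tree_to_nested(t, taxa)
            if admissible(nst):
                starts.append(nst)
            else:
                # nudge across the constrained edge with NNI
                for cand in _neighbor_nesteds(nst, taxa, "NNI"):
                    if admissible(cand):
                        starts.append(cand)
                        break

    side_b = [i for i in range(n) if mask >> i & 1]
    side_a = [i for i in range(n) if not mask >> i & 1 and i != 0]

    def cold_start(rng):
        from .trees import _nested_insert_positions
        if mode == "forbid":
            order = list(rng.permutation(np.arange(1, n)))
            nst = _stepwise_addition([0] + order, codes, w)
            if admissible(nst):
                return nst
            for cand in _neighbor_nesteds(nst, taxa, "NNI"):
                if admissible(cand):
                    return cand
            return None
        # require: build the constrained side as an intact clade, then pick
        # the attachment on the remainder that scores best
        sub_b = _random_subtree(side_b, rng)
        nested_a = _random_subtree(side_a, rng)
        best, best_score = None, None
        for cand in _nested_insert_positions(nested_a, None):
            cand = _replace_none(cand, sub_b)
            sc = float(_nested_changes(cand, codes) @ w)
            if best_score is None or sc < best_score:
                best, best_score = cand, sc
        return best

    nesteds, score = _heuristic_search(codes, w, taxa, config,
                                       accept=admissible,
                                       start_nesteds=starts or None,
                                       start_factory=cold_start)
    return _result_from_nesteds(nesteds, taxa, score, False, config.seed,
                                config.max_held)


# ---------------------------------------------------------------------------
# Exhaustive per-partition length table (shared by Bremer / PBS)
# ---------------------------------------------------------------------------

@dataclass
class ExhaustiveTable:
    """Per-partition Fitch lengths of every unrooted topology on the taxa."""
    taxa: list[str]
    part_names: list[str]
    nesteds: list
    splits: list[frozenset]
    lengths: np.ndarray          # (n_topologies, n_partitions) ints
    totals: np.ndarray           # row sums

    def tree(self, i: int) -> PhyloTree:
        return nested_to_tree(self.nesteds[i], self.taxa)


def exhaustive_partition_table(matrix: CharacterMatrix,
                               gap_as_state: bool = False,
                               cap: int = 9) -> ExhaustiveTable:
    taxa = sorted(matrix.taxa)
    n = len(taxa)
    if n > cap:
        raise SearchError(f"{n} taxa exceeds the exhaustive cap ({cap})")
    part_names = sorted(matrix.partitions)
    codes = encode_columns(matrix, taxa, None, gap_as_state)
    uniq, inverse = np.unique(codes, axis=1, return_inverse=True)
    inverse = inverse.ravel()
    W = np.zeros((uniq.shape[1], len(part_names)))
    for j, name in enumerate(part_names):
        np.add.at(W[:, j], inverse[matrix.partitions[name]], 1.0)
    nesteds, splits, rows = [], [], []
    for nested in iter_nested_topologies(n):
        ch = _nested_changes(nested, uniq)
        nesteds.append(nested)
        splits.append(nested_splits(nested, n))
        rows.append(ch @ W)
    L = np.rint(np.array(rows)).astype(np.int64)
    return ExhaustiveTable(taxa, part_names, nesteds, splits, L,
                           L.sum(axis=1))
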