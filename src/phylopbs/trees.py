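"""Phylogenetic tree structures, Newick/NEXUS I/O, bipartition algebra, and
tree enumeration / rearrangement operators.

Trees are stored as plain parent/child node structures.  A tree may carry a
rooted or unrooted interpretation; branch support is always computed on the
unrooted view, where the identity of a "node" is the bipartition (split) of
the taxon set induced by removing one branch.

The exhaustive machinery used by the parsimony engine works on a compact
*nested-tuple* encoding of unrooted binary topologies: taxa are indexed
0..n-1 against a sorted label list, leaf 0 serves as a fixed handle, and the
rest of the tree is a nested pair structure over indices 1..n-1.  Stepwise
insertion over that encoding generates each unrooted topology exactly once.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Callable, Iterable, Iterator, Optional, Sequence

import dendropy


class TreeError(ValueError):
    """Invalid tree, or an operation applied to an unsuitable tree."""


class NewickParseError(TreeError):
    """Malformed Newick/NEXUS input."""


# ---------------------------------------------------------------------------
# Node / PhyloTree
# ---------------------------------------------------------------------------

class Node:
    __slots__ = ("label", "children", "parent", "length", "support")

    def __init__(self, label: Optional[str] = None,
                 length: Optional[float] = None):
        self.label = label
        self.children: list["Node"] = []
        self.parent: Optional["Node"] = None
        self.length = length
        self.support: Optional[float] = None

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def detach(self) -> "Node":
        if self.parent is not None:
            self.parent.children.remove(self)
            self.parent = None
        return self

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"<Node {self.label!r} deg={len(self.children)}>"


class PhyloTree:
    """A phylogenetic tree with uniquely labeled leaves.

    ``rooted`` records whether the root placement is meaningful.  All support
    computations unroot the tree first (bipartitions are branch attributes).
    """

    def __init__(self, root: Node, rooted: bool = True):
        self.root = root
        self.rooted = rooted
        self._validate()

    # -- construction / validation -------------------------------------
    def _validate(self) -> None:
        labels = [n.label for n in self.leaf_nodes()]
        if any(lbl is None or lbl == "" for lbl in labels):
            raise TreeError("every leaf must carry a non-empty label")
        if len(set(labels)) != len(labels):
            dups = sorted({l for l in labels if labels.count(l) > 1})
            raise TreeError(f"duplicate leaf labels: {', '.join(dups)}")

    # -- traversal ------------------------------------------------------
    def postorder(self) -> Iterator[Node]:
        stack, out = [self.root], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return reversed(out)

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaf_nodes(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    @property
    def leaf_labels(self) -> tuple[str, ...]:
        return tuple(sorted(n.label for n in self.leaf_nodes()))

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_nodes())

    def find_leaf(self, label: str) -> Node:
        for n in self.leaf_nodes():
            if n.label == label:
                return n
        raise TreeError(f"no leaf labeled {label!r}")

    def mrca(self, labels: Iterable[str]) -> Node:
        """Most recent common ancestor of the given leaf labels (rooted view)."""
        want = set(labels)
        below: dict[Node, set[str]] = {}
        for node in self.postorder():
            if node.is_leaf:
                below[node] = {node.label}
            else:
                below[node] = set().union(*(below[c] for c in node.children))
            if want <= below[node]:
                return node
        raise TreeError(f"labels {sorted(want)} not all present in tree")

    def copy(self) -> "PhyloTree":
        def dup(node: Node) -> Node:
            new = Node(node.label, node.length)
            new.support = node.support
            for c in node.children:
                new.add(dup(c))
            return new
        return PhyloTree(dup(self.root), rooted=self.rooted)

    # -- topology predicates ---------------------------------------------
    def is_binary(self) -> bool:
        """Binary in the unrooted sense (all internal degrees 3, root deg 2/3)."""
        for node in self.postorder():
            if node.is_leaf:
                continue
            deg = len(node.children) + (0 if node.parent is None else 1)
            if node.parent is None:
                if deg not in (2, 3):
                    return False
            elif deg != 3:
                return False
        return True

    # -- bipartitions -----------------------------------------------------
    def bipartitions(self, include_trivial: bool = False) -> frozenset["Bipartition"]:
        """Bipartitions of the unrooted view of this tree.

        Nontrivial bipartitions (both sides >= 2) only, unless
        ``include_trivial``.  The two edges incident to a degree-2 root induce
        the same split and are reported once.
        """
        all_taxa = set(self.leaf_labels)
        n = len(all_taxa)
        if n < 4 and not include_trivial:
            return frozenset()
        out = set()
        below: dict[Node, frozenset[str]] = {}
        for node in self.postorder():
            if node.is_leaf:
                below[node] = frozenset([node.label])
            else:
                below[node] = frozenset().union(*(below[c] for c in node.children))
            if node.parent is None:
                continue
            side = below[node]
            k = len(side)
            if k == 0 or k == n:
                continue
            if not include_trivial and (k < 2 or k > n - 2):
                continue
            out.add(Bipartition.of(side, all_taxa - side))
        return frozenset(out)

    # -- serialization ----------------------------------------------------
    def newick(self, lengths: bool = True, support: str = "none") -> str:
        """Serialize to Newick.

        ``support`` controls internal-node support annotation: "none",
        "label" (written as internal node label) or "comment" (bracket
        comment ``[freq]`` after the node).
        """
        def quote(label: str) -> str:
            if any(c in label for c in " \t()[]:;,'"):
                return "'" + label.replace("'", "''") + "'"
            return label

        def fmt(node: Node) -> str:
            if node.is_leaf:
                s = quote(node.label)
            else:
                s = "(" + ",".join(fmt(c) for c in node.children) + ")"
                if support != "none" and node.support is not None:
                    val = f"{node.support:g}"
                    s += val if support == "label" else f"[{val}]"
                elif node.label:
                    s += quote(node.label)
            if lengths and node.length is not None:
                s += f":{node.length:g}"
            return s

        return fmt(self.root) + ";"

    def __repr__(self):  # pragma: no cover
        return f"<PhyloTree n={self.n_leaves} rooted={self.rooted}>"


# ---------------------------------------------------------------------------
# Bipartition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Bipartition:
    """A split of the full taxon set into two disjoint non-empty sides.

    Canonical orientation: the side containing the lexicographically smallest
    taxon is ``side1``.
    """
    side1: frozenset
    side2: frozenset

    @staticmethod
    def of(side_a: Iterable[str], side_b: Iterable[str]) -> "Bipartition":
        a, b = frozenset(side_a), frozenset(side_b)
        if not a or not b:
            raise TreeError("bipartition sides must be non-empty")
        if a & b:
            raise TreeError(f"bipartition sides overlap: {sorted(a & b)}")
        if min(a | b) in b:
            a, b = b, a
        return Bipartition(a, b)

    @property
    def taxa(self) -> frozenset:
        return self.side1 | self.side2

    @property
    def is_trivial(self) -> bool:
        return min(len(self.side1), len(self.side2)) < 2

    @staticmethod
    def from_string(text: str) -> "Bipartition":
        try:
            a, b = text.split("|")
        except ValueError:
            raise TreeError(f"bad bipartition string {text!r}") from None
        return Bipartition.of(a.split(), b.split())

    def side_of(self, label: str) -> int:
        if label in self.side1:
            return 0
        if label in self.side2:
            return 1
        raise KeyError(label)

    def __str__(self) -> str:
        return " ".join(sorted(self.side1)) + " | " + " ".join(sorted(self.side2))


# ---------------------------------------------------------------------------
# Newick / NEXUS I/O (parsing delegated to dendropy)
# ---------------------------------------------------------------------------

def _from_dendropy(dtree: "dendropy.Tree") -> PhyloTree:
    def conv(dnode) -> Node:
        label = None
        if dnode.taxon is not None:
            label = dnode.taxon.label
        elif dnode.label:
            label = dnode.label
        node = Node(label if dnode.is_leaf() else None,
                    dnode.edge.length)
        if not dnode.is_leaf() and label:
            try:
                node.support = float(label)
            except ValueError:
                node.label = label
        for c in dnode.child_nodes():
            node.add(conv(c))
        return node

    root = conv(dtree.seed_node)
    rooted = dtree.is_rooted if dtree.is_rooted is not None else len(root.children) == 2
    return PhyloTree(root, rooted=bool(rooted))


def parse_newick(text: str, min_leaves: int = 3) -> PhyloTree:
    """Parse a single Newick string into a :class:`PhyloTree`.

    Raises :class:`NewickParseError` (with the offending position, when the
    parser reports one) for malformed input, and :class:`TreeError` for
    duplicate/empty labels or trees below ``min_leaves`` leaves.
    """
    if not isinstance(text, str) or not text.strip():
        raise NewickParseError("empty Newick string")
    try:
        dtree = dendropy.Tree.get(data=text, schema="newick",
                                  suppress_internal_node_taxa=True,
                                  preserve_underscores=True)
    except Exception as exc:  # dendropy raises several error classes
        raise NewickParseError(f"malformed Newick: {exc}") from exc
    tree = _from_dendropy(dtree)
    if tree.n_leaves < min_leaves:
        raise TreeError(
            f"tree has {tree.n_leaves} leaves; at least {min_leaves} required "
            "for unrooted analyses")
    return tree


def read_trees_nexus(path) -> list[PhyloTree]:
    """Read all trees from a NEXUS TREES block."""
    try:
        tl = dendropy.TreeList.get(path=str(path), schema="nexus",
                                   preserve_underscores=True)
    except Exception as exc:
        raise NewickParseError(f"cannot read NEXUS trees from {path}: {exc}") from exc
    return [_from_dendropy(t) for t in tl]


# ---------------------------------------------------------------------------
# Nested-tuple encoding of unrooted binary topologies
# ---------------------------------------------------------------------------
# nested := leaf index (int) | (nested, nested); taxon 0 is the implicit
# handle attached to the root of the nested structure.

Nested = object  # int | tuple


def _nested_insert_positions(sub, leaf: int):
    """Yield copies of ``sub`` with ``leaf`` attached on every edge."""
    yield (sub, leaf)
    if isinstance(sub, tuple):
        left, right = sub
        for nl in _nested_insert_positions(left, leaf):
            yield (nl, right)
        for nr in _nested_insert_positions(right, leaf):
            yield (left, nr)


def iter_nested_topologies(n: int) -> Iterator:
    """All distinct unrooted binary topologies on leaf indices 0..n-1."""
    if n < 3:
        raise TreeError("need at least 3 taxa")

    def rec(topo, leaf):
        if leaf == n:
            yield topo
            return
        for cand in _nested_insert_positions(topo, leaf):
            yield from rec(cand, leaf + 1)

    yield from rec((1, 2), 3)


def nested_splits(nested, n: int) -> frozenset:
    """Nontrivial splits of the topology as leaf-index bitmasks.

    Masks never contain bit 0 (the handle leaf), which makes them canonical.
    """
    out = []

    def walk(sub) -> int:
        if not isinstance(sub, tuple):
            return 1 << sub
        mask = walk(sub[0]) | walk(sub[1])
        k = mask.bit_count()
        if 2 <= k <= n - 2:
            out.append(mask)
        return mask

    walk(nested)
    return frozenset(out)


def nested_canonical(nested):
    """Canonical form of a nested topology (children sorted by min leaf)."""
    if not isinstance(nested, tuple):
        return nested

    def rec(sub):
        if not isinstance(sub, tuple):
            return sub, sub
        (la, ka), (lb, kb) = rec(sub[0]), rec(sub[1])
        if ka < kb:
            return (la, lb), ka
        return (lb, la), kb

    return rec(nested)[0]


def nested_to_tree(nested, taxa: Sequence[str]) -> PhyloTree:
    """Convert a nested topology (with handle leaf ``taxa[0]``) to a PhyloTree."""
    def build(sub) -> Node:
        if not isinstance(sub, tuple):
            return Node(taxa[sub])
        node = Node()
        node.add(build(sub[0]))
        node.add(build(sub[1]))
        return node

    root = Node()
    root.add(Node(taxa[0]))
    root.add(build(nested))
    return PhyloTree(root, rooted=False)


def tree_to_nested(tree: PhyloTree, taxa: Sequence[str]):
    """Convert a binary tree to nested form on the given (sorted) taxon list.

    The tree is unrooted first; its leaf set must equal ``taxa``.
    """
    if tuple(sorted(taxa)) != tree.leaf_labels:
        raise TreeError("taxon list does not match tree leaves")
    index = {t: i for i, t in enumerate(taxa)}
    adj, leaf_of = tree_to_graph(tree)
    handle = next(i for i, lbl in leaf_of.items() if lbl == taxa[0])
    if len(adj[handle]) != 1:
        raise TreeError("handle taxon is not a leaf")

    def build(node: int, parent: int):
        nbrs = [x for x in adj[node] if x != parent]
        if not nbrs:
            return index[leaf_of[node]]
        if len(nbrs) != 2:
            raise TreeError("tree is not binary (unrooted)")
        return (build(nbrs[0], node), build(nbrs[1], node))

    start = next(iter(adj[handle]))
    return build(start, handle)


# ---------------------------------------------------------------------------
# Adjacency-graph view (for rearrangements)
# ---------------------------------------------------------------------------

def tree_to_graph(tree: PhyloTree) -> tuple[dict[int, set], dict[int, str]]:
    """Unrooted adjacency view: (adjacency map, leaf id -> label).

    A degree-2 root is suppressed (its two incident edges are merged).
    """
    ids: dict[Node, int] = {}
    adj: dict[int, set] = {}
    leaf_of: dict[int, str] = {}
    for node in tree.postorder():
        i = ids[node] = len(ids)
        adj[i] = set()
        if node.is_leaf:
            leaf_of[i] = node.label
    for node in tree.postorder():
        if node.parent is not None:
            adj[ids[node]].add(ids[node.parent])
            adj[ids[node.parent]].add(ids[node])
    r = ids[tree.root]
    if len(adj[r]) == 2:
        a, b = adj[r]
        adj[a].discard(r)
        adj[b].discard(r)
        adj[a].add(b)
        adj[b].add(a)
        del adj[r]
    return adj, leaf_of


def graph_to_tree(adj: dict[int, set], leaf_of: dict[int, str]) -> PhyloTree:
    """Rebuild a (rooted-at-arbitrary-internal-node) PhyloTree from a graph."""
    internal = [i for i in adj if i not in leaf_of]
    start = min(internal) if internal else min(adj)

    def build(i: int, parent: Optional[int]) -> Node:
        node = Node(leaf_of.get(i))
        for j in sorted(adj[i]):
            if j != parent:
                node.add(build(j, i))
        return node

    return PhyloTree(build(start, None), rooted=False)


def _graph_splits(adj, leaf_of) -> frozenset:
    taxa = set(leaf_of.values())
    n = len(taxa)
    out = set()
    seen = set()

    def below(i, parent):
        acc = set()
        if i in leaf_of:
            acc.add(leaf_of[i])
        for j in adj[i]:
            if j != parent:
                acc |= below(j, i)
        return acc

    for u in adj:
        for v in adj[u]:
            if (v, u) in seen:
                continue
            seen.add((u, v))
            side = frozenset(below(v, u))
            if 2 <= len(side) <= n - 2:
                out.add(Bipartition.of(side, taxa - side))
    return frozenset(out)


def rearrangement_neighbors(tree: PhyloTree, move: str = "NNI") -> list[PhyloTree]:
    """All distinct topologies one NNI or SPR move away (input excluded)."""
    if move not in ("NNI", "SPR"):
        raise TreeError(f"unknown move type {move!r}")
    if not tree.is_binary():
        raise TreeError("rearrangements require a binary tree")
    if tree.n_leaves < 4:
        raise TreeError("rearrangements require at least 4 leaves")
    adj, leaf_of = tree_to_graph(tree)
    self_fp = _graph_splits(adj, leaf_of)
    results: dict[frozenset, tuple] = {}

    def record(adj2):
        fp = _graph_splits(adj2, leaf_of)
        if fp != self_fp and fp not in results:
            results[fp] = {k: set(v) for k, v in adj2.items()}

    if move == "NNI":
        for u in adj:
            if u in leaf_of:
                continue
            for v in adj[u]:
                if v in leaf_of or v < u:
                    continue
                (a, b) = sorted(x for x in adj[u] if x != v)
                for c in adj[v]:
                    if c == u:
                        continue
                    # swap subtree b (on u side) with subtree c (on v side)
                    adj2 = {k: set(s) for k, s in adj.items()}
                    adj2[u].discard(b); adj2[b].discard(u)
                    adj2[v].discard(c); adj2[c].discard(v)
                    adj2[u].add(c); adj2[c].add(u)
                    adj2[v].add(b); adj2[b].add(v)
                    record(adj2)
    else:  # SPR
        edges = [(u, v) for u in adj for v in adj[u]]
        for (p, s) in edges:
            # prune the subtree hanging at s away from attachment node p;
            # p must be internal (degree 3) so it can be suppressed
            if p in leaf_of:
                continue
            adj2 = {k: set(x) for k, x in adj.items()}
            adj2[p].discard(s); adj2[s].discard(p)
            a, b = sorted(adj2[p])
            adj2[a].discard(p); adj2[b].discard(p)
            adj2[a].add(b); adj2[b].add(a)
            del adj2[p]
            # remaining edges of the pruned tree (component containing a)
            comp = set()
            stack = [a]
            while stack:
                x = stack.pop()
                if x in comp:
                    continue
                comp.add(x)
                stack.extend(adj2[x])
            if s in comp:
                continue
            redges = {(min(x, y), max(x, y))
                      for x in comp for y in adj2[x]}
            for (x, y) in sorted(redges):
                if {x, y} == {a, b}:
                    continue  # regrafting on the original edge restores input
                adj3 = {k: set(z) for k, z in adj2.items()}
                adj3[x].discard(y); adj3[y].discard(x)
                adj3[p] = {x, y, s}
                adj3[x].add(p); adj3[y].add(p)
                adj3[s].add(p)
                record(adj3)

    return [graph_to_tree(a, leaf_of) for a in results.values()]


# ---------------------------------------------------------------------------
# Enumeration (public API)
# ---------------------------------------------------------------------------

def enumerate_unrooted_topologies(taxa: Sequence[str], cap: int = 9) -> list[PhyloTree]:
    """All distinct unrooted binary topologies on the given taxa.

    Refuses taxon sets larger than ``cap`` (default 9, i.e. 135,135 trees);
    use the heuristic search for anything bigger.
    """
    labels = sorted(taxa)
    if len(labels) != len(set(labels)):
        raise TreeError("duplicate taxon labels")
    n = len(labels)
    if n < 3:
        raise TreeError("need at least 3 taxa")
    if n > cap:
        raise TreeError(
            f"{n} taxa exceeds the exhaustive-enumeration cap ({cap}); "
            "use the heuristic search instead")
    return [nested_to_tree(t, labels) for t in iter_nested_topologies(n)]


# ---------------------------------------------------------------------------
# Consensus
# ---------------------------------------------------------------------------

def majority_rule_consensus(trees: Sequence[PhyloTree],
                            threshold: float = 0.5) -> PhyloTree:
    """Majority-rule consensus with per-node occurrence percentages.

    Keeps exactly the bipartitions present in strictly more than
    ``threshold`` of the input trees (``threshold=1.0`` means "in all
    trees").  Node ``support`` attributes carry percentages in [0, 100].
    """
    if not trees:
        raise TreeError("no trees given")
    if not 0.5 <= threshold <= 1.0:
        raise TreeError("threshold must be in [0.5, 1.0]")
    taxa = trees[0].leaf_labels
    for t in trees[1:]:
        if t.leaf_labels != taxa:
            extra = set(t.leaf_labels) ^ set(taxa)
            raise TreeError(
                f"trees are on different taxon sets; symmetric difference: "
                f"{sorted(extra)}")
    total = len(trees)
    counts: dict[Bipartition, int] = {}
    for t in trees:
        for b in t.bipartitions():
            counts[b] = counts.get(b, 0) + 1
    anchor = taxa[0]
    keep: list[tuple[frozenset, float]] = []
    for b, c in counts.items():
        if (c == total) if threshold >= 1.0 else (c > threshold * total):
            cluster = b.side2 if anchor in b.side1 else b.side1
            keep.append((cluster, 100.0 * c / total))
    # nested/disjoint clusters (threshold >= 0.5 guarantees compatibility)
    keep.sort(key=lambda cf: (-len(cf[0]), sorted(cf[0])))
    root = Node()
    node_of: dict[frozenset, Node] = {}
    parent_cluster: dict[frozenset, Optional[frozenset]] = {}
    for cluster, freq in keep:
        parent = None
        for other, _ in keep:
            if other is cluster:
                continue
            if cluster < other and (parent is None or other < parent):
                parent = other
        parent_cluster[cluster] = parent
        node = Node()
        node.support = freq
        node_of[cluster] = node
    for cluster, _ in keep:
        p = parent_cluster[cluster]
        (root if p is None else node_of[p]).add(node_of[cluster])
    for label in taxa:
        parent = None
        for cluster, _ in keep:
            if label in cluster and (parent is None or cluster < parent):
                parent = cluster
        (root if parent is None else node_of[parent]).add(Node(label))
    return PhyloTree(root, rooted=False)


def strict_consensus_splits(trees: Sequence[PhyloTree]) -> frozenset:
    """Bipartitions common to all trees (the strict consensus split set)."""
    if not trees:
        raise TreeError("no trees given")
    splits = set(trees[0].bipartitions())
    for t in trees[1:]:
        splits &= t.bipartitions()
    return frozenset(splits)


def restrict_to_leaves(tree: PhyloTree, labels: Iterable[str]) -> Optional[PhyloTree]:
    """Prune the tree down to the given leaves, suppressing unary nodes.

    Rootedness is preserved.  Returns None if no requested leaf is present
    or only one remains (no tree to speak of).
    """
    keep = set(labels)

    def rec(node: Node) -> Optional[Node]:
        if node.is_leaf:
            if node.label in keep:
                return Node(node.label, node.length)
            return None
        kids = [k for k in (rec(c) for c in node.children) if k is not None]
        if not kids:
            return None
        if len(kids) == 1:
            only = kids[0]
            if node.length is not None or only.length is not None:
                only.length = (only.length or 0.0) + (node.length or 0.0)
            return only
        new = Node(None, node.length)
        for k in kids:
            new.add(k)
        return new

    root = rec(tree.root)
    if root is None or root.is_leaf:
        return None
    return PhyloTree(root, rooted=tree.rooted)


def double_factorial_topology_count(n: int) -> int:
    """(2n-5)!! — number of unrooted binary topologies on n >= 3 taxa."""
    out = 1
    for k in range(3, 2 * n - 4, 2):
        out *= k
    return out
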