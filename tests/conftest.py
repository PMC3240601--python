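"""Shared fixtures: small worked-example matrices and random-tree helpers."""
from __future__ import annotations

import numpy as np
import pytest

from phylopbs.matrix import CharacterMatrix
from phylopbs.parsimony import _random_subtree
from phylopbs.trees import PhyloTree, nested_to_tree, parse_newick


@pytest.fixture
def quartet_two_partitions() -> CharacterMatrix:
    """P1 = 5 columns (A,A,C,C); P2 = 3 columns (A,C,A,C).

    The combined optimum is ((A,B),(C,D)) at 11 steps; P1 supports AB|CD
    (+5) while P2 contradicts it (-3), for a Bremer support of 2.
    """
    return CharacterMatrix.from_dict(
        {"A": "AAAAA" + "AAA", "B": "AAAAA" + "CCC",
         "C": "CCCCC" + "AAA", "D": "CCCCC" + "CCC"},
        {"P1": range(0, 5), "P2": range(5, 8)})


@pytest.fixture
def fig_gene_family_tree() -> tuple[PhyloTree, dict]:
    """Gene-family tree with a root duplication and a within-species pair.

    Species A, B, C; the expected decomposition is {A1,B1,C1} and
    {A2,A3,B2,C2} (the A2/A3 co-ortholog pair stays with its partners).
    """
    tree = parse_newick("(((A1,B1),C1),((A2,A3),(B2,C2)));")
    return tree, {g: g[0] for g in tree.leaf_labels}


def random_binary_tree(rng: np.random.Generator, n: int,
                       prefix: str = "t") -> PhyloTree:
    taxa = [f"{prefix}{i:02d}" for i in range(n)]
    nested = _random_subtree(list(range(1, n)), rng)
    return nested_to_tree(nested, taxa)


def random_matrix(rng: np.random.Generator, n_taxa: int, n_parts: int,
                  alphabet: str = "ACGT") -> CharacterMatrix:
    taxa = [chr(65 + i) for i in range(n_taxa)]
    cols = {t: "" for t in taxa}
    parts = {}
    at = 0
    for p in range(n_parts):
        width = int(rng.integers(3, 8))
        parts[f"g{p}"] = range(at, at + width)
        at += width
        for t in taxa:
            cols[t] += "".join(rng.choice(list(alphabet), width))
    return CharacterMatrix.from_dict(cols, parts)
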