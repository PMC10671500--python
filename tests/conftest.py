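"""Shared fixtures: small trees, alignments, and sequence builders."""

from __future__ import annotations

import numpy as np
import pytest

from serpinscape.io import parse_newick
from serpinscape.phylo import Alignment, TreeNode

AA = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tree4():
    """Unrooted 4-taxon tree (trifurcating root)."""
    return parse_newick("((A:0.3,B:0.3):0.15,C:0.4,D:0.4);")


@pytest.fixture
def tree6():
    """6-taxon tree with serpin-paralog-scale divergence."""
    return parse_newick(
        "((A:0.4,B:0.4):0.2,(C:0.4,D:0.4):0.2,(E:0.5,F:0.5):0.1);"
    )


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA), size=length))


def mutate(seq: str, n: int, rng: np.random.Generator) -> str:
    """Substitute n random positions (possibly to the same residue class)."""
    s = list(seq)
    for i in rng.choice(len(s), size=n, replace=False):
        s[i] = rng.choice(list(AA))
    return "".join(s)


def hierarchical_alignment(rng: np.random.Generator) -> tuple:
    """Eight taxa in two nested 4-taxon clades with diagnostic columns on
    every internal edge; returns (Alignment, expected bipartitions)."""
    root = random_protein(rng, 300)
    cladeA = mutate(root, 60, rng)
    cladeB = mutate(root, 60, rng)
    a01 = mutate(cladeA, 30, rng)
    a23 = mutate(cladeA, 30, rng)
    b01 = mutate(cladeB, 30, rng)
    b23 = mutate(cladeB, 30, rng)
    rows = {}
    for name, anc in (("A0", a01), ("A1", a01), ("A2", a23), ("A3", a23),
                      ("B0", b01), ("B1", b01), ("B2", b23), ("B3", b23)):
        rows[name] = mutate(anc, 4, rng)
    aln = Alignment(ids=list(rows), rows=list(rows.values()))
    expected = [
        frozenset({"A0", "A1"}), frozenset({"A2", "A3"}),
        frozenset({"B0", "B1"}), frozenset({"B2", "B3"}),
        frozenset({"A0", "A1", "A2", "A3"}),
    ]
    return aln, expected


def random_additive_tree(
    n_taxa: int, rng: np.random.Generator
) -> tuple:
    """Random binary topology with positive branch lengths; returns
    (TreeNode with trifurcating root, leaf-name list)."""
    nodes = [TreeNode(name=f"T{i}", length=float(rng.uniform(0.1, 1.0)))
             for i in range(n_taxa)]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = TreeNode(length=float(rng.uniform(0.1, 1.0)))
        parent.children = [nodes[i], nodes[j]]
        rest = [nodes[k] for k in range(len(nodes)) if k not in (i, j)]
        nodes = rest + [parent]
    root = TreeNode()
    root.children = nodes
    return root, [f"T{i}" for i in range(n_taxa)]


def tree_distances(tree: TreeNode) -> dict:
    """Path-length distances between all leaf pairs."""
    paths = {}

    def walk(node, acc):
        if node.is_leaf():
            paths[node.name] = acc
        for c in node.children:
            walk(c, acc + [(c, c.length)])

    walk(tree, [])
    out = {}
    names = list(paths)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            ea = {id(n): l for n, l in paths[a]}
            eb = {id(n): l for n, l in paths[b]}
            d = sum(l for k, l in ea.items() if k not in eb)
            d += sum(l for k, l in eb.items() if k not in ea)
            out[(a, b)] = out[(b, a)] = d
    return out
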