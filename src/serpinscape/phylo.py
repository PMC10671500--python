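"""Distance-based phylogenetics: Poisson-corrected distances, neighbor
joining, bootstrap support, and global pairwise alignment identity.

Distances use pairwise deletion of gapped columns; the Poisson correction
d = -ln(1 - p) converts the proportion of differing columns p into an
expected number of substitutions per site.  Neighbor joining follows the
Saitou-Nei agglomeration with ties broken on the lowest (i, j) index pair
and negative branch-length estimates clamped to zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "Alignment",
    "DistanceMatrix",
    "TreeNode",
    "pairwise_distance",
    "neighbor_joining",
    "bootstrap_support",
    "global_align",
    "bipartitions",
    "robinson_foulds",
]

GAP_CHARS = frozenset("-.")


@dataclass
class Alignment:
    """Equal-length gapped rows keyed by ordered ids."""

    ids: List[str]
    rows: List[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows must be parallel")
        if len(self.rows) < 2:
            raise ValueError("alignment needs at least 2 rows")
        ncol = len(self.rows[0])
        if any(len(r) != ncol for r in self.rows):
            raise ValueError("alignment rows must all have the same length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("alignment ids must be unique")

    @property
    def n_cols(self) -> int:
        return len(self.rows[0])

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def subset_columns(self, cols: Sequence[int]) -> "Alignment":
        rows = ["".join(r[c] for c in cols) for r in self.rows]
        return Alignment(ids=list(self.ids), rows=rows)


@dataclass
class DistanceMatrix:
    ids: List[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape must match ids")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(m), 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        if (m < -1e-12).any():
            raise ValueError("distances must be non-negative")
        self.matrix = m


@dataclass
class TreeNode:
    """Simple rooted-representation tree node (used unrooted for NJ output)."""

    name: Optional[str] = None
    length: float = 0.0
    support: Optional[float] = None
    children: List["TreeNode"] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> List["TreeNode"]:
        if self.is_leaf():
            return [self]
        out: List[TreeNode] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> List[str]:
        return [l.name for l in self.leaves()]

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()

    def to_newick(self, include_support: bool = True) -> str:
        return self._newick_inner(include_support) + ";"

    def _newick_inner(self, include_support: bool) -> str:
        if self.is_leaf():
            return f"{self.name}:{self.length:.10g}"
        inner = ",".join(c._newick_inner(include_support) for c in self.children)
        label = ""
        if include_support and self.support is not None:
            label = f"{self.support:.10g}"
        elif self.name:
            label = self.name
        return f"({inner}){label}:{self.length:.10g}"


def pairwise_distance(aln: Alignment, model: str = "poisson") -> DistanceMatrix:
    """Pairwise distances with pairwise deletion of gapped columns.

    model 'p' returns the raw proportion of differences; 'poisson' applies
    d = -ln(1 - p).  A pair with no shared non-gap column, or with p >= 1
    under the Poisson model (saturation), is an error.
    """
    if model not in {"p", "poisson"}:
        raise ValueError(f"unknown distance model {model!r}")
    n = aln.n_rows
    D = np.zeros((n, n))
    for i in range(n):
        ri = aln.rows[i]
        for j in range(i + 1, n):
            rj = aln.rows[j]
            shared = mismatch = 0
            for a, b in zip(ri, rj):
                if a in GAP_CHARS or b in GAP_CHARS:
                    continue
                shared += 1
                if a != b:
                    mismatch += 1
            if shared == 0:
                raise ValueError(
                    f"no shared non-gap columns between {aln.ids[i]} and {aln.ids[j]}"
                )
            p = mismatch / shared
            if model == "p":
                d = p
            else:
                if p >= 1.0:
                    raise ValueError(
                        f"saturated pair {aln.ids[i]}/{aln.ids[j]}: p = {p} >= 1 "
                        "has no Poisson-corrected distance"
                    )
                d = -math.log(1.0 - p)
            D[i, j] = D[j, i] = d
    return DistanceMatrix(ids=list(aln.ids), matrix=D)


def neighbor_joining(D: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining; returns an unrooted tree represented
    with a trifurcating root.

    On an additive matrix the generating topology and branch lengths are
    recovered exactly.  Negative branch-length estimates are clamped to 0.
    """
    n = len(D.ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    nodes: List[TreeNode] = [TreeNode(name=i) for i in D.ids]
    d = D.matrix.astype(float).copy()
    active = list(range(n))
    dist: Dict[Tuple[int, int], float] = {}
    for a in range(n):
        for b in range(a + 1, n):
            dist[(a, b)] = d[a, b]
    node_of: Dict[int, TreeNode] = {i: nodes[i] for i in range(n)}
    next_id = n

    def get(a: int, b: int) -> float:
        return dist[(a, b) if a < b else (b, a)]

    while len(active) > 3:
        r = len(active)
        net = {a: sum(get(a, b) for b in active if b != a) for a in active}
        best = None
        best_q = math.inf
        for ia in range(r):
            for ib in range(ia + 1, r):
                a, b = active[ia], active[ib]
                q = (r - 2) * get(a, b) - net[a] - net[b]
                if q < best_q - 1e-12:
                    best_q = q
                    best = (a, b)
        a, b = best
        dab = get(a, b)
        la = 0.5 * dab + (net[a] - net[b]) / (2 * (r - 2))
        lb = dab - la
        la, lb = max(la, 0.0), max(lb, 0.0)
        parent = TreeNode()
        ca, cb = node_of[a], node_of[b]
        ca.length, cb.length = la, lb
        parent.children = [ca, cb]
        u = next_id
        next_id += 1
        node_of[u] = parent
        for c in active:
            if c in (a, b):
                continue
            duc = 0.5 * (get(a, c) + get(b, c) - dab)
            dist[(min(c, u), max(c, u))] = max(duc, 0.0)
        active = [c for c in active if c not in (a, b)] + [u]

    # Final three nodes: resolve with the three-point formulas.
    a, b, c = active
    dab, dac, dbc = get(a, b), get(a, c), get(b, c)
    la = 0.5 * (dab + dac - dbc)
    lb = 0.5 * (dab + dbc - dac)
    lc = 0.5 * (dac + dbc - dab)
    root = TreeNode()
    for idx, ln in zip((a, b, c), (la, lb, lc)):
        child = node_of[idx]
        child.length = max(ln, 0.0)
        root.children.append(child)
    return root


def bipartitions(tree: TreeNode) -> Dict[FrozenSet[str], TreeNode]:
    """Non-trivial bipartitions of an unrooted tree, keyed by the smaller-
    or lexicographically-first side as a frozen leaf-name set."""
    all_leaves = frozenset(tree.leaf_names())
    out: Dict[FrozenSet[str], TreeNode] = {}
    for node in tree.walk():
        if node is tree or node.is_leaf():
            continue
        side = frozenset(node.leaf_names())
        other = all_leaves - side
        if len(side) < 2 or len(other) < 2:
            continue
        key = min(side, other, key=lambda s: (len(s), tuple(sorted(s))))
        out[key] = node
    return out


def robinson_foulds(t1: TreeNode, t2: TreeNode) -> int:
    """Unweighted Robinson-Foulds distance (symmetric bipartition difference)."""
    b1 = set(bipartitions(t1))
    b2 = set(bipartitions(t2))
    return len(b1 ^ b2)


def bootstrap_support(
    aln: Alignment,
    reps: int = 1000,
    seed: int = 0,
    model: str = "poisson",
) -> TreeNode:
    """NJ tree from the full alignment with bootstrap supports.

    Columns are resampled with replacement per replicate; support is the
    percentage of replicates whose NJ tree contains each internal
    bipartition of the full-data tree.
    """
    if reps < 1:
        raise ValueError("bootstrap needs at least 1 replicate")
    tree = neighbor_joining(pairwise_distance(aln, model=model))
    target = bipartitions(tree)
    counts = {key: 0 for key in target}
    rng = np.random.default_rng(seed)
    ncol = aln.n_cols
    for _ in range(reps):
        cols = rng.integers(0, ncol, size=ncol)
        rep_aln = aln.subset_columns(cols.tolist())
        try:
            rep_tree = neighbor_joining(pairwise_distance(rep_aln, model=model))
        except ValueError:
            continue  # saturated / all-gap resample contributes no support
        rep_bi = set(bipartitions(rep_tree))
        for key in counts:
            if key in rep_bi:
                counts[key] += 1
    for key, node in target.items():
        node.support = 100.0 * counts[key] / reps
    return tree


def global_align(
    a: str,
    b: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -5.0,
    gap_extend: float = -1.0,
    matrix: Optional[str] = None,
) -> Tuple[str, str, float, float]:
    """Needleman-Wunsch global alignment via Biopython's PairwiseAligner.

    Returns (aligned_a, aligned_b, score, identity_pct) where identity is
    matches over all alignment columns (gaps included in the denominator).
    ``matrix`` names a Biopython substitution matrix (e.g. 'BLOSUM62');
    otherwise match/mismatch scores apply.
    """
    if not a or not b:
        raise ValueError("global_align requires two non-empty sequences")
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    if matrix is not None:
        aligner.substitution_matrix = substitution_matrices.load(matrix)
    else:
        aligner.match_score = match
        aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    result = aligner.align(a, b)
    best = result[0]
    row_a, row_b = str(best[0]), str(best[1])
    cols = len(row_a)
    ident = sum(1 for x, y in zip(row_a, row_b) if x == y and x not in GAP_CHARS)
    return row_a, row_b, float(best.score), round(100.0 * ident / cols, 2)
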