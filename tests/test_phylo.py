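"""Distances, neighbor joining, bootstrap, and pairwise alignment."""

import itertools
import math

import numpy as np
import pytest

from serpinscape.phylo import (
    Alignment,
    DistanceMatrix,
    bipartitions,
    bootstrap_support,
    global_align,
    neighbor_joining,
    pairwise_distance,
    robinson_foulds,
)

from conftest import hierarchical_alignment, random_additive_tree, tree_distances


class TestPairwiseDistance:
    def test_identical_rows_are_zero(self):
        aln = Alignment(ids=["a", "b"], rows=["MKV", "MKV"])
        assert pairwise_distance(aln).matrix[0, 1] == 0.0

    def test_poisson_closed_form(self):
        aln = Alignment(ids=["a", "b"], rows=["AAAA", "AAAC"])
        p = pairwise_distance(aln, model="p").matrix[0, 1]
        d = pairwise_distance(aln, model="poisson").matrix[0, 1]
        assert p == pytest.approx(0.25)
        assert d == pytest.approx(-math.log(0.75), abs=1e-10)

    def test_pairwise_deletion(self):
        aln = Alignment(ids=["a", "b"], rows=["A-AA", "AGAC"])
        p = pairwise_distance(aln, model="p").matrix[0, 1]
        assert p == pytest.approx(1 / 3)

    def test_saturation_error(self):
        aln = Alignment(ids=["a", "b"], rows=["AAAA", "CCCC"])
        with pytest.raises(ValueError, match="[Ss]aturat"):
            pairwise_distance(aln, model="poisson")

    def test_no_shared_columns_error(self):
        aln = Alignment(ids=["a", "b"], rows=["A--", "-AA"])
        with pytest.raises(ValueError, match="shared"):
            pairwise_distance(aln)

    def test_poisson_never_below_p(self, rng):
        for _ in range(20):
            p = rng.uniform(0.01, 0.95)
            assert -math.log(1 - p) >= p


def quartet_brute_force(ids, D):
    """Least-squares fit of all 3 quartet topologies; returns the best
    topology as a frozenset split and its fitted branch lengths."""
    (a, b, c, d) = range(4)
    best = None
    for (i, j), (k, l) in [((a, b), (c, d)), ((a, c), (b, d)), ((a, d), (b, c))]:
        # tree ((i,j),(k,l)) with 5 edges: solve least squares
        A = []
        y = []
        pairs = list(itertools.combinations(range(4), 2))
        for (x, z) in pairs:
            row = [0.0] * 5  # ei, ej, ek, el, middle
            for idx, leaf in ((0, i), (1, j), (2, k), (3, l)):
                if leaf in (x, z):
                    row[idx] = 1.0
            same_side = ({x, z} == {i, j}) or ({x, z} == {k, l})
            if not same_side:
                row[4] = 1.0
            A.append(row)
            y.append(D[x, z])
        coef, res, *_ = np.linalg.lstsq(np.array(A), np.array(y), rcond=None)
        sse = float(((np.array(A) @ coef - y) ** 2).sum())
        if best is None or sse < best[0]:
            best = (sse, frozenset({ids[i], ids[j]}), coef)
    return best


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        D = np.array([[0, 5, 9], [5, 0, 8], [9, 8, 0]], float)
        tree = neighbor_joining(DistanceMatrix(ids=["a", "b", "c"], matrix=D))
        lengths = {c.name: c.length for c in tree.children}
        assert lengths["a"] == pytest.approx(0.5 * (5 + 9 - 8))
        assert lengths["b"] == pytest.approx(0.5 * (5 + 8 - 9))
        assert lengths["c"] == pytest.approx(0.5 * (9 + 8 - 5))

    def test_fewer_than_three_taxa_error(self):
        D = np.zeros((2, 2))
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(ids=["a", "b"], matrix=D))

    def test_four_taxon_additive_recovery_vs_quartet_oracle(self, rng):
        # additive matrix from tree ((A,B),(C,D)) with known lengths
        ea, eb, ec, ed, em = 1.0, 2.0, 3.0, 1.5, 0.8
        ids = ["A", "B", "C", "D"]
        D = np.zeros((4, 4))
        D[0, 1] = ea + eb
        D[0, 2] = ea + em + ec
        D[0, 3] = ea + em + ed
        D[1, 2] = eb + em + ec
        D[1, 3] = eb + em + ed
        D[2, 3] = ec + ed
        D = D + D.T
        tree = neighbor_joining(DistanceMatrix(ids=ids, matrix=D))
        sse, split, coef = quartet_brute_force(ids, D)
        assert sse == pytest.approx(0.0, abs=1e-16)
        assert split in {frozenset({"A", "B"}), frozenset({"C", "D"})}
        keys = set(map(frozenset, bipartitions(tree)))
        assert frozenset({"A", "B"}) in keys or frozenset({"C", "D"}) in keys
        # branch lengths recovered exactly
        total = sum(n.length for n in tree.walk() if n is not tree)
        assert total == pytest.approx(ea + eb + ec + ed + em, abs=1e-9)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_additive_recovery_eight_taxa(self, seed):
        rng = np.random.default_rng(seed)
        gen_tree, names = random_additive_tree(8, rng)
        dists = tree_distances(gen_tree)
        D = np.zeros((8, 8))
        for i, a in enumerate(names):
            for j, b in enumerate(names):
                if i != j:
                    D[i, j] = dists[(a, b)]
        nj = neighbor_joining(DistanceMatrix(ids=names, matrix=D))
        assert robinson_foulds(nj, gen_tree) == 0

    def test_taxon_order_invariance_on_additive_matrix(self, rng):
        gen_tree, names = random_additive_tree(6, rng)
        dists = tree_distances(gen_tree)
        D = np.zeros((6, 6))
        for i, a in enumerate(names):
            for j, b in enumerate(names):
                if i != j:
                    D[i, j] = dists[(a, b)]
        t1 = neighbor_joining(DistanceMatrix(ids=names, matrix=D))
        perm = list(rng.permutation(6))
        names2 = [names[i] for i in perm]
        D2 = D[np.ix_(perm, perm)]
        t2 = neighbor_joining(DistanceMatrix(ids=names2, matrix=D2))
        s1 = sum(n.length for n in t1.walk() if n is not t1)
        s2 = sum(n.length for n in t2.walk() if n is not t2)
        assert s1 == pytest.approx(s2, abs=1e-9)
        assert robinson_foulds(t1, t2) == 0

    def test_agrees_with_skbio_on_random_matrix(self, rng):
        skbio = pytest.importorskip("skbio")
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj as sk_nj

        gen_tree, names = random_additive_tree(7, rng)
        dists = tree_distances(gen_tree)
        D = np.zeros((7, 7))
        for i, a in enumerate(names):
            for j, b in enumerate(names):
                if i != j:
                    D[i, j] = dists[(a, b)] + 0.01 * (i + j)  # mildly non-additive
        D = 0.5 * (D + D.T)
        mine = neighbor_joining(DistanceMatrix(ids=names, matrix=D))
        theirs = sk_nj(SkDM(D, ids=names))
        their_bips = set()
        all_names = frozenset(names)
        for node in theirs.non_tips():
            side = frozenset(t.name for t in node.tips())
            other = all_names - side
            if len(side) >= 2 and len(other) >= 2:
                their_bips.add(min(side, other,
                                   key=lambda s: (len(s), tuple(sorted(s)))))
        mine_bips = set(bipartitions(mine))
        assert mine_bips == their_bips


class TestBootstrap:
    def test_same_seed_identical_supports(self, rng):
        aln, _ = hierarchical_alignment(rng)
        t1 = bootstrap_support(aln, reps=30, seed=7)
        t2 = bootstrap_support(aln, reps=30, seed=7)
        s1 = sorted(n.support for n in t1.walk() if n.support is not None)
        s2 = sorted(n.support for n in t2.walk() if n.support is not None)
        assert s1 == s2

    def test_structured_clades_strongly_supported(self, rng):
        aln, expected = hierarchical_alignment(rng)
        tree = bootstrap_support(aln, reps=100, seed=11)
        bips = bipartitions(tree)
        for key in expected:
            assert key in bips, f"missing bipartition {set(key)}"
            assert bips[key].support >= 95.0
        for node in tree.walk():
            if node.support is not None:
                assert 0.0 <= node.support <= 100.0

    def test_zero_reps_error(self, rng):
        aln, _ = hierarchical_alignment(rng)
        with pytest.raises(ValueError):
            bootstrap_support(aln, reps=0, seed=1)


def nw_oracle(a, b, match=1.0, mismatch=-1.0, gap=-1.0):
    """Plain dynamic-programming global alignment score (linear gaps)."""
    n, m = len(a), len(b)
    F = np.zeros((n + 1, m + 1))
    F[:, 0] = np.arange(n + 1) * gap
    F[0, :] = np.arange(m + 1) * gap
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            F[i, j] = max(F[i - 1, j - 1] + s, F[i - 1, j] + gap,
                          F[i, j - 1] + gap)
    return F[n, m]


class TestGlobalAlign:
    def test_identical_sequences_full_identity(self):
        _, _, _, ident = global_align("MKVLLA", "MKVLLA")
        assert ident == 100.00

    def test_score_matches_dp_oracle(self):
        a, b = "GATTACA", "GCATGCT"
        _, _, score, _ = global_align(a, b, match=1, mismatch=-1,
                                      gap_open=-1, gap_extend=-1)
        assert score == nw_oracle(a, b)

    def test_empty_input_error(self):
        with pytest.raises(ValueError):
            global_align("", "A")
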