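"""Birth-death model of gene-family size evolution on a dated species tree.

Each gene duplicates and is lost at the same per-gene rate lambda (events
per gene per million years), giving the critical linear birth-death
process used for gene gain/loss reconstruction.  The transition
probability from i to j genes over time t has the closed form

    P(i -> j) = sum_k C(i, k) C(i + j - k - 1, j - k)
                alpha^(i + j - 2k) (1 - 2 alpha)^k,     alpha = lt / (1 + lt)

(state 0 is absorbing).  Family likelihoods come from pruning over integer
states with a uniform root prior on [1, 2 * max leaf count]; lambda is
fitted by bounded scalar search, and ancestral counts are per-node
max-marginal posteriors from an up-down pass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.linalg import expm as _expm
from scipy.special import gammaln

from .phylo import TreeNode

__all__ = [
    "BDParams",
    "AncestralMap",
    "bd_transition_prob",
    "bd_transition_matrix",
    "family_likelihood",
    "fit_lambda",
    "ancestral_counts",
]


@dataclass(frozen=True)
class BDParams:
    lam: float  # per-gene gain/loss rate, events per gene per My
    max_count: int = 100

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lambda must be non-negative")
        if self.max_count < 2:
            raise ValueError("max_count must be at least 2")


@dataclass
class AncestralMap:
    node_counts: Dict[str, int]          # node label -> inferred count
    branch_deltas: Dict[str, int]        # child label -> child - parent
    tree: TreeNode
    lam: float
    node_posteriors: Dict[str, np.ndarray] = field(default_factory=dict)


def _log_binom(n: float, k: float) -> float:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def bd_transition_prob(i: int, j: int, params: BDParams, t: float) -> float:
    """P(j descendants | i genes, time t) under the critical BDP."""
    if t < 0:
        raise ValueError("time must be non-negative")
    if not (0 <= i <= params.max_count and 0 <= j <= params.max_count):
        raise ValueError("counts must lie in [0, max_count]")
    if t == 0 or params.lam == 0:
        return 1.0 if i == j else 0.0
    if i == 0:
        return 1.0 if j == 0 else 0.0
    lt = params.lam * t
    alpha = lt / (1.0 + lt)
    if j == 0:
        return alpha ** i
    total = 0.0
    one_minus_2a = 1.0 - 2.0 * alpha
    for k in range(min(i, j) + 1):
        log_coeff = _log_binom(i, k) + _log_binom(i + j - k - 1, j - k)
        power_a = (i + j - 2 * k) * math.log(alpha)
        term = math.exp(log_coeff + power_a)
        if k:
            term *= one_minus_2a ** k
        total += term
    return max(total, 0.0)


def bd_transition_matrix(
    params: BDParams, t: float, method: str = "closed_form"
) -> np.ndarray:
    """Transition matrix over states 0..max_count.

    method 'closed_form' uses the analytic sum; 'expm' exponentiates the
    truncated tridiagonal generator (birth suppressed at the top state so
    rows stay stochastic under truncation).
    """
    m = params.max_count
    if method == "closed_form":
        if t == 0 or params.lam == 0:
            return np.eye(m + 1)
        lt = params.lam * t
        alpha = lt / (1.0 + lt)
        # Exact per-gene descendant law of the critical BDP:
        #   P(0) = alpha, P(j >= 1) = (1 - alpha)^2 alpha^(j-1).
        # Row i is its i-fold convolution — an all-positive, numerically
        # stable equivalent of the alternating binomial sum.
        j = np.arange(m + 1)
        p1 = np.empty(m + 1)
        p1[0] = alpha
        p1[1:] = (1.0 - alpha) ** 2 * alpha ** (j[1:] - 1.0)
        P = np.zeros((m + 1, m + 1))
        P[0, 0] = 1.0
        P[1] = p1
        for i in range(2, m + 1):
            P[i] = np.convolve(P[i - 1], p1)[: m + 1]
        return P
    if method == "expm":
        Q = np.zeros((m + 1, m + 1))
        for i in range(1, m + 1):
            rate = params.lam * i
            Q[i, i - 1] = rate
            if i < m:
                Q[i, i + 1] = rate
            Q[i, i] = -(Q[i, i - 1] + (Q[i, i + 1] if i < m else 0.0))
        return _expm(Q * t)
    raise ValueError(f"unknown method {method!r}")


@lru_cache(maxsize=4096)
def _cached_matrix(lam: float, t: float, max_count: int) -> np.ndarray:
    P = bd_transition_matrix(BDParams(lam=lam, max_count=max_count), t)
    P.setflags(write=False)
    return P


def _label_nodes(tree: TreeNode) -> None:
    """Give every unnamed internal node a stable label N0, N1, ..."""
    k = 0
    for node in tree.walk():
        if node.name is None:
            node.name = f"N{k}"
            k += 1


def _check_inputs(
    tree: TreeNode, counts: Dict[str, int], params: BDParams
) -> List[str]:
    leaves = tree.leaf_names()
    missing = [l for l in leaves if l not in counts]
    if missing:
        raise ValueError(f"missing leaf counts for: {missing}")
    for l in leaves:
        if counts[l] < 0:
            raise ValueError(f"negative count for {l}")
        if counts[l] > params.max_count:
            raise ValueError(
                f"count {counts[l]} for {l} exceeds max_count {params.max_count}"
            )
    return leaves


def _root_prior(counts: Dict[str, int], max_count: int) -> np.ndarray:
    """Uniform prior on [1, 2 * max leaf count]."""
    hi = min(2 * max(counts.values()), max_count)
    hi = max(hi, 1)
    prior = np.zeros(max_count + 1)
    prior[1:hi + 1] = 1.0 / hi
    return prior


class _BDEngine:
    """Cached pruning machinery for one (tree, params) pair."""

    def __init__(
        self,
        tree: TreeNode,
        counts: Dict[str, int],
        params: BDParams,
        root_prior: Optional[np.ndarray] = None,
    ):
        _check_inputs(tree, counts, params)
        self.tree = tree
        self.counts = counts
        self.params = params
        if root_prior is None:
            self.prior = _root_prior(counts, params.max_count)
        else:
            prior = np.asarray(root_prior, dtype=float)
            if prior.shape != (params.max_count + 1,) or prior.sum() <= 0:
                raise ValueError("root_prior must be a distribution over 0..max_count")
            self.prior = prior / prior.sum()
        self._pcache: Dict[float, np.ndarray] = {}

    def share_cache(self, cache: Dict[float, np.ndarray]) -> None:
        self._pcache = cache

    def P(self, t: float) -> np.ndarray:
        key = round(t, 12)
        if key not in self._pcache:
            self._pcache[key] = _cached_matrix(
                self.params.lam, float(t), self.params.max_count
            )
        return self._pcache[key]

    def up(self) -> Dict[int, np.ndarray]:
        """Partial likelihoods: up[node id][s] = P(data below | state s)."""
        m = self.params.max_count
        out: Dict[int, np.ndarray] = {}

        def rec(node: TreeNode) -> np.ndarray:
            if node.is_leaf():
                v = np.zeros(m + 1)
                v[self.counts[node.name]] = 1.0
            else:
                v = np.ones(m + 1)
                for c in rec_children(node):
                    v = v * c
            out[id(node)] = v
            return v

        def rec_children(node: TreeNode):
            for c in node.children:
                child_up = rec(c)
                yield self.P(c.length) @ child_up

        rec(self.tree)
        return out

    def log_likelihood(self) -> float:
        up = self.up()
        root = up[id(self.tree)]
        like = float(self.prior @ root)
        if like <= 0:
            return -math.inf
        return math.log(like)


def family_likelihood(
    tree: TreeNode,
    counts: Dict[str, int],
    params: BDParams,
    root_prior: Optional[np.ndarray] = None,
) -> float:
    """Log-likelihood of one family's leaf counts under the birth-death model.

    ``root_prior`` is a distribution over states 0..max_count; the default
    is uniform on [1, 2 * max leaf count].
    """
    return _BDEngine(tree, counts, params, root_prior).log_likelihood()


def fit_lambda(
    tree: TreeNode,
    counts_set: Sequence[Dict[str, int]],
    max_count: int = 100,
    lam_max: float = 0.05,
) -> Tuple[float, bool]:
    """Maximum-likelihood lambda over one or many families.

    Returns (lambda_hat, at_boundary); at_boundary is True when the
    optimum sits at (or numerically against) lambda = 0, e.g. when every
    family has identical counts across all leaves.
    """
    from scipy.optimize import minimize_scalar

    if not counts_set:
        raise ValueError("need at least one family")
    leaves = tree.leaf_names()
    if all(len({c[l] for l in leaves}) == 1 for c in counts_set):
        return 0.0, True

    def negloglik(lam: float) -> float:
        params = BDParams(lam=max(lam, 1e-9), max_count=max_count)
        cache: Dict[float, np.ndarray] = {}
        total = 0.0
        for c in counts_set:
            engine = _BDEngine(tree, c, params)
            engine.share_cache(cache)
            total += engine.log_likelihood()
        return -total

    res = minimize_scalar(
        negloglik, bounds=(1e-6, lam_max), method="bounded",
        options={"xatol": 1e-6},
    )
    lam_hat = float(res.x)
    boundary = lam_hat <= 2e-6 or lam_hat >= lam_max - 1e-6
    return lam_hat, boundary


def ancestral_counts(
    tree: TreeNode, counts: Dict[str, int], lam: float, max_count: int = 100
) -> AncestralMap:
    """Max-marginal-posterior integer count per node plus branch deltas.

    Marginal posteriors come from the standard up-down pass: the root
    posterior is prior * up; each child's outside message combines its
    parent's outside with the siblings' upward messages through the
    branch transition matrix.
    """
    import copy

    tree = copy.deepcopy(tree)
    _label_nodes(tree)
    params = BDParams(lam=lam, max_count=max_count)
    engine = _BDEngine(tree, counts, params)
    up = engine.up()

    posteriors: Dict[str, np.ndarray] = {}
    node_counts: Dict[str, int] = {}

    def normalize(v: np.ndarray) -> np.ndarray:
        s = v.sum()
        if s <= 0:
            raise ValueError("zero posterior mass; increase max_count")
        return v / s

    outside: Dict[int, np.ndarray] = {id(tree): engine.prior.copy()}

    def rec(node: TreeNode) -> None:
        post = normalize(outside[id(node)] * up[id(node)])
        posteriors[node.name] = post
        if node.is_leaf():
            node_counts[node.name] = counts[node.name]
        else:
            node_counts[node.name] = int(np.argmax(post))
        for c in node.children:
            sib_product = outside[id(node)].copy()
            for s in node.children:
                if s is c:
                    continue
                sib_product = sib_product * (engine.P(s.length) @ up[id(s)])
            outside[id(c)] = sib_product @ engine.P(c.length)
            rec(c)

    rec(tree)

    deltas: Dict[str, int] = {}

    def walk_deltas(node: TreeNode) -> None:
        for c in node.children:
            deltas[c.name] = node_counts[c.name] - node_counts[node.name]
            walk_deltas(c)

    walk_deltas(tree)
    return AncestralMap(
        node_counts=node_counts,
        branch_deltas=deltas,
        tree=tree,
        lam=lam,
        node_posteriors=posteriors,
    )
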