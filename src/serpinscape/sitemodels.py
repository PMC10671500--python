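"""Codon site models of selection: GY94 rate matrices, M0/M3/M7/M8 fits,
likelihood-ratio tests, and Bayes-empirical-Bayes site detection.

The substitution process is a Goldman–Yang-style codon model over the 61
sense codons: the rate from codon i to codon j is zero unless they differ
at exactly one position, and otherwise proportional to the target codon's
equilibrium frequency (F3x4), multiplied by kappa for transitions and by
omega for nonsynonymous changes.  Site-to-site variation in omega is a
finite mixture: one class (M0), three free classes (M3), ten
equal-probability beta quantiles on [0, 1] (M7), or the beta plus one
class with omega >= 1 (M8).  Branch lengths are measured in expected
substitutions per codon site under the fitted mixture; they are estimated
under M0 and then held fixed for the mixture models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats

from ._constants import (
    GAP_CODON,
    GENETIC_CODE,
    SENSE_CODONS,
    CODON_INDEX,
    is_transition,
)
from .codon import CodonAlignment
from .phylo import TreeNode

__all__ = [
    "SiteModelFit",
    "LRTResult",
    "SiteResult",
    "f3x4_frequencies",
    "uniform_codon_frequencies",
    "build_rate_matrix",
    "transition_matrices",
    "mixture_scale",
    "log_likelihood",
    "fit_site_model",
    "fit_site_models",
    "lrt",
    "beb_sites",
]

N_CODONS = len(SENSE_CODONS)
DEFAULT_NCAT = 10  # beta discretization and BEB grid resolution

# --- static structure of the codon graph -------------------------------

_single = np.zeros((N_CODONS, N_CODONS), dtype=bool)
_ts = np.zeros((N_CODONS, N_CODONS), dtype=bool)
_nonsyn = np.zeros((N_CODONS, N_CODONS), dtype=bool)
for _i, _ci in enumerate(SENSE_CODONS):
    for _j, _cj in enumerate(SENSE_CODONS):
        if _i == _j:
            continue
        diffs = [p for p in range(3) if _ci[p] != _cj[p]]
        if len(diffs) != 1:
            continue
        _single[_i, _j] = True
        p = diffs[0]
        _ts[_i, _j] = is_transition(_ci[p], _cj[p])
        _nonsyn[_i, _j] = GENETIC_CODE[_ci] != GENETIC_CODE[_cj]
SINGLE_STEP, TRANSITION, NONSYNONYMOUS = _single, _ts, _nonsyn
del _single, _ts, _nonsyn, _i, _j, _ci, _cj


def uniform_codon_frequencies() -> np.ndarray:
    return np.full(N_CODONS, 1.0 / N_CODONS)


def f3x4_frequencies(aln: CodonAlignment, floor: float = 1e-4) -> np.ndarray:
    """F3x4 codon frequencies from position-specific nucleotide counts.

    Each position-specific nucleotide frequency is floored to keep every
    sense codon's frequency strictly positive.
    """
    counts = np.zeros((3, 4))
    order = {"A": 0, "C": 1, "G": 2, "T": 3}
    for row in aln.rows:
        for codon in row:
            if codon == GAP_CODON:
                continue
            for pos in range(3):
                counts[pos, order[codon[pos]]] += 1
    if counts.sum() == 0:
        raise ValueError("empty alignment: no codons to count")
    freqs = counts / counts.sum(axis=1, keepdims=True)
    freqs = np.maximum(freqs, floor)
    freqs /= freqs.sum(axis=1, keepdims=True)
    pi = np.array(
        [
            freqs[0, order[c[0]]] * freqs[1, order[c[1]]] * freqs[2, order[c[2]]]
            for c in SENSE_CODONS
        ]
    )
    return pi / pi.sum()


def build_rate_matrix(
    omega: float, kappa: float, pi: np.ndarray
) -> Tuple[np.ndarray, float]:
    """Unscaled GY94 generator and its mean substitution rate under pi."""
    Q = np.where(SINGLE_STEP, pi[None, :], 0.0)
    Q = Q * np.where(TRANSITION, kappa, 1.0) * np.where(NONSYNONYMOUS, omega, 1.0)
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    rate = float(-(pi * np.diag(Q)).sum())
    return Q, rate


def mixture_scale(
    omegas: Sequence[float], proportions: Sequence[float], kappa: float, pi: np.ndarray
) -> float:
    """Common scale factor: mean rate over site classes (one unit of branch
    length = one expected substitution per codon site under the mixture)."""
    return float(
        sum(
            p * build_rate_matrix(w, kappa, pi)[1]
            for w, p in zip(omegas, proportions)
        )
    )


def _eig_decompose(omegas: Sequence[float], kappa: float, pi: np.ndarray):
    """Batched symmetric eigendecomposition of the class generators."""
    sqrt_pi = np.sqrt(pi)
    Qs = np.stack([build_rate_matrix(w, kappa, pi)[0] for w in omegas])
    S = Qs * (sqrt_pi[None, :, None] / sqrt_pi[None, None, :])
    S = 0.5 * (S + np.transpose(S, (0, 2, 1)))  # symmetrize fp noise
    vals, vecs = np.linalg.eigh(S)
    return vals, vecs, sqrt_pi


def transition_matrices(
    omegas: Sequence[float],
    kappa: float,
    pi: np.ndarray,
    times: Sequence[float],
    scale: Optional[float] = None,
) -> np.ndarray:
    """P[c, b] = expm(Q_c * t_b / scale) for every class c and branch b.

    Returns an array of shape (n_classes, n_branches, 61, 61).
    """
    if scale is None:
        scale = build_rate_matrix(omegas[0], kappa, pi)[1] if len(omegas) == 1 else 1.0
    if scale <= 0:
        raise ValueError("non-positive rate scale")
    vals, vecs, sqrt_pi = _eig_decompose(omegas, kappa, pi)
    times = np.asarray(times, dtype=float)
    if (times < 0).any():
        raise ValueError("negative branch length")
    inv_sqrt = 1.0 / sqrt_pi
    vecsT = np.transpose(vecs, (0, 2, 1))
    out = np.empty((len(omegas), len(times), N_CODONS, N_CODONS))
    for b, t in enumerate(times):
        expd = np.exp(vals * (t / scale))  # (ncls, 61)
        M = np.matmul(vecs * expd[:, None, :], vecsT)
        P = inv_sqrt[None, :, None] * M * sqrt_pi[None, None, :]
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=2, keepdims=True)
        out[:, b] = P
    return out


# --- tree bookkeeping ---------------------------------------------------

class _TreeIndex:
    """Postorder flattening of a TreeNode topology for pruning."""

    def __init__(self, tree: TreeNode, ids: Sequence[str]):
        self.nodes: List[TreeNode] = [n for n in tree.walk()]
        order = {id(n): k for k, n in enumerate(self.nodes)}
        self.parent = {order[id(c)]: order[id(n)] for n in self.nodes for c in n.children}
        self.postorder = sorted(
            range(len(self.nodes)),
            key=lambda k: -_depth(self.nodes[k], tree),
        )
        leaf_names = [n.name for n in self.nodes if n.is_leaf()]
        if sorted(leaf_names) != sorted(ids):
            raise ValueError(
                "tree leaves do not match alignment ids: "
                f"{sorted(leaf_names)} vs {sorted(ids)}"
            )
        self.root_index = order[id(tree)]
        self.branch_nodes = [k for k in range(len(self.nodes)) if k != self.root_index]

    def branch_lengths(self) -> np.ndarray:
        return np.array([self.nodes[k].length for k in self.branch_nodes])

    def set_branch_lengths(self, lengths: Sequence[float]) -> None:
        for k, t in zip(self.branch_nodes, lengths):
            self.nodes[k].length = float(t)


def _depth(node: TreeNode, root: TreeNode) -> int:
    # depth by search; trees here are tiny
    def rec(cur: TreeNode, d: int) -> Optional[int]:
        if cur is node:
            return d
        for c in cur.children:
            r = rec(c, d + 1)
            if r is not None:
                return r
        return None

    return rec(root, 0) or 0


def _leaf_indicators(aln: CodonAlignment) -> Dict[str, np.ndarray]:
    """Per-leaf observed codon indices; -1 marks a gap (uninformative)."""
    out = {}
    for rid, row in zip(aln.ids, aln.rows):
        out[rid] = np.array(
            [CODON_INDEX.get(c, -1) for c in row], dtype=np.intp
        )
    return out


def _site_class_likelihoods(
    index: _TreeIndex,
    indicators: Dict[str, np.ndarray],
    P: np.ndarray,  # (ncls, nbranch, 61, 61)
    pi: np.ndarray,
    n_sites: int,
) -> np.ndarray:
    """Per-class per-site likelihoods f_c(h), shape (ncls, nsites)."""
    ncls = P.shape[0]
    partial: Dict[int, Optional[np.ndarray]] = {}
    branch_pos = {k: b for b, k in enumerate(index.branch_nodes)}
    node_key = {id(n): k for k, n in enumerate(index.nodes)}
    for k in index.postorder:
        node = index.nodes[k]
        if node.is_leaf():
            partial[k] = None  # message computed directly from P rows
            continue
        part = np.ones((ncls, n_sites, N_CODONS))
        for c in node.children:
            ck = node_key[id(c)]
            Pb = P[:, branch_pos[ck]]  # (ncls, 61, 61)
            child_part = partial.pop(ck)
            if child_part is None:
                idx = indicators[c.name]
                # leaf message: msg[cls, s, i] = P[cls, i, codon_s]
                msg = Pb[:, :, np.where(idx < 0, 0, idx)].transpose(0, 2, 1)
                if (idx < 0).any():
                    msg = msg.copy()
                    msg[:, idx < 0, :] = 1.0  # gap: sums over all states
                part = part * msg
            else:
                part = part * np.matmul(
                    child_part, np.transpose(Pb, (0, 2, 1))
                )
        partial[k] = part
    root_part = partial[index.root_index]
    return np.einsum("csk,k->cs", root_part, pi)


def log_likelihood(
    aln: CodonAlignment,
    tree: TreeNode,
    omegas: Sequence[float],
    proportions: Sequence[float],
    kappa: float,
    pi: Optional[np.ndarray] = None,
) -> float:
    """Mixture log-likelihood at given parameters (branch lengths from tree)."""
    pi = f3x4_frequencies(aln) if pi is None else pi
    index = _TreeIndex(tree, aln.ids)
    indicators = _leaf_indicators(aln)
    scale = mixture_scale(omegas, proportions, kappa, pi)
    P = transition_matrices(omegas, kappa, pi, index.branch_lengths(), scale)
    f = _site_class_likelihoods(index, indicators, P, pi, aln.n_sites)
    mix = np.asarray(proportions) @ f
    return float(np.log(np.maximum(mix, 1e-300)).sum())


@dataclass
class SiteModelFit:
    model: str
    lnl: float
    kappa: float
    omegas: List[float]
    proportions: List[float]
    parameters: Dict[str, float]
    branch_lengths: List[float]
    pi: np.ndarray
    site_class_posteriors: Optional[np.ndarray] = None  # (ncls, nsites)
    converged: bool = True
    diagnostics: Dict[str, object] = field(default_factory=dict)
    # Rate normalization tying branch lengths to one time unit: the mean
    # substitution rate under the M0 fit (see fit_site_models).
    rate_scale: float = 1.0


@dataclass(frozen=True)
class LRTResult:
    statistic: float
    df: int
    p_value: float
    significant_5pct: bool
    significant_1pct: bool
    family_size: int


@dataclass(frozen=True)
class SiteResult:
    site: int  # 1-based codon site
    posterior: float
    pss: bool


def _beta_bin_omegas(p: float, q: float, ncat: int) -> np.ndarray:
    """Median omega of each of ncat equal-probability beta bins."""
    quantiles = (2 * np.arange(ncat) + 1) / (2 * ncat)
    w = stats.beta.ppf(quantiles, p, q)
    return np.clip(w, 1e-8, 1.0 - 1e-9)


class _Objective:
    """Shared state for one (alignment, tree) optimization problem.

    Eigendecompositions of the class generators are cached per (omega,
    kappa), so likelihood evaluations that perturb only mixture weights or
    a subset of classes (as numeric gradients do) pay only for pruning.
    """

    def __init__(self, aln: CodonAlignment, tree: TreeNode, pi: np.ndarray):
        self.aln = aln
        self.pi = pi
        self.sqrt_pi = np.sqrt(pi)
        self.index = _TreeIndex(tree, aln.ids)
        self.indicators = _leaf_indicators(aln)
        self.n_sites = aln.n_sites
        self.n_eval = 0
        self._eig_cache: Dict[Tuple[float, float], Tuple[np.ndarray, np.ndarray]] = {}

    def _eig(self, omega: float, kappa: float):
        key = (float(omega), float(kappa))
        hit = self._eig_cache.get(key)
        if hit is None:
            Q, _ = build_rate_matrix(omega, kappa, self.pi)
            S = Q * (self.sqrt_pi[:, None] / self.sqrt_pi[None, :])
            S = 0.5 * (S + S.T)
            hit = np.linalg.eigh(S)
            if len(self._eig_cache) > 1024:
                self._eig_cache.clear()
            self._eig_cache[key] = hit
        return hit

    def _transitions(
        self,
        omegas: Sequence[float],
        kappa: float,
        times: np.ndarray,
        scale: float,
    ) -> np.ndarray:
        vals = np.empty((len(omegas), N_CODONS))
        vecs = np.empty((len(omegas), N_CODONS, N_CODONS))
        for c, w in enumerate(omegas):
            vals[c], vecs[c] = self._eig(w, kappa)
        vecsT = np.transpose(vecs, (0, 2, 1))
        inv_sqrt = 1.0 / self.sqrt_pi
        out = np.empty((len(omegas), len(times), N_CODONS, N_CODONS))
        for b, t in enumerate(times):
            expd = np.exp(vals * (t / scale))
            M = np.matmul(vecs * expd[:, None, :], vecsT)
            P = inv_sqrt[None, :, None] * M * self.sqrt_pi[None, None, :]
            np.clip(P, 0.0, None, out=P)
            P /= P.sum(axis=2, keepdims=True)
            out[:, b] = P
        return out

    def site_likelihoods(
        self,
        omegas: Sequence[float],
        kappa: float,
        times: Sequence[float],
        scale: Optional[float] = None,
    ) -> np.ndarray:
        """Per-class per-site likelihoods f_c(h) at fixed branch lengths."""
        times = np.asarray(times, dtype=float)
        if scale is None:
            scale = build_rate_matrix(omegas[0], kappa, self.pi)[1]
        P = self._transitions(omegas, kappa, times, scale)
        return _site_class_likelihoods(
            self.index, self.indicators, P, self.pi, self.n_sites
        )

    def lnl(
        self,
        omegas: Sequence[float],
        proportions: Sequence[float],
        kappa: float,
        times: Sequence[float],
        scale: Optional[float] = None,
    ) -> float:
        self.n_eval += 1
        f = self.site_likelihoods(omegas, kappa, times, scale)
        mix = np.asarray(proportions) @ f
        return float(np.log(np.maximum(mix, 1e-300)).sum())

    def class_posteriors(
        self,
        omegas: Sequence[float],
        proportions: Sequence[float],
        kappa: float,
        times: Sequence[float],
        scale: Optional[float] = None,
    ) -> np.ndarray:
        f = self.site_likelihoods(omegas, kappa, times, scale)
        w = np.asarray(proportions)[:, None] * f
        return w / np.maximum(w.sum(axis=0, keepdims=True), 1e-300)


def _softmax(z: np.ndarray) -> np.ndarray:
    e = np.exp(z - z.max())
    return e / e.sum()


_LOG_T_BOUNDS = (math.log(1e-4), math.log(30.0))
_LOG_K_BOUNDS = (math.log(0.05), math.log(50.0))
_LOG_W_BOUNDS = (math.log(1e-5), math.log(50.0))


def _fit_m0(obj: _Objective, t_init: np.ndarray, seed: int) -> SiteModelFit:
    nb = len(obj.index.branch_nodes)

    def negloglik(x):
        times = np.exp(x[:nb])
        kappa = math.exp(x[nb])
        omega = math.exp(x[nb + 1])
        return -obj.lnl([omega], [1.0], kappa, times)

    bounds = [_LOG_T_BOUNDS] * nb + [_LOG_K_BOUNDS, _LOG_W_BOUNDS]
    rng = np.random.default_rng(seed)
    starts = [
        np.concatenate([np.log(t_init), [math.log(2.0), math.log(0.4)]]),
        np.concatenate(
            [np.log(np.maximum(t_init * rng.uniform(0.5, 2.0, nb), 1e-3)),
             [math.log(1.5), math.log(1.0)]]
        ),
    ]
    best = None
    for x0 in starts:
        res = optimize.minimize(
            negloglik, x0, method="L-BFGS-B", bounds=bounds,
            options={"maxfun": 2000, "ftol": 1e-9},
        )
        if best is None or res.fun < best.fun:
            best = res
    times = np.exp(best.x[:nb])
    kappa = math.exp(best.x[nb])
    omega = math.exp(best.x[nb + 1])
    post = obj.class_posteriors([omega], [1.0], kappa, times)
    return SiteModelFit(
        model="M0",
        lnl=-best.fun,
        kappa=kappa,
        omegas=[omega],
        proportions=[1.0],
        parameters={"omega": omega, "kappa": kappa},
        branch_lengths=list(times),
        pi=obj.pi,
        site_class_posteriors=post,
        converged=bool(best.success or best.fun < math.inf),
        diagnostics={"n_eval": obj.n_eval, "starts": len(starts)},
    )


def _fit_m3(
    obj: _Objective, times: np.ndarray, m0: SiteModelFit, ncls: int, seed: int,
    scale: float = 1.0,
) -> SiteModelFit:
    def unpack(x):
        omegas = np.exp(x[:ncls])
        props = _softmax(np.concatenate([x[ncls:2 * ncls - 1], [0.0]]))
        kappa = math.exp(x[-1])
        return omegas, props, kappa

    def negloglik(x):
        omegas, props, kappa = unpack(x)
        return -obj.lnl(omegas, props, kappa, times, scale)

    bounds = (
        [_LOG_W_BOUNDS] * ncls + [(-8.0, 8.0)] * (ncls - 1) + [_LOG_K_BOUNDS]
    )
    w0 = m0.parameters["omega"]
    starts = [
        np.concatenate(
            [np.log([max(w0 * f, 1e-4) for f in (0.25, 1.0, 4.0)][:ncls]),
             np.zeros(ncls - 1), [math.log(m0.kappa)]]
        ),
        np.concatenate(
            [np.log(np.clip([0.01, 0.3, 2.0][:ncls], 1e-4, None)),
             np.zeros(ncls - 1), [math.log(m0.kappa)]]
        ),
    ]
    best = None
    for x0 in starts:
        res = optimize.minimize(
            negloglik, x0, method="L-BFGS-B", bounds=bounds,
            options={"maxfun": 2000, "ftol": 1e-9},
        )
        if best is None or res.fun < best.fun:
            best = res
    omegas, props, kappa = unpack(best.x)
    # Nesting guard: M3 with all classes at the M0 omega equals M0.
    lnl = -best.fun
    if lnl < m0.lnl:
        omegas = np.full(ncls, w0)
        props = np.full(ncls, 1.0 / ncls)
        kappa = m0.kappa
        lnl = obj.lnl(omegas, props, kappa, times, scale)
    order = np.argsort(omegas)
    omegas, props = omegas[order], props[order]
    post = obj.class_posteriors(omegas, props, kappa, times, scale)
    return SiteModelFit(
        model="M3",
        lnl=lnl,
        kappa=kappa,
        omegas=list(omegas),
        proportions=list(props),
        parameters={
            **{f"omega{k}": float(w) for k, w in enumerate(omegas)},
            **{f"p{k}": float(p) for k, p in enumerate(props)},
            "kappa": kappa,
        },
        branch_lengths=list(times),
        pi=obj.pi,
        site_class_posteriors=post,
        converged=True,
        diagnostics={"n_eval": obj.n_eval},
    )


def _fit_m7(
    obj: _Objective, times: np.ndarray, m0: SiteModelFit, ncat: int, seed: int,
    scale: float = 1.0,
) -> SiteModelFit:
    props = np.full(ncat, 1.0 / ncat)

    def negloglik(x):
        p, q, kappa = map(math.exp, x)
        omegas = _beta_bin_omegas(p, q, ncat)
        return -obj.lnl(omegas, props, kappa, times, scale)

    bounds = [(math.log(0.005), math.log(99.0))] * 2 + [_LOG_K_BOUNDS]
    starts = [
        np.array([math.log(0.5), math.log(2.0), math.log(m0.kappa)]),
        np.array([math.log(0.2), math.log(5.0), math.log(m0.kappa)]),
    ]
    best = None
    for x0 in starts:
        res = optimize.minimize(
            negloglik, x0, method="L-BFGS-B", bounds=bounds,
            options={"maxfun": 2000, "ftol": 1e-9},
        )
        if best is None or res.fun < best.fun:
            best = res
    p, q, kappa = map(math.exp, best.x)
    omegas = _beta_bin_omegas(p, q, ncat)
    post = obj.class_posteriors(omegas, props, kappa, times, scale)
    return SiteModelFit(
        model="M7",
        lnl=-best.fun,
        kappa=kappa,
        omegas=list(omegas),
        proportions=list(props),
        parameters={"p": p, "q": q, "kappa": kappa},
        branch_lengths=list(times),
        pi=obj.pi,
        site_class_posteriors=post,
        converged=True,
        diagnostics={"n_eval": obj.n_eval},
    )


def _fit_m8(
    obj: _Objective,
    times: np.ndarray,
    m0: SiteModelFit,
    m7: Optional[SiteModelFit],
    ncat: int,
    seed: int,
    scale: float = 1.0,
) -> SiteModelFit:
    def unpack(x):
        p, q = math.exp(x[0]), math.exp(x[1])
        p0 = 1.0 / (1.0 + math.exp(-x[2]))
        ws = 1.0 + math.exp(x[3])
        kappa = math.exp(x[4])
        return p, q, p0, ws, kappa

    def mixture(p, q, p0, ws):
        omegas = np.concatenate([_beta_bin_omegas(p, q, ncat), [ws]])
        props = np.concatenate([np.full(ncat, p0 / ncat), [1.0 - p0]])
        return omegas, props

    def negloglik(x):
        p, q, p0, ws, kappa = unpack(x)
        omegas, props = mixture(p, q, p0, ws)
        return -obj.lnl(omegas, props, kappa, times, scale)

    bounds = [
        (math.log(0.005), math.log(99.0)),
        (math.log(0.005), math.log(99.0)),
        (-12.0, 12.0),
        (math.log(1e-6), math.log(30.0)),
        _LOG_K_BOUNDS,
    ]
    if m7 is not None:
        p7, q7 = m7.parameters["p"], m7.parameters["q"]
        k7 = m7.kappa
    else:
        p7, q7, k7 = 0.5, 2.0, m0.kappa
    starts = [
        np.array([math.log(p7), math.log(q7), math.log(0.95 / 0.05),
                  math.log(1.0), math.log(k7)]),
        np.array([math.log(p7), math.log(q7), math.log(0.85 / 0.15),
                  math.log(4.0), math.log(k7)]),
    ]
    best = None
    for x0 in starts:
        res = optimize.minimize(
            negloglik, x0, method="L-BFGS-B", bounds=bounds,
            options={"maxfun": 2000, "ftol": 1e-9},
        )
        if best is None or res.fun < best.fun:
            best = res
    p, q, p0, ws, kappa = unpack(best.x)
    lnl = -best.fun
    if m7 is not None and lnl < m7.lnl:
        # Nested limit p0 -> 1 reduces M8 to M7 exactly.
        p, q, p0, ws, kappa = p7, q7, 1.0 - 1e-9, 1.0, k7
        omegas, props = mixture(p, q, p0, ws)
        lnl = obj.lnl(omegas, props, kappa, times, scale)
        lnl = max(lnl, m7.lnl)
    omegas, props = mixture(p, q, p0, ws)
    post = obj.class_posteriors(omegas, props, kappa, times, scale)
    return SiteModelFit(
        model="M8",
        lnl=lnl,
        kappa=kappa,
        omegas=list(omegas),
        proportions=list(props),
        parameters={"p0": p0, "p": p, "q": q, "p1": 1.0 - p0,
                    "omega_s": ws, "kappa": kappa},
        branch_lengths=list(times),
        pi=obj.pi,
        site_class_posteriors=post,
        converged=True,
        diagnostics={"n_eval": obj.n_eval},
    )


def _initial_branch_lengths(aln: CodonAlignment, index: _TreeIndex) -> np.ndarray:
    """Rough per-branch start from mean pairwise codon difference."""
    nb = len(index.branch_nodes)
    diffs = []
    for i in range(aln.n_rows):
        for j in range(i + 1, aln.n_rows):
            shared = same = 0
            for a, b in zip(aln.rows[i], aln.rows[j]):
                if a == GAP_CODON or b == GAP_CODON:
                    continue
                shared += 1
                same += a == b
            if shared:
                diffs.append(1.0 - same / shared)
    mean_p = float(np.mean(diffs)) if diffs else 0.1
    per_branch = max(mean_p, 0.02)
    return np.full(nb, per_branch)


def fit_site_models(
    aln: CodonAlignment,
    tree: TreeNode,
    models: Sequence[str] = ("M0", "M3", "M7", "M8"),
    ncat: int = DEFAULT_NCAT,
    seed: int = 0,
) -> Dict[str, SiteModelFit]:
    """Fit a set of site models, sharing the M0 branch lengths.

    M0 is always fitted first (jointly with branch lengths); M3/M7/M8 hold
    those branch lengths fixed.  M8's start set includes the fitted M7
    parameters so the nesting lnL(M8) >= lnL(M7) holds after polishing.
    """
    for m in models:
        if m not in {"M0", "M3", "M7", "M8"}:
            raise ValueError(f"unknown site model {m!r}")
    if aln.n_rows < 2:
        raise ValueError("site models need at least 2 sequences")
    import copy

    pi = f3x4_frequencies(aln)
    work_tree = copy.deepcopy(tree)  # fitted branch lengths live on a copy
    obj = _Objective(aln, work_tree, pi)
    t0 = _initial_branch_lengths(aln, obj.index)
    fits: Dict[str, SiteModelFit] = {}
    m0 = _fit_m0(obj, t0, seed)
    fits["M0"] = m0
    times = np.asarray(m0.branch_lengths)
    obj.index.set_branch_lengths(times)
    # One time unit for all models: the M0 mean substitution rate.  The
    # mixtures inherit the M0-calibrated branch lengths unchanged, so the
    # nested comparisons stay on a common footing.
    scale0 = build_rate_matrix(m0.parameters["omega"], m0.kappa, pi)[1]
    if "M3" in models:
        fits["M3"] = _fit_m3(obj, times, m0, 3, seed, scale0)
    m7 = None
    if "M7" in models or "M8" in models:
        m7 = _fit_m7(obj, times, m0, ncat, seed, scale0)
        if "M7" in models:
            fits["M7"] = m7
    if "M8" in models:
        fits["M8"] = _fit_m8(obj, times, m0, m7, ncat, seed, scale0)
    for fit in fits.values():
        fit.rate_scale = scale0
    return {m: fits[m] for m in models}


def fit_site_model(
    aln: CodonAlignment,
    tree: TreeNode,
    model: str = "M0",
    ncat: int = DEFAULT_NCAT,
    seed: int = 0,
) -> SiteModelFit:
    """Fit a single site model (M0 is pre-fitted internally for mixtures)."""
    if model in {"M7", "M8"} and aln.n_rows < 3:
        raise ValueError(f"{model} needs at least 3 sequences")
    models = (model,) if model == "M0" else ("M0", model)
    return fit_site_models(aln, tree, models=models, ncat=ncat, seed=seed)[model]


def lrt(
    null_lnl: float,
    alt_lnl: float,
    df: int,
    family_size: int = 1,
) -> LRTResult:
    """Likelihood-ratio test of nested site models.

    The statistic 2(alt - null) is clipped at zero (optimizer noise);
    significance flags apply a Bonferroni correction over ``family_size``
    simultaneous comparisons.
    """
    if df < 1:
        raise ValueError("degrees of freedom must be >= 1")
    if family_size < 1:
        raise ValueError("family_size must be >= 1")
    stat = max(0.0, 2.0 * (alt_lnl - null_lnl))
    p = float(stats.chi2.sf(stat, df)) if stat > 0 else 1.0
    return LRTResult(
        statistic=stat,
        df=df,
        p_value=p,
        significant_5pct=p < 0.05 / family_size,
        significant_1pct=p < 0.01 / family_size,
        family_size=family_size,
    )


# --- Bayes empirical Bayes ---------------------------------------------

def _beb_grids(ncat: int):
    p0_grid = (2 * np.arange(ncat) + 1) / (2 * ncat)
    pq_grid = np.exp(np.linspace(math.log(0.1), math.log(16.0), ncat))
    ws_grid = 1.0 + (2 * np.arange(ncat) + 1) / (2 * ncat) * 10.0  # (1, 11]
    return p0_grid, pq_grid, ws_grid


def beb_sites(
    m8_fit: SiteModelFit,
    aln: CodonAlignment,
    tree: TreeNode,
    ncat: int = DEFAULT_NCAT,
    threshold: float = 0.95,
) -> List[SiteResult]:
    """Posterior probability per site of the omega > 1 class under M8,
    averaging over a uniform prior grid on (p0, p, q, omega_s).

    Branch lengths and kappa are held at their M8 estimates.  Each (p, q)
    grid cell represents its beta component with the same ``ncat``
    equal-probability quantile bins the fitter uses, so the grid model
    family is exactly the fitted one; a site is flagged as positively
    selected (PSS) at posterior >= ``threshold``.
    """
    if not m8_fit.converged:
        raise ValueError("BEB requires a converged M8 fit")
    if m8_fit.model != "M8":
        raise ValueError("beb_sites expects an M8 fit")
    import copy

    pi = m8_fit.pi
    work_tree = copy.deepcopy(tree)
    obj = _Objective(aln, work_tree, pi)
    obj.index.set_branch_lengths(m8_fit.branch_lengths)
    times = np.asarray(m8_fit.branch_lengths)
    kappa = m8_fit.kappa
    # Same rate normalization as the fit, so grid points share its time unit.
    scale = m8_fit.rate_scale

    p0_grid, pq_grid, ws_grid = _beb_grids(ncat)

    F_ws = obj.site_likelihoods(ws_grid, kappa, times, scale)  # (ncat, ns)

    # Beta-averaged site likelihoods per (p, q) cell, using the fitter's
    # equal-probability discretization of each cell's beta.
    n_pq = ncat * ncat
    M = np.empty((n_pq, aln.n_sites))
    k = 0
    for p in pq_grid:
        for q in pq_grid:
            omegas = _beta_bin_omegas(float(p), float(q), ncat)
            f_cell = obj.site_likelihoods(omegas, kappa, times, scale)
            M[k] = f_cell.mean(axis=0)
            k += 1

    ns = aln.n_sites
    p0 = p0_grid[:, None, None, None]          # (ncat,1,1,1)
    Lbeta = M[None, :, None, :]                # (1,n_pq,1,ns)
    Lsel = F_ws[None, None, :, :]              # (1,1,ncat,ns)
    L = p0 * Lbeta + (1.0 - p0) * Lsel          # (ncat,n_pq,ncat,ns)
    L = np.maximum(L, 1e-300)
    loglik = np.log(L).sum(axis=3)             # grid log-likelihoods
    loglik -= loglik.max()
    grid_post = np.exp(loglik)
    grid_post /= grid_post.sum()
    frac_sel = (1.0 - p0) * Lsel / L           # (ncat,n_pq,ncat,ns)
    post_site = np.einsum("ijk,ijks->s", grid_post, frac_sel)
    return [
        SiteResult(site=h + 1, posterior=float(post_site[h]),
                   pss=bool(post_site[h] >= threshold))
        for h in range(ns)
    ]
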