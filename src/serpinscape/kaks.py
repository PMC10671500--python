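"""Pairwise Ka/Ks estimation for paralog pairs, plus the rank-sum group test.

The primary estimator follows the Yang–Nielsen counting strategy: the
transition/transversion ratio kappa is estimated from fourfold-degenerate
and nondegenerate codon positions (K2P-corrected), synonymous and
nonsynonymous site opportunities are weighted by kappa, substitutions are
counted over equally weighted minimal mutation pathways, and the raw
proportions are corrected for multiple hits.  The simpler NG86 estimator
(kappa = 1, Jukes–Cantor correction) is available as a cross-check.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as _st

from ._constants import GAP_CODON, GENETIC_CODE, NUCLEOTIDES, is_transition
from .codon import CodonAlignment
from .records import ProteinRecord

__all__ = [
    "KaKsResult",
    "estimate_kaks",
    "pair_paralogs",
    "rank_sum_test",
]

MIN_SHARED_SITES = 10


@dataclass(frozen=True)
class KaKsResult:
    ka: float
    ks: float
    ratio: Optional[float]  # None when Ks == 0 (undefined)
    kappa: float
    n_sites: int

    @property
    def undefined(self) -> bool:
        return self.ratio is None


def _codon_site_fractions(codon: str, kappa: float) -> float:
    """Synonymous site count of one codon (0..3), kappa-weighted.

    Each position contributes one site, split between synonymous and
    nonsynonymous in proportion to the weighted mutational opportunity;
    mutations to stop codons are excluded from the opportunity.
    """
    aa = GENETIC_CODE[codon]
    syn = 0.0
    for pos in range(3):
        wsum = 0.0
        wsyn = 0.0
        for alt in NUCLEOTIDES:
            if alt == codon[pos]:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1:]
            if GENETIC_CODE[mutant] == "*":
                continue
            w = kappa if is_transition(codon[pos], alt) else 1.0
            wsum += w
            if GENETIC_CODE[mutant] == aa:
                wsyn += w
        if wsum > 0:
            syn += wsyn / wsum
    return syn


def _pathway_counts(c1: str, c2: str) -> Tuple[float, float]:
    """Average synonymous/nonsynonymous substitution counts between two
    codons over equally weighted minimal pathways that avoid stop codons."""
    diff = [p for p in range(3) if c1[p] != c2[p]]
    if not diff:
        return 0.0, 0.0
    syn_tot = 0.0
    non_tot = 0.0
    n_paths = 0
    for order in itertools.permutations(diff):
        cur = c1
        syn = non = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if GENETIC_CODE[nxt] == "*":
                ok = False
                break
            if GENETIC_CODE[nxt] == GENETIC_CODE[cur]:
                syn += 1
            else:
                non += 1
            cur = nxt
        if ok:
            syn_tot += syn
            non_tot += non
            n_paths += 1
    if n_paths == 0:  # all pathways cross a stop; count changes as nonsyn
        return 0.0, float(len(diff))
    return syn_tot / n_paths, non_tot / n_paths


def _degeneracy(codon: str, pos: int) -> int:
    """Number of nucleotide alternatives at ``pos`` that keep the amino acid."""
    aa = GENETIC_CODE[codon]
    return sum(
        1
        for alt in NUCLEOTIDES
        if alt != codon[pos]
        and GENETIC_CODE[codon[:pos] + alt + codon[pos + 1:]] == aa
    )


def _k2p_kappa(ts: int, tv: int, n: int) -> Optional[float]:
    """K2P-corrected transition/transversion *rate* ratio from counts at n sites."""
    if n == 0:
        return None
    P, Q = ts / n, tv / n
    try:
        a = -0.5 * math.log(1 - 2 * P - Q) + 0.25 * math.log(1 - 2 * Q)
        b = -0.5 * math.log(1 - 2 * Q)
    except ValueError:
        return None
    if b <= 0 or a < 0:
        return None
    # a = alpha*t (rate to the single transition target); b/2 = beta*t
    # (rate per transversion target), so kappa = alpha/beta = 2a/b.
    return 2.0 * a / b


def _estimate_kappa(pairs: Sequence[Tuple[str, str]]) -> float:
    """Kappa from fourfold-degenerate and nondegenerate positions.

    Positions where both codons share the degeneracy class are pooled per
    class, K2P-corrected, and averaged weighted by site counts.  Falls back
    to 2.0 when no class yields a usable estimate.
    """
    counts = {4: [0, 0, 0], 0: [0, 0, 0]}  # class -> [n, ts, tv]
    for c1, c2 in pairs:
        for pos in range(3):
            d1, d2 = _degeneracy(c1, pos), _degeneracy(c2, pos)
            cls1 = 4 if d1 == 3 else (0 if d1 == 0 else None)
            cls2 = 4 if d2 == 3 else (0 if d2 == 0 else None)
            if cls1 is None or cls1 != cls2:
                continue
            counts[cls1][0] += 1
            if c1[pos] != c2[pos]:
                if is_transition(c1[pos], c2[pos]):
                    counts[cls1][1] += 1
                else:
                    counts[cls1][2] += 1
    estimates: List[Tuple[float, int]] = []
    for cls, (n, ts, tv) in counts.items():
        k = _k2p_kappa(ts, tv, n)
        if k is not None:
            estimates.append((k, n))
    if not estimates:
        return 2.0
    total = sum(n for _, n in estimates)
    return sum(k * n for k, n in estimates) / total


def estimate_kaks(pair: CodonAlignment, method: str = "yn") -> KaKsResult:
    """Ka/Ks for a two-row codon alignment.

    method 'yn' uses kappa-weighted site counting with a Jukes–Cantor-style
    multiple-hit correction; 'ng86' fixes kappa at 1 (classic NG86).
    """
    if pair.n_rows != 2:
        raise ValueError("estimate_kaks needs exactly two rows")
    if method not in {"yn", "ng86"}:
        raise ValueError(f"unknown method {method!r}")
    shared = [
        (a, b)
        for a, b in zip(pair.rows[0], pair.rows[1])
        if a != GAP_CODON and b != GAP_CODON
    ]
    if not shared:
        raise ValueError("all-gap pair: no shared codon sites")
    if len(shared) < MIN_SHARED_SITES:
        raise ValueError(
            f"only {len(shared)} shared codon sites; need >= {MIN_SHARED_SITES}"
        )
    kappa = _estimate_kappa(shared) if method == "yn" else 1.0
    S = 0.0
    for c1, c2 in shared:
        S += 0.5 * (
            _codon_site_fractions(c1, kappa) + _codon_site_fractions(c2, kappa)
        )
    N = 3.0 * len(shared) - S
    sd = nd = 0.0
    for c1, c2 in shared:
        s, n = _pathway_counts(c1, c2)
        sd += s
        nd += n
    ps = sd / S if S > 0 else 0.0
    pn = nd / N if N > 0 else 0.0

    def _correct(p: float) -> float:
        x = 1.0 - 4.0 * p / 3.0
        if x <= 0:
            raise ValueError(f"saturated proportion p = {p:.4f}; distance undefined")
        return -0.75 * math.log(x)

    ks = _correct(ps)
    ka = _correct(pn)
    ratio = None if ks == 0.0 else ka / ks
    return KaKsResult(ka=ka, ks=ks, ratio=ratio, kappa=kappa, n_sites=len(shared))


def pair_paralogs(
    records: Iterable[ProteinRecord],
) -> List[Tuple[str, str]]:
    """All unordered within-species id pairs; never pairs across species."""
    by_species: Dict[str, List[str]] = {}
    for r in records:
        by_species.setdefault(r.species, []).append(r.id)
    pairs: List[Tuple[str, str]] = []
    for ids in by_species.values():
        pairs.extend(itertools.combinations(ids, 2))
    return pairs


def _midranks(values: Sequence[float]) -> np.ndarray:
    return _st.rankdata(values)


def rank_sum_test(
    x: Sequence[float],
    y: Sequence[float],
    exact_max_n: int = 12,
) -> Tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Returns (W, p) where W is the rank sum of ``x`` in the pooled sample.
    For combined sample size <= ``exact_max_n`` the p-value is computed by
    full enumeration of rank assignments; otherwise a tie-corrected normal
    approximation is used.
    """
    x = list(map(float, x))
    y = list(map(float, y))
    if not x or not y:
        raise ValueError("both groups must be non-empty")
    m, n = len(x), len(y)
    pooled = x + y
    ranks = _midranks(pooled)
    w_obs = float(ranks[:m].sum())
    mean_w = m * (m + n + 1) / 2.0
    if m + n <= exact_max_n:
        dev = abs(w_obs - mean_w)
        total = 0
        extreme = 0
        for combo in itertools.combinations(range(m + n), m):
            w = float(sum(ranks[k] for k in combo))
            total += 1
            if abs(w - mean_w) >= dev - 1e-9:
                extreme += 1
        return w_obs, extreme / total
    # tie-corrected normal approximation
    nn = m + n
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum())
    var_w = m * n / 12.0 * ((nn + 1) - tie_term / (nn * (nn - 1)))
    if var_w <= 0:
        return w_obs, 1.0
    z = (w_obs - mean_w) / math.sqrt(var_w)
    p = 2.0 * _st.norm.sf(abs(z))
    return w_obs, min(p, 1.0)
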