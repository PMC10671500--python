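"""Synthetic-data generators with recorded ground truth.

Every generator is a deterministic function of its parameters and seed and
returns, alongside the data, a :class:`TruthBundle` holding the planted
truth (hinge positions and P1 classes, per-site omega, internal gene
counts, expression block labels) so downstream recovery can be scored
without re-reading generator internals.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._constants import AMINO_ACIDS, SENSE_CODONS
from .codon import CodonAlignment
from .gainloss import BDParams, _label_nodes
from .phylo import TreeNode
from .records import ProteinRecord
from .sitemodels import (
    _beta_bin_omegas,
    mixture_scale,
    transition_matrices,
    uniform_codon_frequencies,
)

__all__ = [
    "TruthBundle",
    "gen_serpin_proteins",
    "sim_codon_alignment",
    "sim_gene_counts",
    "sim_expression",
]

# Residues planted at P1 for each target-protease class (the named anchors).
P1_BY_CLASS = {
    "trypsin": "RK",
    "chymotrypsin": "LIY",
    "elastase": "AVM",
}

_HINGE_SETS = ("E", "EKR", "G", "TS", None, "AGS", "AGS", "AGS", "AGS")
_DISALLOWED = "P"  # proline matches no hinge position


@dataclass
class TruthBundle:
    """Ground truth and provenance for one generator invocation."""

    generator: str
    seed: int
    params: Dict[str, object]
    truth: Dict[str, object]
    manifest: List[str] = field(default_factory=list)


def _random_protein(rng: np.random.Generator, length: int) -> List[str]:
    return list(rng.choice(list(AMINO_ACIDS), size=length))


def _plant_hinge(
    seq: List[str], p17_index: int, rng: np.random.Generator
) -> None:
    """Write a perfect 9-residue hinge with the P17 anchor at ``p17_index``
    (1-based)."""
    i0 = p17_index - 1
    for off, allowed in enumerate(_HINGE_SETS):
        if allowed is None:
            seq[i0 + off] = rng.choice(list(AMINO_ACIDS))
        else:
            seq[i0 + off] = rng.choice(list(allowed))


def _plant_degraded_hinge(
    seq: List[str], p17_index: int, rng: np.random.Generator, n_hits: int = 3
) -> None:
    """Hinge with exactly ``n_hits`` of the 8 scored positions satisfied."""
    i0 = p17_index - 1
    scored = [0, 1, 2, 3, 5, 6, 7, 8]
    hits = set(rng.choice(scored, size=n_hits, replace=False).tolist())
    for off, allowed in enumerate(_HINGE_SETS):
        if allowed is None:
            seq[i0 + off] = rng.choice(list(AMINO_ACIDS))
        elif off in hits:
            seq[i0 + off] = rng.choice(list(allowed))
        else:
            seq[i0 + off] = _DISALLOWED


def gen_serpin_proteins(
    n: int,
    class_mix: Optional[Dict[str, float]] = None,
    decoy_fraction: float = 0.0,
    seed: int = 0,
    length_range: Tuple[int, int] = (345, 570),
) -> Tuple[List[ProteinRecord], TruthBundle]:
    """Serpin-like proteins with a planted perfect hinge and P1 residue.

    A ``decoy_fraction`` of records instead carry one of three defects,
    cycled deterministically: a degraded hinge (3/8 consensus positions),
    a hinge truncated against the C-terminus (RCL-less), or a hinge pushed
    far from the C-terminus (over-long RCL).  Background composition is
    uniform over the 20 residues.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= decoy_fraction <= 1.0:
        raise ValueError("decoy_fraction must lie in [0, 1]")
    class_mix = class_mix or {"trypsin": 1 / 3, "chymotrypsin": 1 / 3,
                              "elastase": 1 / 3}
    bad = set(class_mix) - set(P1_BY_CLASS)
    if bad:
        raise ValueError(f"unknown specificity classes: {sorted(bad)}")
    probs = np.array([class_mix.get(c, 0.0) for c in sorted(class_mix)])
    if (probs < 0).any() or not np.isclose(probs.sum(), 1.0):
        raise ValueError("class_mix proportions must be non-negative and sum to 1")
    classes = sorted(class_mix)
    rng = np.random.default_rng(seed)
    records: List[ProteinRecord] = []
    truth: Dict[str, Dict[str, object]] = {}
    decoy_types = ("degraded", "truncated", "long_rcl")
    n_decoys_so_far = 0
    for idx in range(n):
        rid = f"SYN{idx + 1:04d}"
        L = int(rng.integers(length_range[0], length_range[1] + 1))
        seq = _random_protein(rng, L)
        is_decoy = bool(rng.random() < decoy_fraction)
        if not is_decoy:
            d = int(rng.integers(30, 71))  # P17 distance from C-terminus
            p17 = L - d
            _plant_hinge(seq, p17, rng)
            cls = classes[int(rng.choice(len(classes), p=probs))]
            p1 = p17 + 16
            p1_res = str(rng.choice(list(P1_BY_CLASS[cls])))
            seq[p1 - 1] = p1_res
            truth[rid] = {
                "decoy": None, "p17_index": p17, "p1_index": p1,
                "p1_residue": p1_res, "class": cls,
            }
        else:
            dtype = decoy_types[n_decoys_so_far % 3]
            n_decoys_so_far += 1
            if dtype == "degraded":
                d = int(rng.integers(30, 71))
                _plant_degraded_hinge(seq, L - d, rng)
            elif dtype == "truncated":
                d = int(rng.integers(10, 17))  # hinge jammed against the C-terminus
                _plant_hinge(seq, L - d, rng)
            else:  # long_rcl: hinge too far upstream, tail > 60 residues
                d = int(rng.integers(90, 131))
                _plant_hinge(seq, L - d, rng)
            truth[rid] = {"decoy": dtype, "p17_index": None, "p1_index": None,
                          "p1_residue": None, "class": None}
        records.append(
            ProteinRecord(id=rid, sequence="".join(seq), species="synthetic")
        )
    bundle = TruthBundle(
        generator="gen_serpin_proteins",
        seed=seed,
        params={"n": n, "class_mix": dict(class_mix),
                "decoy_fraction": decoy_fraction,
                "length_range": list(length_range)},
        truth=truth,
    )
    return records, bundle


def _site_classes_from_spec(
    params: Dict[str, object], ncat: int = 10
) -> Tuple[np.ndarray, np.ndarray]:
    model = params.get("model", "M0")
    if model == "M0":
        return np.array([float(params["omega"])]), np.array([1.0])
    if model == "M7":
        omegas = _beta_bin_omegas(float(params["p"]), float(params["q"]), ncat)
        return omegas, np.full(ncat, 1.0 / ncat)
    if model == "M8":
        p0 = float(params["p0"])
        omegas = np.concatenate(
            [_beta_bin_omegas(float(params["p"]), float(params["q"]), ncat),
             [float(params["omega_s"])]]
        )
        props = np.concatenate([np.full(ncat, p0 / ncat), [1.0 - p0]])
        return omegas, props
    if model == "custom":
        omegas = np.asarray(params["omegas"], dtype=float)
        props = np.asarray(params["proportions"], dtype=float)
        if not np.isclose(props.sum(), 1.0):
            raise ValueError("class proportions must sum to 1")
        return omegas, props
    raise ValueError(f"unknown site-model spec {model!r}")


def sim_codon_alignment(
    tree: TreeNode,
    params: Dict[str, object],
    n_sites: int,
    seed: int = 0,
    pi: Optional[np.ndarray] = None,
) -> Tuple[CodonAlignment, TruthBundle]:
    """Evolve a codon alignment along ``tree`` under a GY94 site mixture.

    ``params`` carries the site-model spec (e.g. ``{"model": "M0",
    "omega": 0.2, "kappa": 2.0}``; M7/M8 and explicit ``custom`` mixtures
    are supported).  Root codons are drawn from the equilibrium
    frequencies; the truth records each site's class and omega.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    kappa = float(params.get("kappa", 2.0))
    omegas, props = _site_classes_from_spec(params)
    pi = uniform_codon_frequencies() if pi is None else np.asarray(pi, float)
    rng = np.random.default_rng(seed)
    site_class = rng.choice(len(omegas), p=props, size=n_sites)
    scale = mixture_scale(omegas, props, kappa, pi)
    root_states = rng.choice(len(SENSE_CODONS), p=pi, size=n_sites)

    leaf_states: Dict[str, np.ndarray] = {}

    def evolve(node: TreeNode, states: np.ndarray) -> None:
        if node.is_leaf():
            leaf_states[node.name] = states
            return
        for child in node.children:
            P = transition_matrices(
                omegas, kappa, pi, [child.length], scale
            )[:, 0]  # (ncls, 61, 61)
            rows = P[site_class, states]  # (nsites, 61)
            u = rng.random(n_sites)
            child_states = (rows.cumsum(axis=1) < u[:, None]).sum(axis=1)
            child_states = np.minimum(child_states, len(SENSE_CODONS) - 1)
            evolve(child, child_states)

    evolve(tree, root_states)
    ids = tree.leaf_names()
    rows = [
        tuple(SENSE_CODONS[s] for s in leaf_states[name]) for name in ids
    ]
    aln = CodonAlignment(ids=ids, rows=rows)
    bundle = TruthBundle(
        generator="sim_codon_alignment",
        seed=seed,
        params={**{k: v for k, v in params.items()}, "n_sites": n_sites,
                "kappa": kappa},
        truth={
            "site_class": site_class.tolist(),
            "site_omega": [float(omegas[c]) for c in site_class],
            "omegas": omegas.tolist(),
            "proportions": props.tolist(),
        },
    )
    return aln, bundle


def sim_gene_counts(
    tree: TreeNode,
    lam: float,
    root_count: int,
    seed: int = 0,
    max_count: int = 100,
) -> Tuple[Dict[str, int], TruthBundle]:
    """Evolve family sizes along a dated tree under the critical BDP.

    Returns leaf counts plus a truth bundle recording every internal
    node's sampled state (nodes are labelled N0, N1, ... in preorder).
    """
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    if root_count < 1:
        raise ValueError("root_count must be >= 1")
    tree = copy.deepcopy(tree)
    _label_nodes(tree)
    params = BDParams(lam=lam, max_count=max_count)
    rng = np.random.default_rng(seed)
    from .gainloss import _cached_matrix

    def P(t: float) -> np.ndarray:
        return _cached_matrix(lam, float(t), max_count)

    states: Dict[str, int] = {}

    def evolve(node: TreeNode, state: int) -> None:
        states[node.name] = state
        for child in node.children:
            row = P(child.length)[state]
            row = row / row.sum()
            evolve(child, int(rng.choice(len(row), p=row)))

    evolve(tree, root_count)
    leaves = set(tree.leaf_names())
    counts = {name: states[name] for name in leaves}
    internal = {k: v for k, v in states.items() if k not in leaves}
    bundle = TruthBundle(
        generator="sim_gene_counts",
        seed=seed,
        params={"lam": lam, "root_count": root_count, "max_count": max_count},
        truth={"internal_counts": internal, "all_counts": states,
               "tree_newick": tree.to_newick(include_support=False)},
    )
    return counts, bundle


def sim_expression(
    n_genes: int,
    sample_labels: Sequence[str],
    block_spec: Sequence[Dict[str, object]],
    noise_sd: float = 0.5,
    seed: int = 0,
) -> Tuple[pd.DataFrame, TruthBundle]:
    """Block-structured FPKM matrix whose log2(FPKM + 1) transform is a
    gaussian block model.

    ``block_spec`` is a list of ``{"size": g, "means": per-sample means}``
    (scalar means are broadcast).  FPKM = 2^(mean + noise) - 1 floored at
    zero, so the transform recovers the gaussian blocks exactly.
    """
    sizes = [int(b["size"]) for b in block_spec]
    if any(s < 1 for s in sizes) or sum(sizes) != n_genes:
        raise ValueError(
            f"block sizes {sizes} must be positive and sum to n_genes = {n_genes}"
        )
    ns = len(sample_labels)
    rng = np.random.default_rng(seed)
    rows = []
    labels = []
    gene_ids = []
    g = 0
    for bi, block in enumerate(block_spec):
        means = np.broadcast_to(
            np.asarray(block["means"], dtype=float), (ns,)
        )
        for _ in range(int(block["size"])):
            g += 1
            gene_ids.append(f"gene{g:04d}")
            labels.append(bi)
            logv = means + rng.normal(0.0, noise_sd, size=ns)
            rows.append(np.maximum(np.exp2(logv) - 1.0, 0.0))
    m = pd.DataFrame(np.array(rows), index=gene_ids, columns=list(sample_labels))
    bundle = TruthBundle(
        generator="sim_expression",
        seed=seed,
        params={"n_genes": n_genes, "noise_sd": noise_sd,
                "sample_labels": list(sample_labels),
                "block_sizes": sizes},
        truth={"block_labels": dict(zip(gene_ids, labels))},
    )
    return m, bundle
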