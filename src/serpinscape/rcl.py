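"""Reactive-center-loop (RCL) annotation of serpin proteins.

Inhibitory serpins carry a conserved hinge consensus immediately N-terminal
of the RCL: E at P17, E/K/R at P16, G at P15, T/S at P14, anything at P13,
and small residues (A/G/S) at P12 through P9.  The scissile bond sits
sixteen residues C-terminal of the P17 anchor, between P1 and P1'; the P1
residue determines which protease family the serpin inhibits.

This module scans for the hinge, predicts P1/P1', classifies inhibitory
activity and target-protease specificity, computes physicochemical features
(molecular weight, isoelectric point), tallies family-level summaries, and
assembles mutually-exclusive-exon splice isoforms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

from ._constants import (
    AMINO_ACIDS,
    PKA_CTERM,
    PKA_NTERM,
    PKA_SIDECHAIN_ACID,
    PKA_SIDECHAIN_BASE,
    RESIDUE_MASS,
    WATER_MASS,
    translate_cds,
)
from .records import (
    FamilyReport,
    GeneModel,
    HingeMatch,
    IsoformRecord,
    ProteinRecord,
    RCLAnnotation,
)

__all__ = [
    "HINGE_ALLOWED",
    "SPECIFICITY_MAP",
    "scan_hinge",
    "annotate_rcl",
    "classify_specificity",
    "compute_mw",
    "compute_pi",
    "summarize_family",
    "assemble_isoforms",
]

MIN_SEQUENCE_LENGTH = 40

# Allowed residue sets for the eight constrained hinge positions
# P17, P16, P15, P14, P12, P11, P10, P9 (offsets 0,1,2,3,5,6,7,8 from P17;
# P13 at offset 4 is a wildcard and not scored).
HINGE_ALLOWED: Tuple[Tuple[int, frozenset], ...] = (
    (0, frozenset("E")),
    (1, frozenset("EKR")),
    (2, frozenset("G")),
    (3, frozenset("TS")),
    (5, frozenset("AGS")),
    (6, frozenset("AGS")),
    (7, frozenset("AGS")),
    (8, frozenset("AGS")),
)

# P1-residue -> target-protease class.  The named anchors are R/K (trypsin),
# L/I/Y (chymotrypsin) and small hydrophobics (elastase); F/W extend the
# chymotrypsin set and G/S the elastase set by protease P1-pocket chemistry.
SPECIFICITY_MAP: Dict[str, str] = {
    "R": "trypsin", "K": "trypsin",
    "L": "chymotrypsin", "I": "chymotrypsin", "Y": "chymotrypsin",
    "F": "chymotrypsin", "W": "chymotrypsin",
    "A": "elastase", "V": "elastase", "M": "elastase",
    "G": "elastase", "S": "elastase",
}


@dataclass(frozen=True)
class HingeWindow:
    """P17 search window, as offsets from the C-terminus (inclusive).

    The anchor is restricted to ``[L - max_from_cterm, L - min_from_cterm]``
    where L is the sequence length; the RCL sits near the C-terminal end of
    a serpin so distant anchors are not considered.
    """

    min_from_cterm: int = 25
    max_from_cterm: int = 75


DEFAULT_WINDOW = HingeWindow()
DEFAULT_MIN_SCORE = 6
DEFAULT_MAX_TAIL = 60


def score_anchor(seq: str, p17_index: int) -> HingeMatch:
    """Score the eight constrained hinge positions for a P17 anchor.

    ``p17_index`` is 1-based; the nine hinge residues P17..P9 must fit in
    the sequence.
    """
    i0 = p17_index - 1
    if i0 < 0 or i0 + 9 > len(seq):
        raise ValueError(f"anchor {p17_index} leaves no room for the 9-residue hinge")
    hits = tuple(seq[i0 + off] in allowed for off, allowed in HINGE_ALLOWED)
    return HingeMatch(p17_index=p17_index, per_position_hits=hits, score=sum(hits))


def scan_hinge(
    seq: str,
    window: HingeWindow = DEFAULT_WINDOW,
) -> List[HingeMatch]:
    """Scan the C-terminal window for hinge-consensus anchors.

    Returns every candidate with score >= 1, sorted by score (descending)
    then by P17 position (descending, i.e. C-terminal-most first — the
    canonical RCL placement wins ties).
    """
    seq = seq.upper()
    L = len(seq)
    if L < MIN_SEQUENCE_LENGTH:
        raise ValueError(
            f"sequence of length {L} is too short to carry an RCL "
            f"(minimum {MIN_SEQUENCE_LENGTH} residues)"
        )
    lo = max(1, L - window.max_from_cterm)
    hi = min(L - window.min_from_cterm, L - 8)
    matches = [
        m
        for p17 in range(lo, hi + 1)
        if (m := score_anchor(seq, p17)).score >= 1
    ]
    matches.sort(key=lambda m: (-m.score, -m.p17_index))
    return matches


def classify_specificity(p1_residue: str) -> str:
    """Map a P1 residue to its target-protease class.

    R/K -> trypsin; L/I/Y/F/W -> chymotrypsin; A/V/M/G/S -> elastase;
    anything else -> none.
    """
    if len(p1_residue) != 1 or p1_residue.upper() not in AMINO_ACIDS:
        raise ValueError(f"not a standard amino-acid letter: {p1_residue!r}")
    return SPECIFICITY_MAP.get(p1_residue.upper(), "none")


def annotate_rcl(
    record: ProteinRecord,
    min_score: int = DEFAULT_MIN_SCORE,
    max_tail: int = DEFAULT_MAX_TAIL,
    window: HingeWindow = DEFAULT_WINDOW,
) -> RCLAnnotation:
    """Annotate the RCL of one serpin record.

    The best-scoring hinge anchors the numbering: P1 = P17 + 16,
    P1' = P17 + 17.  The record is called inhibitory when the hinge scores
    at least ``min_score`` of 8, at least one residue remains C-terminal of
    P1, and the P1-to-C-terminus tail does not exceed ``max_tail`` residues
    (an over-long tail marks an aberrant RCL).
    """
    seq = record.sequence
    matches = scan_hinge(seq, window=window)
    if not matches:
        return RCLAnnotation(hinge=None, inhibitory=False, specificity="none")
    hinge = matches[0]
    p1 = hinge.p17_index + 16
    p1p = hinge.p17_index + 17
    L = len(seq)
    if p1 > L:  # truncated after the hinge: no scissile bond at all
        return RCLAnnotation(hinge=hinge, inhibitory=False, specificity="none")
    p1_res = seq[p1 - 1]
    has_p1p = p1p <= L
    tail = L - p1 + 1
    inhibitory = hinge.score >= min_score and has_p1p and tail <= max_tail
    specificity = classify_specificity(p1_res) if inhibitory else "none"
    if specificity == "none":
        inhibitory = False
    return RCLAnnotation(
        hinge=hinge,
        p1_index=p1,
        p1p_index=p1p if has_p1p else None,
        p1_residue=p1_res,
        p1p_residue=seq[p1p - 1] if has_p1p else None,
        inhibitory=inhibitory,
        specificity=specificity,
    )


def compute_mw(seq: str) -> float:
    """Theoretical average molecular weight in kDa (residue masses + one water)."""
    if not seq:
        raise ValueError("cannot compute molecular weight of an empty sequence")
    try:
        total = sum(RESIDUE_MASS[aa] for aa in seq.upper())
    except KeyError as e:
        raise ValueError(f"unknown residue {e.args[0]!r} in sequence") from None
    return (total + WATER_MASS) / 1000.0


def _net_charge(seq: str, ph: float) -> float:
    """Henderson-Hasselbalch net charge at a given pH (termini + side chains)."""
    def frac_base(pka: float) -> float:
        return 1.0 / (1.0 + 10.0 ** (ph - pka))

    def frac_acid(pka: float) -> float:
        return -1.0 / (1.0 + 10.0 ** (pka - ph))

    charge = frac_base(PKA_NTERM) + frac_acid(PKA_CTERM)
    for aa in seq:
        if aa in PKA_SIDECHAIN_BASE:
            charge += frac_base(PKA_SIDECHAIN_BASE[aa])
        elif aa in PKA_SIDECHAIN_ACID:
            charge += frac_acid(PKA_SIDECHAIN_ACID[aa])
    return charge


def compute_pi(seq: str, tol: float = 1e-3) -> float:
    """Isoelectric point by bisection of the net-charge curve on pH [0, 14]."""
    if not seq:
        raise ValueError("cannot compute pI of an empty sequence")
    seq = seq.upper()
    bad = set(seq) - set(AMINO_ACIDS)
    if bad:
        raise ValueError(f"unknown residue(s) {sorted(bad)} in sequence")
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _net_charge(seq, mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def summarize_family(
    records: Sequence[ProteinRecord],
    annotations: Sequence[RCLAnnotation],
    chromosome_set: Iterable[str] = (),
) -> FamilyReport:
    """Tally family-level counts over annotated records.

    ``pct_on_chromosome_set`` is the percentage of all records whose
    chromosome label falls in ``chromosome_set``, rounded to 2 decimals.
    """
    if not records:
        raise ValueError("summarize_family requires at least one record")
    if len(records) != len(annotations):
        raise ValueError("records and annotations must be parallel sequences")
    chromosome_set = {str(c) for c in chromosome_set}
    n = len(records)
    n_inh = sum(1 for a in annotations if a.inhibitory)
    n_sp = sum(1 for r in records if r.signal_peptide is not None)
    chrom_counts: Dict[str, int] = {}
    group_counts: Dict[str, int] = {}
    on_set = 0
    for r in records:
        if r.chromosome is not None:
            chrom_counts[r.chromosome] = chrom_counts.get(r.chromosome, 0) + 1
            if r.chromosome in chromosome_set:
                on_set += 1
        if r.gene_group is not None:
            group_counts[r.gene_group] = group_counts.get(r.gene_group, 0) + 1
    return FamilyReport(
        n_records=n,
        n_inhibitory=n_inh,
        n_noninhibitory=n - n_inh,
        n_signal_peptide=n_sp,
        chromosomes=dict(sorted(chrom_counts.items())),
        pct_on_chromosome_set=round(100.0 * on_set / n, 2),
        group_counts=dict(sorted(group_counts.items())),
    )


def assemble_isoforms(
    model: GeneModel,
    translate: bool = True,
    min_score: int = DEFAULT_MIN_SCORE,
) -> List[IsoformRecord]:
    """Assemble one isoform per mutually exclusive variant exon.

    Each isoform's cDNA is shared-prefix exons + one variant exon +
    shared-suffix exons.  When ``translate`` is true the cDNA must be a
    whole number of codons; the protein is annotated via :func:`annotate_rcl`
    so isoforms can differ in P1 and specificity.
    """
    variants = model.variants
    if not variants:
        raise ValueError(f"{model.gene_id}: gene model has no variant exon")
    prefix = "".join(e.sequence for e in model.shared_prefix)
    suffix = "".join(e.sequence for e in model.shared_suffix)
    isoforms: List[IsoformRecord] = []
    for letter, exon in zip("ABCDEFGHIJKLMNOPQRSTUVWXYZ", variants):
        cdna = prefix + exon.sequence + suffix
        iso_id = f"{model.gene_id}{letter}"
        protein = ""
        annotation = None
        if translate:
            if len(cdna) % 3:
                raise ValueError(
                    f"{iso_id}: cDNA length {len(cdna)} breaks codon phase"
                )
            protein = translate_cds(cdna)
            if protein.endswith("*"):
                protein = protein[:-1]
            if "*" in protein:
                raise ValueError(f"{iso_id}: internal stop codon in cDNA")
            annotation = annotate_rcl(
                ProteinRecord(id=iso_id, sequence=protein), min_score=min_score
            )
        isoforms.append(
            IsoformRecord(
                isoform_id=iso_id, cdna=cdna, protein=protein, annotation=annotation
            )
        )
    return isoforms
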