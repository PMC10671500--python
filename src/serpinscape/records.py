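"""Core domain records shared across the analysis modules.

Coordinates in user-facing fields are 1-based inclusive, matching the
convention of the annotation tables these records mirror.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

from ._constants import AMINO_ACIDS

_VALID_RESIDUES = frozenset(AMINO_ACIDS + "X")


@dataclass(frozen=True)
class ProteinRecord:
    """One serpin protein with its per-record metadata.

    signal_peptide is a 1-based inclusive residue range (e.g. ``(1, 18)``)
    carried as input metadata, never predicted here.
    """

    id: str
    sequence: str
    species: str = ""
    chromosome: Optional[str] = None
    signal_peptide: Optional[Tuple[int, int]] = None
    gene_group: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.sequence:
            raise ValueError(f"{self.id}: sequence must be non-empty")
        bad = set(self.sequence.upper()) - _VALID_RESIDUES
        if bad:
            raise ValueError(
                f"{self.id}: illegal residue(s) {sorted(bad)} in sequence"
            )
        object.__setattr__(self, "sequence", self.sequence.upper())
        if self.signal_peptide is not None:
            lo, hi = self.signal_peptide
            if not (1 <= lo <= hi <= len(self.sequence)):
                raise ValueError(
                    f"{self.id}: signal peptide range {self.signal_peptide} "
                    f"outside [1, {len(self.sequence)}]"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class HingeMatch:
    """A candidate hinge anchored at P17.

    per_position_hits covers the eight constrained hinge positions
    P17, P16, P15, P14, P12, P11, P10, P9 (P13 is unconstrained).
    """

    p17_index: int  # 1-based position of the P17 anchor residue
    per_position_hits: Tuple[bool, ...]
    score: int

    def __post_init__(self) -> None:
        if len(self.per_position_hits) != 8:
            raise ValueError("per_position_hits must have exactly 8 entries")
        if self.score != sum(self.per_position_hits):
            raise ValueError("score must equal the number of matched positions")


@dataclass(frozen=True)
class RCLAnnotation:
    """Reactive-center-loop annotation for one protein."""

    hinge: Optional[HingeMatch]
    p1_index: Optional[int] = None
    p1p_index: Optional[int] = None
    p1_residue: Optional[str] = None
    p1p_residue: Optional[str] = None
    inhibitory: bool = False
    specificity: str = "none"  # trypsin | chymotrypsin | elastase | none

    def __post_init__(self) -> None:
        if self.specificity not in {"trypsin", "chymotrypsin", "elastase", "none"}:
            raise ValueError(f"unknown specificity class {self.specificity!r}")
        if not self.inhibitory and self.specificity != "none":
            raise ValueError("non-inhibitory annotation must carry specificity 'none'")
        if self.p1_index is not None and self.p1p_index is not None:
            if self.p1p_index != self.p1_index + 1:
                raise ValueError("P1' must sit immediately C-terminal of P1")


@dataclass
class FamilyReport:
    """Family-level tallies over a set of annotated proteins."""

    n_records: int
    n_inhibitory: int
    n_noninhibitory: int
    n_signal_peptide: int
    chromosomes: dict = field(default_factory=dict)
    pct_on_chromosome_set: float = 0.0
    group_counts: dict = field(default_factory=dict)


@dataclass(frozen=True)
class Exon:
    """One exon of a gene model; sequence is the spliced (coding-strand) DNA."""

    index: int
    sequence: str
    variant: bool = False

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GeneModel:
    """Exon table with one slot of mutually exclusive variant exons.

    All exons with ``variant=True`` must share a single slot position in the
    exon order; each isoform uses exactly one of them.
    """

    gene_id: str
    exons: list  # list[Exon] in genomic/transcript order

    def __post_init__(self) -> None:
        variant_positions = {
            i for i, e in enumerate(self.exons) if e.variant
        }
        if variant_positions:
            lo, hi = min(variant_positions), max(variant_positions)
            if set(range(lo, hi + 1)) != variant_positions:
                raise ValueError(
                    f"{self.gene_id}: variant exons must form one contiguous slot"
                )

    @property
    def shared_prefix(self) -> list:
        out = []
        for e in self.exons:
            if e.variant:
                break
            out.append(e)
        return out

    @property
    def variants(self) -> list:
        return [e for e in self.exons if e.variant]

    @property
    def shared_suffix(self) -> list:
        seen_variant = False
        out = []
        for e in self.exons:
            if e.variant:
                seen_variant = True
                continue
            if seen_variant:
                out.append(e)
        return out


@dataclass(frozen=True)
class IsoformRecord:
    """One assembled splice isoform."""

    isoform_id: str
    cdna: str
    protein: str
    annotation: Optional[RCLAnnotation] = None

    @property
    def cdna_length(self) -> int:
        return len(self.cdna)
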