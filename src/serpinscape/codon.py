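"""In-frame codon alignments and protein-guided back-translation."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

from ._constants import GAP_CODON, SENSE_CODONS, translate_cds
from .phylo import Alignment

__all__ = ["CodonAlignment", "back_translate"]

_SENSE = frozenset(SENSE_CODONS)


@dataclass
class CodonAlignment:
    """Gap-aware in-frame codon matrix.

    Every non-gap codon must be a sense codon of the standard code; the gap
    codon is ``---``.
    """

    ids: List[str]
    rows: List[Tuple[str, ...]]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows must be parallel")
        if not self.rows:
            raise ValueError("codon alignment must have at least one row")
        ns = len(self.rows[0])
        self.rows = [tuple(r) for r in self.rows]
        for rid, row in zip(self.ids, self.rows):
            if len(row) != ns:
                raise ValueError(f"{rid}: row has {len(row)} sites, expected {ns}")
            for k, codon in enumerate(row):
                if codon == GAP_CODON:
                    continue
                if codon not in _SENSE:
                    raise ValueError(
                        f"{rid}: site {k + 1} holds {codon!r}, not a sense codon"
                    )

    @property
    def n_sites(self) -> int:
        return len(self.rows[0])

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def pair(self, i: int = 0, j: int = 1) -> "CodonAlignment":
        return CodonAlignment(
            ids=[self.ids[i], self.ids[j]], rows=[self.rows[i], self.rows[j]]
        )

    def to_nucleotide_rows(self) -> List[str]:
        return ["".join(row) for row in self.rows]


def back_translate(protein_aln: Alignment, cds: Dict[str, str]) -> CodonAlignment:
    """Thread coding sequences onto a gapped protein alignment.

    Each CDS must translate exactly to its ungapped protein row under the
    standard code (a trailing stop codon is stripped); every protein gap
    becomes the gap codon and every residue becomes its source codon.
    """
    rows: List[Tuple[str, ...]] = []
    for rid, prow in zip(protein_aln.ids, protein_aln.rows):
        if rid not in cds:
            raise ValueError(f"no coding sequence supplied for {rid}")
        dna = cds[rid].upper().replace("U", "T")
        if len(dna) % 3:
            raise ValueError(f"{rid}: CDS length {len(dna)} is not a codon multiple")
        protein = translate_cds(dna)
        if protein.endswith("*"):
            protein = protein[:-1]
            dna = dna[:-3]
        if "*" in protein:
            pos = protein.index("*") + 1
            raise ValueError(f"{rid}: internal stop codon at codon {pos}")
        ungapped = prow.replace("-", "").replace(".", "")
        if protein != ungapped:
            for k, (a, b) in enumerate(zip(protein, ungapped), start=1):
                if a != b:
                    raise ValueError(
                        f"{rid}: CDS translation disagrees with protein row at "
                        f"residue {k} ({a!r} vs {b!r})"
                    )
            raise ValueError(
                f"{rid}: CDS translates to {len(protein)} residues but the "
                f"protein row has {len(ungapped)}"
            )
        codons: List[str] = []
        cursor = 0
        for aa in prow:
            if aa in "-.":
                codons.append(GAP_CODON)
            else:
                codons.append(dna[3 * cursor: 3 * cursor + 3])
                cursor += 1
        rows.append(tuple(codons))
    return CodonAlignment(ids=list(protein_aln.ids), rows=rows)
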