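"""Packaged desk-scale fixtures.

The serpin family table carries the published per-gene metadata (lengths,
signal peptides, chromosomes, P1/P1' calls, phylogenetic and expression
groups) for the 26 codling-moth serpins; the protein sequences attached to
it are SYNTHETIC stand-ins engineered so that hinge/RCL annotation
reproduces the published calls (the real sequences live in a journal
appendix and are not redistributed here).  The 14-taxon dated species tree
and most of its per-species serpin counts are likewise synthetic, keeping
only the counts printed in the text (C. pomonella 26, B. mori 34,
H. armigera 26, Drosophila 29).
"""

from __future__ import annotations

from importlib import resources
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from ._constants import AMINO_ACIDS
from .io import _parse_signal_peptide, parse_newick
from .phylo import TreeNode
from .records import ProteinRecord
from .simulate import _plant_degraded_hinge, _plant_hinge

__all__ = [
    "load_family_table",
    "family_records",
    "species_tree",
    "serpin_counts",
]

_FIXTURE_SEED = 20230


def _data_text(name: str) -> str:
    return resources.files("serpinscape.data").joinpath(name).read_text()


def load_family_table() -> pd.DataFrame:
    """The 26-serpin family metadata table."""
    from io import StringIO

    return pd.read_csv(StringIO(_data_text("cpom_serpins.tsv")), sep="\t",
                       dtype=str)


def _synthetic_sequence(row: pd.Series, rng: np.random.Generator) -> str:
    """Synthetic stand-in sequence consistent with the table's annotation.

    Inhibitory rows get a perfect hinge 50 residues from the C-terminus
    with the tabulated P1/P1' residues; the non-inhibitory rows mimic
    their published defect (degraded hinge, missing RCL, or an RCL pushed
    out of the serpin-typical register).
    """
    L = int(row["length"])
    seq = list(rng.choice(list(AMINO_ACIDS), size=L))
    rid = row["id"]
    if row["inhibitory"] == "Y":
        p17 = L - 50
        _plant_hinge(seq, p17, rng)
        seq[p17 + 15] = row["p1"]
        seq[p17 + 16] = row["p1p"]
    elif rid in {"CpSPN10", "CpSPN20"}:
        _plant_degraded_hinge(seq, L - 50, rng)
    elif rid == "CpSPN26":
        # ~40 extra residues inserted into the RCL: hinge sits far from
        # the C-terminus, outside the serpin-typical register.
        _plant_hinge(seq, L - 110, rng)
    # CpSPN22 carries no hinge at all (no RCL).
    return "".join(seq)


def family_records(seed: int = _FIXTURE_SEED) -> Tuple[List[ProteinRecord], pd.DataFrame]:
    """The 26-record fixture: synthetic sequences + published metadata."""
    df = load_family_table()
    records: List[ProteinRecord] = []
    for idx, row in df.iterrows():
        rng = np.random.default_rng([seed, idx])
        records.append(
            ProteinRecord(
                id=row["id"],
                sequence=_synthetic_sequence(row, rng),
                species=row["species"],
                chromosome=row["chromosome"],
                signal_peptide=_parse_signal_peptide(row["signal_peptide"]),
                gene_group=row["gene_group"],
            )
        )
    return records, df


def species_tree() -> TreeNode:
    """Dated 14-taxon species tree (ultrametric, branch lengths in My)."""
    return parse_newick(_data_text("lepidoptera_tree.nwk"))


def serpin_counts() -> Dict[str, int]:
    """Per-species serpin family sizes for the 14-taxon tree."""
    from io import StringIO

    df = pd.read_csv(StringIO(_data_text("serpin_counts.tsv")), sep="\t")
    return dict(zip(df["species"], df["count"].astype(int)))
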