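"""Readers and writers for the standard formats: FASTA, Newick, TSV tables.

All user-facing coordinates are 1-based inclusive; tables are TSV with a
header row and stable column order.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import pandas as pd

from .phylo import TreeNode
from .records import Exon, GeneModel, ProteinRecord

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_newick",
    "write_newick",
    "parse_newick",
    "read_protein_table",
    "read_exon_table",
    "read_counts_tsv",
    "read_expression_tsv",
]

_FASTA_PROTEIN = re.compile(r"^[A-Za-z*\-\.]+$")


def read_fasta(path: Union[str, Path]) -> Dict[str, str]:
    """Order-preserving FASTA parse; rejects duplicate ids and illegal
    characters; concatenates wrapped lines."""
    path = Path(path)
    out: Dict[str, str] = {}
    current: Optional[str] = None
    chunks: List[str] = []

    def flush() -> None:
        if current is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise ValueError(f"{path}: record {current!r} has an empty sequence")
        out[current] = seq

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                rid = line[1:].split()[0] if len(line) > 1 else ""
                if not rid:
                    raise ValueError(f"{path}:{lineno}: empty FASTA header")
                if rid in out:
                    raise ValueError(f"{path}:{lineno}: duplicate id {rid!r}")
                current = rid
                chunks = []
            else:
                if current is None:
                    raise ValueError(f"{path}:{lineno}: sequence before header")
                if not _FASTA_PROTEIN.match(line):
                    raise ValueError(
                        f"{path}:{lineno}: illegal characters in sequence line"
                    )
                chunks.append(line.upper())
    flush()
    if not out:
        raise ValueError(f"{path}: empty FASTA file")
    return out


def write_fasta(
    path: Union[str, Path], sequences: Dict[str, str], width: int = 60
) -> None:
    with open(path, "w") as fh:
        for rid, seq in sequences.items():
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# --- newick -------------------------------------------------------------

def parse_newick(text: str) -> TreeNode:
    """Parse one newick string into a TreeNode, reporting the offset of
    any syntax error."""
    text = text.strip()
    if not text.endswith(";"):
        raise ValueError(f"newick string must end with ';' (offset {len(text)})")
    pos = 0

    def error(msg: str):
        raise ValueError(f"newick parse error at offset {pos}: {msg}")

    def parse_node() -> TreeNode:
        nonlocal pos
        node = TreeNode()
        if text[pos] == "(":
            pos += 1
            while True:
                node.children.append(parse_node())
                if pos >= len(text):
                    error("unbalanced parentheses")
                if text[pos] == ",":
                    pos += 1
                    continue
                if text[pos] == ")":
                    pos += 1
                    break
                error(f"unexpected character {text[pos]!r}")
        # label
        m = re.match(r"[^\s(),:;]+", text[pos:])
        if m:
            label = m.group(0)
            pos += len(label)
            if node.children:
                try:
                    node.support = float(label)
                except ValueError:
                    node.name = label
            else:
                node.name = label
        # branch length
        if pos < len(text) and text[pos] == ":":
            pos += 1
            m = re.match(r"[-+0-9.eE]+", text[pos:])
            if not m:
                error("expected branch length after ':'")
            node.length = float(m.group(0))
            if node.length < 0:
                error("negative branch length")
            pos += len(m.group(0))
        return node

    root = parse_node()
    if pos >= len(text) or text[pos] != ";":
        error("trailing content before ';'")
    names = root.leaf_names()
    if len(set(names)) != len(names):
        raise ValueError("duplicate leaf labels in tree")
    return root


def read_newick(path: Union[str, Path]) -> TreeNode:
    text = Path(path).read_text()
    return parse_newick(text)


def write_newick(
    path: Union[str, Path], tree: TreeNode, include_support: bool = True
) -> None:
    Path(path).write_text(tree.to_newick(include_support=include_support) + "\n")


# --- tables -------------------------------------------------------------

def _parse_signal_peptide(value: str) -> Optional[Tuple[int, int]]:
    value = str(value).strip()
    if value.upper() in {"NO", "NONE", "-", "NA", ""}:
        return None
    m = re.match(r"^(\d+)\s*[-–]\s*(\d+)$", value)
    if not m:
        raise ValueError(f"cannot parse signal peptide range {value!r}")
    return int(m.group(1)), int(m.group(2))


def read_protein_table(
    path: Union[str, Path], sequences: Optional[Dict[str, str]] = None
) -> Tuple[List[ProteinRecord], pd.DataFrame]:
    """Metadata TSV (id, species, chromosome, signal_peptide, gene_group,
    ...) joined with sequences into ProteinRecords.

    When ``sequences`` is None a 'sequence' column must exist in the table.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "id" not in df.columns:
        raise ValueError(f"{path}: metadata table needs an 'id' column")
    if df["id"].duplicated().any():
        dups = df.loc[df["id"].duplicated(), "id"].tolist()
        raise ValueError(f"{path}: duplicate ids {dups}")
    records: List[ProteinRecord] = []
    for _, row in df.iterrows():
        rid = row["id"]
        if sequences is not None:
            if rid not in sequences:
                raise ValueError(f"no sequence provided for {rid}")
            seq = sequences[rid]
        else:
            seq = row.get("sequence", "")
        records.append(
            ProteinRecord(
                id=rid,
                sequence=seq,
                species=row.get("species", "") or "",
                chromosome=row.get("chromosome") or None,
                signal_peptide=_parse_signal_peptide(row.get("signal_peptide", "NO")),
                gene_group=row.get("gene_group") or None,
            )
        )
    return records, df


def read_exon_table(path: Union[str, Path]) -> Dict[str, GeneModel]:
    """Exon TSV (gene_id, exon_index, variant_flag, sequence) -> GeneModels."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene_id", "exon_index", "variant_flag", "sequence"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: exon table missing columns {sorted(missing)}")
    models: Dict[str, GeneModel] = {}
    for gene_id, sub in df.groupby("gene_id", sort=False):
        sub = sub.assign(exon_index=sub["exon_index"].astype(int))
        sub = sub.sort_values("exon_index", kind="stable")
        exons = [
            Exon(
                index=int(r["exon_index"]),
                sequence=str(r["sequence"]).upper(),
                variant=str(r["variant_flag"]).strip().lower()
                in {"1", "true", "yes", "y"},
            )
            for _, r in sub.iterrows()
        ]
        models[gene_id] = GeneModel(gene_id=gene_id, exons=exons)
    return models


def read_counts_tsv(path: Union[str, Path]) -> Dict[str, int]:
    df = pd.read_csv(path, sep="\t")
    cols = list(df.columns)
    if len(cols) < 2:
        raise ValueError(f"{path}: counts table needs species and count columns")
    out = dict(zip(df[cols[0]].astype(str), df[cols[1]].astype(int)))
    if any(v < 0 for v in out.values()):
        raise ValueError(f"{path}: negative gene counts")
    return out


def read_expression_tsv(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.astype(float)
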