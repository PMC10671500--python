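"""Umbrella pipeline: configuration, stage orchestration, and report output.

Each stage is a thin wrapper over the library modules; outputs are TSV
tables and annotated Newick trees in the configured output directory,
plus a log recording the seed and a hash of the configuration so a run
can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd

from . import fixtures
from .codon import CodonAlignment
from .expression import cluster_genes, transform_fpkm
from .gainloss import ancestral_counts, fit_lambda
from .io import (
    read_counts_tsv,
    read_expression_tsv,
    read_fasta,
    read_newick,
    read_protein_table,
    write_newick,
)
from .kaks import estimate_kaks
from .phylo import Alignment, bootstrap_support
from .rcl import annotate_rcl, summarize_family
from .records import ProteinRecord
from .sitemodels import beb_sites, fit_site_models, lrt

__all__ = ["PipelineConfig", "run_pipeline", "annotation_table"]

_TARGET_LETTER = {"trypsin": "T", "chymotrypsin": "C", "elastase": "E", "none": "-"}

_KNOWN_KEYS = {
    "stages", "out_dir", "seed",
    "protein_fasta", "metadata_tsv", "chromosome_set",
    "alignment_fasta", "bootstrap_reps",
    "codon_fasta", "tree_newick",
    "counts_tsv", "species_tree_newick", "lambda_max",
    "expression_tsv", "n_groups",
    "min_hinge_score",
}

_ALL_STAGES = ("annotate", "tree", "kaks", "sitetest", "gainloss", "express")


@dataclass
class PipelineConfig:
    stages: List[str] = field(default_factory=lambda: list(_ALL_STAGES))
    out_dir: str = "serpinscape_out"
    seed: int = 0
    # annotate
    protein_fasta: Optional[str] = None
    metadata_tsv: Optional[str] = None
    chromosome_set: List[str] = field(default_factory=lambda: ["1", "2", "3", "5", "15"])
    min_hinge_score: int = 6
    # tree
    alignment_fasta: Optional[str] = None
    bootstrap_reps: int = 100
    # kaks / sitetest
    codon_fasta: Optional[str] = None
    tree_newick: Optional[str] = None
    # gainloss
    counts_tsv: Optional[str] = None
    species_tree_newick: Optional[str] = None
    lambda_max: float = 0.05
    # express
    expression_tsv: Optional[str] = None
    n_groups: int = 4

    @classmethod
    def from_dict(cls, raw: Dict) -> "PipelineConfig":
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        cfg = cls(**raw)
        bad = [s for s in cfg.stages if s not in _ALL_STAGES]
        if bad:
            raise ValueError(f"unknown stages: {bad}")
        if not 0 <= cfg.min_hinge_score <= 8:
            raise ValueError("min_hinge_score must be in [0, 8]")
        return cfg

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def annotation_table(records, annotations) -> pd.DataFrame:
    """Per-gene annotation output: features, P1/P1' call, class, location."""
    from .rcl import compute_mw, compute_pi

    rows = []
    for r, a in zip(records, annotations):
        rows.append({
            "id": r.id,
            "length": len(r),
            "mw_kda": round(compute_mw(r.sequence), 3),
            "pi": round(compute_pi(r.sequence), 2),
            "p1": a.p1_residue or "-",
            "p1_prime": a.p1p_residue or "-",
            "p1_index": a.p1_index if a.p1_index else "-",
            "target": _TARGET_LETTER[a.specificity],
            "inhibitory": "Y" if a.inhibitory else "N",
            "hinge_score": a.hinge.score if a.hinge else 0,
            "chromosome": r.chromosome or "-",
            "signal_peptide": (
                f"{r.signal_peptide[0]}-{r.signal_peptide[1]}"
                if r.signal_peptide else "NO"
            ),
            "gene_group": r.gene_group or "-",
        })
    return pd.DataFrame(rows)


def _load_proteins(config: PipelineConfig):
    if config.protein_fasta is None and config.metadata_tsv is None:
        return fixtures.family_records()[0]
    sequences = read_fasta(config.protein_fasta) if config.protein_fasta else None
    if config.metadata_tsv:
        records, _ = read_protein_table(config.metadata_tsv, sequences)
        return records
    return [ProteinRecord(id=k, sequence=v) for k, v in sequences.items()]


def _codon_alignment_from_fasta(path: str) -> CodonAlignment:
    seqs = read_fasta(path)
    rows = []
    for rid, s in seqs.items():
        if len(s) % 3:
            raise ValueError(f"{rid}: aligned CDS length is not a codon multiple")
        rows.append(tuple(s[i:i + 3] for i in range(0, len(s), 3)))
    return CodonAlignment(ids=list(seqs), rows=rows)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the enabled stages; returns the report directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = [
        f"seed\t{config.seed}",
        f"config_hash\t{config.config_hash()}",
        f"stages\t{','.join(config.stages)}",
    ]
    if not config.stages:
        log_lines.append("warning\tno stages enabled; empty report")

    def fail(stage: str, exc: Exception):
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    if "annotate" in config.stages:
        try:
            records = _load_proteins(config)
            annotations = [
                annotate_rcl(r, min_score=config.min_hinge_score) for r in records
            ]
            annotation_table(records, annotations).to_csv(
                out / "annotation.tsv", sep="\t", index=False
            )
            report = summarize_family(records, annotations, config.chromosome_set)
            pd.DataFrame([{
                "n_records": report.n_records,
                "n_inhibitory": report.n_inhibitory,
                "n_noninhibitory": report.n_noninhibitory,
                "n_signal_peptide": report.n_signal_peptide,
                "n_chromosomes": len(report.chromosomes),
                "pct_on_chromosome_set": report.pct_on_chromosome_set,
                "chromosome_counts": json.dumps(report.chromosomes),
                "group_counts": json.dumps(report.group_counts),
            }]).to_csv(out / "family_report.tsv", sep="\t", index=False)
            log_lines.append(f"annotate\t{report.n_records} records")
        except Exception as e:
            fail("annotate", e)

    if "tree" in config.stages:
        try:
            if config.alignment_fasta is None:
                raise ValueError("tree stage needs alignment_fasta")
            seqs = read_fasta(config.alignment_fasta)
            aln = Alignment(ids=list(seqs), rows=list(seqs.values()))
            tree = bootstrap_support(
                aln, reps=config.bootstrap_reps, seed=config.seed
            )
            write_newick(out / "nj_tree.nwk", tree)
            log_lines.append(f"tree\t{aln.n_rows} taxa, {config.bootstrap_reps} reps")
        except Exception as e:
            fail("tree", e)

    if "kaks" in config.stages:
        try:
            if config.codon_fasta is None:
                raise ValueError("kaks stage needs codon_fasta")
            caln = _codon_alignment_from_fasta(config.codon_fasta)
            rows = []
            for i in range(caln.n_rows):
                for j in range(i + 1, caln.n_rows):
                    res = estimate_kaks(caln.pair(i, j))
                    rows.append({
                        "id1": caln.ids[i], "id2": caln.ids[j],
                        "ka": round(res.ka, 6), "ks": round(res.ks, 6),
                        "ka_ks": round(res.ratio, 6) if res.ratio is not None else "NA",
                        "kappa": round(res.kappa, 4),
                        "n_sites": res.n_sites,
                    })
            pd.DataFrame(rows).to_csv(out / "kaks.tsv", sep="\t", index=False)
            log_lines.append(f"kaks\t{len(rows)} pairs")
        except Exception as e:
            fail("kaks", e)

    if "sitetest" in config.stages:
        try:
            if config.codon_fasta is None or config.tree_newick is None:
                raise ValueError("sitetest stage needs codon_fasta and tree_newick")
            caln = _codon_alignment_from_fasta(config.codon_fasta)
            tree = read_newick(config.tree_newick)
            fits = fit_site_models(caln, tree, seed=config.seed)
            m0m3 = lrt(fits["M0"].lnl, fits["M3"].lnl, df=4)
            m7m8 = lrt(fits["M7"].lnl, fits["M8"].lnl, df=2)
            sites = beb_sites(fits["M8"], caln, tree)
            pss = [s for s in sites if s.pss]
            n_seq = caln.n_rows
            dnds = round(fits["M0"].parameters["omega"], 5)
            pd.DataFrame([
                {"comparison": "M0_vs_M3", "n": n_seq, "dnds_m0": dnds,
                 "two_delta_lnl": round(m0m3.statistic, 4),
                 "df": m0m3.df, "p": m0m3.p_value},
                {"comparison": "M7_vs_M8", "n": n_seq, "dnds_m0": dnds,
                 "two_delta_lnl": round(m7m8.statistic, 4),
                 "df": m7m8.df, "p": m7m8.p_value},
            ]).to_csv(out / "site_tests.tsv", sep="\t", index=False)
            pd.DataFrame([
                {"site": s.site, "posterior": round(s.posterior, 4)} for s in pss
            ]).to_csv(out / "pss_sites.tsv", sep="\t", index=False)
            log_lines.append(
                f"sitetest\tM0 omega {fits['M0'].parameters['omega']:.4f}, "
                f"{len(pss)} PSS"
            )
        except Exception as e:
            fail("sitetest", e)

    if "gainloss" in config.stages:
        try:
            tree = (
                read_newick(config.species_tree_newick)
                if config.species_tree_newick else fixtures.species_tree()
            )
            counts = (
                read_counts_tsv(config.counts_tsv)
                if config.counts_tsv else fixtures.serpin_counts()
            )
            lam_hat, boundary = fit_lambda(tree, [counts], lam_max=config.lambda_max)
            amap = ancestral_counts(tree, counts, lam_hat)
            rows = [
                {"node": k, "count": v,
                 "delta": ("%+d" % amap.branch_deltas[k])
                 if k in amap.branch_deltas else ""}
                for k, v in sorted(amap.node_counts.items())
            ]
            pd.DataFrame(rows).to_csv(out / "gainloss.tsv", sep="\t", index=False)
            labelled = amap.tree
            for node in labelled.walk():
                if node.name in amap.branch_deltas:
                    d = amap.branch_deltas[node.name]
                    node.name = f"{node.name}_{amap.node_counts[node.name]}({d:+d})"
            write_newick(out / "gainloss.nwk", labelled, include_support=False)
            log_lines.append(
                f"gainloss\tlambda {lam_hat:.5f}{' (boundary)' if boundary else ''}"
            )
        except Exception as e:
            fail("gainloss", e)

    if "express" in config.stages:
        try:
            if config.expression_tsv is None:
                raise ValueError("express stage needs expression_tsv")
            m = read_expression_tsv(config.expression_tsv)
            t = transform_fpkm(m)
            groups = cluster_genes(t, k=config.n_groups)
            t.to_csv(out / "expression_log2.tsv", sep="\t")
            pd.DataFrame(
                [{"gene": g, "group": grp} for g, grp in groups.items()]
            ).to_csv(out / "expression_groups.tsv", sep="\t", index=False)
            log_lines.append(f"express\t{len(groups)} genes into {config.n_groups} groups")
        except Exception as e:
            fail("express", e)

    (out / "run_log.tsv").write_text("\n".join(log_lines) + "\n")
    return out
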