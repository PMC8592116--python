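"""End-to-end orchestration: config in, per-locus score tables and reports out.

For each configured locus the pipeline defines the LD interval and the
candidate-gene window, runs colocalization for each configured molecular-QTL
dataset against the GWAS, merges the resulting records with the ingested
evidence table, scores every candidate gene and interval SNP, ranks them
and writes TSV outputs plus a manifest recording the configuration hash and
seed.  A failing locus is logged and skipped; the remaining loci still run.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .coloc import ColocPriors, SummaryStats, coloc_posteriors, coloc_to_evidence
from .evidence import WeightScheme, read_evidence_table, write_evidence_table
from .locus import build_locus, read_gene_annotation, read_ld_table
from .report import LocusReport, build_locus_report, crosslocus_summary
from .scoring import score_locus

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "QtlDataset", "LocusSpec", "run_pipeline", "load_run_config"]


@dataclass(frozen=True)
class LocusSpec:
    locus_id: str
    index_snp: str
    chrom: str
    index_pos: int
    secondary: tuple[tuple[str, int], ...] = ()


@dataclass(frozen=True)
class QtlDataset:
    """One molecular-QTL summary-statistics dataset to colocalize."""

    path: str
    gene: str
    study_id: str
    study_type: str = "eqtl"
    tissue: str | None = None
    trait_type: str = "quant"


@dataclass
class RunConfig:
    loci: list[LocusSpec]
    annotation: str
    ld: str | None = None
    gwas: str | None = None
    evidence: str | None = None
    qtl: list[QtlDataset] = field(default_factory=list)
    weights: WeightScheme = field(default_factory=WeightScheme)
    coloc_priors: ColocPriors = field(default_factory=ColocPriors)
    output_dir: str = "genetriage_out"
    seed: int = 0
    gwas_trait_type: str = "cc"

    def __post_init__(self) -> None:
        if not self.loci:
            raise ValueError("locus list must be non-empty")

    def canonical(self) -> dict:
        return {
            "loci": [
                {
                    "locus_id": L.locus_id,
                    "index_snp": L.index_snp,
                    "chrom": L.chrom,
                    "index_pos": L.index_pos,
                    "secondary": [list(s) for s in L.secondary],
                }
                for L in self.loci
            ],
            "annotation": self.annotation,
            "ld": self.ld,
            "gwas": self.gwas,
            "evidence": self.evidence,
            "qtl": [vars(q).copy() for q in self.qtl],
            "weights": vars(self.weights).copy(),
            "coloc_priors": vars(self.coloc_priors).copy(),
            "seed": self.seed,
            "gwas_trait_type": self.gwas_trait_type,
        }


def load_run_config(path) -> RunConfig:
    """Build a RunConfig from a YAML file; referenced paths must exist."""
    raw = yaml.safe_load(Path(path).read_text())
    paths = raw.get("paths", {})
    loci = [
        LocusSpec(
            locus_id=str(l["locus_id"]),
            index_snp=str(l["index_snp"]),
            chrom=str(l["chrom"]),
            index_pos=int(l["index_pos"]),
            secondary=tuple((str(s["snp"]), int(s["pos"])) for s in l.get("secondary", [])),
        )
        for l in raw.get("loci", [])
    ]
    qtl = [
        QtlDataset(
            path=str(q["path"]),
            gene=str(q["gene"]),
            study_id=str(q.get("study_id", Path(q["path"]).stem)),
            study_type=str(q.get("study_type", "eqtl")),
            tissue=q.get("tissue"),
            trait_type=str(q.get("trait_type", "quant")),
        )
        for q in raw.get("qtl", [])
    ]
    cfg = RunConfig(
        loci=loci,
        annotation=paths["annotation"],
        ld=paths.get("ld"),
        gwas=paths.get("gwas"),
        evidence=paths.get("evidence"),
        qtl=qtl,
        weights=WeightScheme(**raw["weights"]) if "weights" in raw else WeightScheme(),
        coloc_priors=ColocPriors(**{k: float(v) for k, v in raw["coloc_priors"].items()})
        if "coloc_priors" in raw
        else ColocPriors(),
        output_dir=str(raw.get("output_dir", "genetriage_out")),
        seed=int(raw.get("seed", 0)),
        gwas_trait_type=str(raw.get("gwas_trait_type", "cc")),
    )
    for p in [cfg.annotation, cfg.ld, cfg.gwas, cfg.evidence, *[q.path for q in cfg.qtl]]:
        if p is not None and not Path(p).exists():
            raise FileNotFoundError(f"configured path does not exist: {p}")
    return cfg


def _ld_for(ld: pd.DataFrame | None, locus_id: str) -> pd.DataFrame | None:
    if ld is None:
        return None
    if "locus_id" in ld.columns:
        return ld[ld["locus_id"] == locus_id]
    return ld


def _score_table(locus_id: str, scores) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "locus_id": locus_id,
                "target_type": s.target_type,
                "target_id": s.target_id,
                "total": s.total,
                "raw_sum": s.raw_sum,
                "het_mult": s.heterogeneity,
                "n_types": s.n_unique_study_types,
                "n_studies": s.n_unique_study_ids,
            }
            for s in scores
        ]
    )


def _breakdown_table(locus_id: str, scores) -> pd.DataFrame:
    rows = []
    for s in scores:
        for c in s.components:
            rows.append(
                {
                    "locus_id": locus_id,
                    "target_type": s.target_type,
                    "target_id": s.target_id,
                    "study_id": c.record.study_id,
                    "study_type": c.record.study_type,
                    "evidence_class": c.record.evidence_class.value,
                    "weight": c.weight,
                    "magnitude": c.magnitude_factor,
                    "specificity": c.specificity_factor,
                    "independence_div": c.independence_divisor,
                    "value": c.value,
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> tuple[dict[str, LocusReport], list[str]]:
    """Run every configured locus; returns (reports by locus, failed loci).

    Writes per-locus gene/SNP score tables and evidence breakdowns, a
    colocalization result table, a cross-locus report TSV and a manifest
    under ``config.output_dir``.  Outputs are deterministic for a fixed
    configuration and seed.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    annotation = read_gene_annotation(config.annotation)
    ld_all = read_ld_table(config.ld) if config.ld else None
    base_evidence = read_evidence_table(config.evidence) if config.evidence else []
    gwas_all = pd.read_csv(config.gwas, sep="\t", dtype={"snp_id": str, "chrom": str}) if config.gwas else None

    reports: dict[str, LocusReport] = {}
    failed: list[str] = []
    coloc_rows = []
    for spec in config.loci:
        try:
            ld = _ld_for(ld_all, spec.locus_id)
            sec = [(snp, pos, ld) for snp, pos in spec.secondary]
            locus = build_locus(
                spec.locus_id, spec.index_snp, spec.chrom, spec.index_pos, ld, annotation, secondary=sec
            )
            evidence = [r for r in base_evidence if r.locus_id == spec.locus_id]

            snp_positions: dict[str, int] = {}
            gwas_stats = None
            if gwas_all is not None:
                gsub = gwas_all[gwas_all["chrom"].astype(str) == spec.chrom]
                snp_positions = dict(zip(gsub["snp_id"], gsub["pos"].astype(int)))
                inside = gsub[(gsub["pos"] >= locus.interval[0]) & (gsub["pos"] <= locus.interval[1])]
                if len(inside) >= 2:
                    gwas_stats = SummaryStats.from_dataframe(
                        inside, trait="gwas", trait_type=config.gwas_trait_type
                    )

            for q in config.qtl:
                if gwas_stats is None:
                    logger.warning("locus %s: no GWAS stats in interval; skipping coloc", spec.locus_id)
                    break
                qdf = pd.read_csv(q.path, sep="\t", dtype={"snp_id": str, "chrom": str})
                qstats = SummaryStats.from_dataframe(qdf, trait=q.study_id, trait_type=q.trait_type)
                result = coloc_posteriors(gwas_stats, qstats, priors=config.coloc_priors)
                coloc_rows.append(
                    {
                        "locus_id": spec.locus_id,
                        "gene": q.gene,
                        "study_id": q.study_id,
                        "tissue": q.tissue or "",
                        "n_variants": result.n_variants,
                        "h0": result.h0,
                        "h1": result.h1,
                        "h2": result.h2,
                        "h3": result.h3,
                        "h4": result.h4,
                        "top_shared_variant": result.top_shared_variant,
                    }
                )
                rec = coloc_to_evidence(
                    result, spec.locus_id, q.gene, study_id=q.study_id,
                    study_type=q.study_type, tissue=q.tissue,
                )
                if rec is not None:
                    evidence.append(rec)

            gene_scores, snp_scores = score_locus(
                locus, evidence, scheme=config.weights, snp_positions=snp_positions or None
            )
            gene_by_id = {g.gene_id: g for g in annotation}
            gdist = {
                gid: float(gene_by_id[gid].edge_distance(spec.index_pos))
                for gid in locus.candidate_genes
                if gid in gene_by_id
            }
            sdist = {s: float(abs(p - spec.index_pos)) for s, p in snp_positions.items()}
            report = build_locus_report(
                spec.locus_id,
                spec.index_snp,
                gene_scores,
                snp_scores,
                nearest_genes=locus.nearest_genes,
                gene_distance=gdist,
                snp_distance=sdist,
            )
            reports[spec.locus_id] = report

            _score_table(spec.locus_id, gene_scores).to_csv(
                outdir / f"{spec.locus_id}_gene_scores.tsv", sep="\t", index=False
            )
            _score_table(spec.locus_id, snp_scores).to_csv(
                outdir / f"{spec.locus_id}_snp_scores.tsv", sep="\t", index=False
            )
            _breakdown_table(spec.locus_id, list(gene_scores) + list(snp_scores)).to_csv(
                outdir / f"{spec.locus_id}_breakdown.tsv", sep="\t", index=False
            )
            write_evidence_table(evidence, outdir / f"{spec.locus_id}_evidence.tsv")
        except Exception:
            logger.exception("locus %s failed; continuing with remaining loci", spec.locus_id)
            failed.append(spec.locus_id)

    if coloc_rows:
        pd.DataFrame(coloc_rows).to_csv(outdir / "coloc.tsv", sep="\t", index=False)
    summary = crosslocus_summary(list(reports.values()))
    summary["digest"].to_csv(outdir / "report.tsv", sep="\t", index=False)

    canonical = yaml.safe_dump(config.canonical(), sort_keys=True)
    manifest = {
        "config_sha256": hashlib.sha256(canonical.encode()).hexdigest(),
        "seed": config.seed,
        "genetriage_version": __version__,
        "n_loci": len(config.loci),
        "failed_loci": failed,
    }
    (outdir / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))
    return reports, failed
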