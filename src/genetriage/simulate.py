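"""Synthetic study conditions: LD blocks, paired summary stats, evidence plans.

The real pipeline ingests over a hundred molecular datasets; this module
generates the minimal synthetic stand-ins needed to exercise every stage:

* an LD block with exponentially decaying correlation R[i, j] = rho^|i-j|,
* GWAS and molecular-QTL z-scores drawn jointly under that LD with a shared
  or distinct causal variant (z ~ MVN(R @ lam, R), lam carrying the
  noncentrality beta * sqrt(n) at the causal position),
* evidence tables with a planted causal gene supported by a configurable
  plan of study types and classes, against background decoy support.

It also exposes the published atopic-dermatitis locus summary table as a
machine-readable fixture for the reporting layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib.resources import files

import numpy as np
import pandas as pd
from scipy.linalg import toeplitz
from scipy.stats import norm

from .coloc import SummaryStats
from .evidence import EvidenceClass, EvidenceRecord
from .report import Classification, LocusReport, RankedTarget, normalize_symbol

__all__ = [
    "SimConfig",
    "EvidenceSpec",
    "rng_for",
    "simulate_ld_block",
    "simulate_joint_stats",
    "generate_evidence_set",
    "strong_support_plan",
    "null_plan",
    "table1_fixture",
    "fixture_reports",
    "simulate_annotation",
]

# Fixed stream labels: every module draws from its own child stream of the
# one user seed, so runs are reproducible and modules independently testable.
_STREAMS = {"ld": 1, "stats": 2, "evidence": 3, "annotation": 4}


def rng_for(seed: int, stream: str) -> np.random.Generator:
    """Child generator for a named stream of the master seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAMS[stream]]))


@dataclass(frozen=True)
class EvidenceSpec:
    """One planned evidence record template for a gene."""

    study_type: str
    evidence_class: EvidenceClass
    magnitude: tuple[float, float]  # uniform draw bounds, lo == hi for fixed
    n_sig: int = 1
    n_exp: int = 1


@dataclass
class SimConfig:
    """Study conditions for one synthetic locus.

    Defaults describe a realistic GWAS locus: 50 variants at 5-kb spacing
    under strong local LD (rho = 0.9), a well-powered GWAS (n = 20,000,
    beta such that the causal noncentrality beta*sqrt(n) ~ 8, around the
    detection threshold of genome-wide studies), a smaller molecular-QTL
    study, and six candidate genes with one planted causal gene.
    """

    seed: int
    n_snps: int = 50
    ld_decay: float = 0.9
    causal_snp: int | None = None  # default: center of the block
    shared: bool = True
    causal_snp2: int | None = None  # trait-2 causal variant when not shared
    beta: float = 0.0566  # * sqrt(n1=20000) ~ z = 8 at the causal variant
    n1: int = 20_000
    n2: int = 20_000
    spacing: int = 5_000
    start_pos: int = 100_000_000
    chrom: str = "1"
    n_genes: int = 6
    planted_gene: int = 0
    locus_id: str = "sim"
    evidence_plan: dict[str, list[EvidenceSpec]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 <= self.ld_decay < 1):
            raise ValueError(f"ld_decay must lie in [0, 1), got {self.ld_decay}")
        if self.causal_snp is None:
            self.causal_snp = self.n_snps // 2
        if not (0 <= self.causal_snp < self.n_snps):
            raise ValueError("causal_snp must index into the SNP panel")
        if not (0 <= self.planted_gene < self.n_genes):
            raise ValueError("planted_gene must index into the gene panel")

    @property
    def gene_ids(self) -> list[str]:
        return [f"GENE{i}" for i in range(self.n_genes)]

    @property
    def snp_ids(self) -> list[str]:
        return [f"rs{i:05d}" for i in range(self.n_snps)]


def simulate_ld_block(n_snps: int, ld_decay: float, spacing: int = 5_000, start_pos: int = 100_000_000):
    """Exponential-decay LD block: R[i, j] = rho^|i-j|, equally spaced SNPs.

    Returns ``(R, positions)``.  The AR(1)-style structure is symmetric
    positive-definite for any rho in [0, 1).
    """
    if not (0 <= ld_decay < 1):
        raise ValueError(f"ld_decay must lie in [0, 1), got {ld_decay}")
    corr = toeplitz(ld_decay ** np.arange(n_snps))
    positions = start_pos + spacing * np.arange(n_snps, dtype=np.int64)
    return corr, positions


def simulate_joint_stats(config: SimConfig) -> tuple[SummaryStats, SummaryStats]:
    """Draw paired GWAS / QTL summary statistics at one LD block.

    z-vectors follow MVN(R @ lam, R); lam places noncentrality beta*sqrt(n)
    at the causal variant of each trait (the same variant for both when
    ``shared``).  Betas and SEs are back-computed with SE = 1/sqrt(n).
    """
    corr, positions = simulate_ld_block(config.n_snps, config.ld_decay, config.spacing, config.start_pos)
    eigmin = np.linalg.eigvalsh(corr)[0]
    if eigmin <= 0:
        raise ValueError("LD matrix is not positive-definite")
    rng = rng_for(config.seed, "stats")
    chol = np.linalg.cholesky(corr)

    if config.shared:
        causal2 = config.causal_snp
    elif config.causal_snp2 is not None:
        causal2 = config.causal_snp2
    else:
        # default distinct causal variant: half a block away, so LD between
        # the two causal positions is negligible (rho^(n/2))
        causal2 = (config.causal_snp + config.n_snps // 2) % config.n_snps
    out = []
    eaf = rng.uniform(0.05, 0.95, size=config.n_snps)
    for trait, n, causal in (("gwas", config.n1, config.causal_snp), ("qtl", config.n2, causal2)):
        lam = np.zeros(config.n_snps)
        lam[causal] = config.beta * np.sqrt(n)
        z = corr @ lam + chol @ rng.standard_normal(config.n_snps)
        se = np.full(config.n_snps, 1.0 / np.sqrt(n))
        out.append(
            SummaryStats(
                trait=trait,
                ids=np.array(config.snp_ids, dtype=object),
                pos=positions,
                beta=z * se,
                se=se,
                eaf=eaf.copy(),
                n=np.full(config.n_snps, float(n)),
                chrom=config.chrom,
            )
        )
    return out[0], out[1]


def sumstats_frame(stats: SummaryStats) -> pd.DataFrame:
    """Summary stats as the pipeline's TSV-dialect DataFrame."""
    z = stats.z
    return pd.DataFrame(
        {
            "snp_id": stats.ids,
            "chrom": stats.chrom or "1",
            "pos": stats.pos,
            "beta": stats.beta,
            "se": stats.se,
            "p": 2 * norm.sf(np.abs(z)),
            "eaf": stats.eaf if stats.eaf is not None else np.nan,
            "n": stats.n if stats.n is not None else np.nan,
        }
    )


def strong_support_plan(
    config_or_genes,
    planted: int = 0,
    n_stat_full: int = 3,
    magnitude: tuple[float, float] = (0.8, 1.0),
) -> dict[str, list[EvidenceSpec]]:
    """Plan where the planted gene gets ``n_stat_full`` full-weight records
    from distinct study types and each decoy gets one weak overlap record."""
    genes = config_or_genes.gene_ids if isinstance(config_or_genes, SimConfig) else list(config_or_genes)
    stat_types = ["coloc", "twas", "finemap", "eqtl", "pqtl"]
    plan: dict[str, list[EvidenceSpec]] = {}
    for i, g in enumerate(genes):
        if i == planted:
            plan[g] = [
                EvidenceSpec(stat_types[j % len(stat_types)], EvidenceClass.STAT_FULL, magnitude)
                for j in range(n_stat_full)
            ]
        else:
            plan[g] = [EvidenceSpec("eqtl", EvidenceClass.OVERLAP, (0.0, 1.0), n_sig=10)]
    return plan


def null_plan(config_or_genes) -> dict[str, list[EvidenceSpec]]:
    """Exchangeable background: one prediction record per gene, uniform
    magnitude — no gene is favored, so top ranks should be uniform."""
    genes = config_or_genes.gene_ids if isinstance(config_or_genes, SimConfig) else list(config_or_genes)
    return {g: [EvidenceSpec("regulatory_pred", EvidenceClass.PREDICTION, (0.0, 1.0))] for g in genes}


def generate_evidence_set(config: SimConfig) -> list[EvidenceRecord]:
    """Materialize the evidence plan into records, deterministically by seed.

    Each planned template becomes one gene-level record with its own study
    id; magnitudes are uniform draws from the template's bounds.
    """
    plan = config.evidence_plan or strong_support_plan(config, planted=config.planted_gene)
    known = set(config.gene_ids)
    unknown = set(plan) - known
    if unknown:
        raise ValueError(f"evidence plan references unknown gene(s): {sorted(unknown)}")
    rng = rng_for(config.seed, "evidence")
    records: list[EvidenceRecord] = []
    for gene in sorted(plan):
        for j, spec in enumerate(plan[gene]):
            lo, hi = spec.magnitude
            mag = float(lo) if lo == hi else float(rng.uniform(lo, hi))
            records.append(
                EvidenceRecord(
                    locus_id=config.locus_id,
                    target_type="gene",
                    target_id=gene,
                    study_id=f"{spec.study_type}_study_{gene}_{j}",
                    study_type=spec.study_type,
                    evidence_class=spec.evidence_class,
                    magnitude=mag,
                    n_sig=spec.n_sig,
                    n_exp=spec.n_exp,
                )
            )
    return records


def simulate_annotation(config: SimConfig) -> list:
    """Evenly spaced gene bodies across the candidate window of the block."""
    from .locus import GeneModel

    center = config.start_pos + config.spacing * (config.n_snps // 2)
    span = 2_400_000
    step = span // max(config.n_genes, 1)
    genes = []
    for i in range(config.n_genes):
        start = center - span // 2 + i * step
        genes.append(
            GeneModel(
                gene_id=f"GENE{i}",
                chrom=config.chrom,
                start=start,
                end=start + 20_000,
                strand="+" if i % 2 == 0 else "-",
            )
        )
    return genes


# ---------------------------------------------------------------------------
# Published locus summary fixture
# ---------------------------------------------------------------------------

_FIXTURE = "ad_locus_summary.tsv"


def table1_fixture() -> pd.DataFrame:
    """The published atopic-dermatitis locus summary table, as printed.

    26 rows (split loci appear as separate a/b rows; merged secondary-signal
    loci as one row).  Scores are comma-free integers and shares integer
    percentages, verbatim from print.  The 6p21.32 nearest-gene cell is
    reproduced as printed but flagged ``nearest_suspect`` (the printed STAT3
    resides on another chromosome and is likely a typesetting artifact).
    """
    path = files("genetriage").joinpath("data", _FIXTURE)
    df = pd.read_csv(path, sep="\t", dtype={"locus": str, "index_snps": str})
    for col in ("score1", "score2", "score3", "share1", "share2", "share3"):
        df[col] = df[col].astype(int)
    for col in ("secondary_signal", "nearest_suspect", "closest1", "closest2", "closest3"):
        df[col] = df[col].astype(bool)
    return df


def fixture_reports(df: pd.DataFrame | None = None) -> list[LocusReport]:
    """Convert the published locus table into per-locus reports.

    Only the printed top-3 genes are available, with integer shares; the
    classification rules (standout > 50% top-1 share; shared pair > 75%
    top-2 cumulative share) are applied to those printed values.
    """
    if df is None:
        df = table1_fixture()
    reports = []
    for row in df.itertuples(index=False):
        genes = [
            RankedTarget(rank=i + 1, target_id=g, score=float(s), share=float(sh))
            for i, (g, s, sh) in enumerate(
                (
                    (row.gene1, row.score1, row.share1),
                    (row.gene2, row.score2, row.share2),
                    (row.gene3, row.score3, row.share3),
                )
            )
        ]
        nearest = {tok for tok in str(row.nearest_genes).split("/") if normalize_symbol(tok)}
        if genes[0].share > 50:
            cls = Classification.STANDOUT
        elif genes[0].share + genes[1].share > 75:
            cls = Classification.SHARED_PAIR
        else:
            cls = Classification.AMBIGUOUS
        near_norm = {normalize_symbol(t) for t in nearest}
        reports.append(
            LocusReport(
                locus_id=row.locus,
                index_snp=str(row.index_snps).split("/")[0],
                genes=genes,
                snps=[],
                classification=cls,
                nearest_genes=nearest,
                nearest_gene_is_top=normalize_symbol(genes[0].target_id) in near_norm,
                index_snp_is_top=None,
                score_decay=genes[0].score / genes[2].score if genes[2].score else None,
            )
        )
    return reports
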