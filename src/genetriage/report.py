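"""Per-locus ranking, share metrics, locus classification, cross-locus summary.

A locus report ranks candidate genes (and SNPs) by total score and expresses
each of the top scores as a percentage of the summed top-10 scores.  Loci
are classified from the unrounded shares:

* **standout** — the top gene alone contributes > 50% of the top-10 sum;
* **shared_pair** — otherwise, the top two genes jointly exceed 75%;
* **ambiguous** — anything else.

Shares are reported half-up-rounded to integer percent for display, matching
how the published locus summary table prints them; classification always
uses full precision.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .scoring import TargetScore

logger = logging.getLogger(__name__)

__all__ = [
    "Classification",
    "RankedTarget",
    "LocusReport",
    "rank_targets",
    "top_share",
    "classify_locus",
    "build_locus_report",
    "crosslocus_summary",
    "normalize_symbol",
    "round_half_up",
]


class Classification(str, enum.Enum):
    STANDOUT = "standout"
    SHARED_PAIR = "shared_pair"
    AMBIGUOUS = "ambiguous"


def round_half_up(x: float) -> int:
    """Round to nearest integer with halves away from zero (display only)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def normalize_symbol(symbol: str) -> str:
    """Case- and hyphen-insensitive gene-symbol key (IL-6R == IL6R)."""
    return symbol.replace("-", "").replace("–", "").strip().upper()


@dataclass(frozen=True)
class RankedTarget:
    """One row of a per-locus ranking; ``share`` is % of the top-10 sum."""

    rank: int
    target_id: str
    score: float
    share: float  # full precision; use round_half_up(share) for display


def rank_targets(
    scores: Sequence[TargetScore],
    distance: Mapping[str, float] | None = None,
) -> list[TargetScore]:
    """Sort target scores descending by total, deterministically.

    Ties are broken by smaller distance to the index SNP (when ``distance``
    supplies one; targets without a known distance sort last), then by
    lexicographic target id.
    """
    dist = distance or {}
    return sorted(
        scores,
        key=lambda s: (-s.total, dist.get(s.target_id, math.inf), s.target_id),
    )


def top_share(totals: Sequence[float], k: int = 10, m: int = 1) -> float:
    """Percentage of the top-``k`` score sum carried by the top ``m`` targets.

    ``totals`` must be sorted descending.  A zero denominator yields share 0
    with a warning (degenerate all-zero locus).
    """
    denom = sum(totals[: min(k, len(totals))])
    if denom == 0:
        logger.warning("top-%d score sum is 0; share defined as 0", k)
        return 0.0
    return 100.0 * sum(totals[:m]) / denom


def classify_locus(totals: Sequence[float], k: int = 10) -> Classification:
    """Classify a locus from its descending-sorted gene totals (unrounded)."""
    if top_share(totals, k=k, m=1) > 50.0:
        return Classification.STANDOUT
    if len(totals) >= 2 and top_share(totals, k=k, m=2) > 75.0:
        return Classification.SHARED_PAIR
    return Classification.AMBIGUOUS


@dataclass
class LocusReport:
    """Ranked targets, shares and classification for one locus."""

    locus_id: str
    index_snp: str
    genes: list[RankedTarget] = field(default_factory=list)
    snps: list[RankedTarget] = field(default_factory=list)
    classification: Classification = Classification.AMBIGUOUS
    nearest_genes: set[str] = field(default_factory=set)
    nearest_gene_is_top: bool | None = None
    index_snp_is_top: bool | None = None
    score_decay: float | None = None  # score[1] / score[3], descriptive only

    @property
    def top_gene(self) -> RankedTarget | None:
        return self.genes[0] if self.genes else None

    def top2_cumulative_share(self) -> float:
        return sum(g.share for g in self.genes[:2])


def _ranked(scores: Sequence[TargetScore], distance: Mapping[str, float] | None, k: int) -> list[RankedTarget]:
    ordered = rank_targets(scores, distance)
    totals = [s.total for s in ordered]
    denom = sum(totals[: min(k, len(totals))])
    return [
        RankedTarget(
            rank=i + 1,
            target_id=s.target_id,
            score=s.total,
            share=100.0 * s.total / denom if denom > 0 else 0.0,
        )
        for i, s in enumerate(ordered)
    ]


def build_locus_report(
    locus_id: str,
    index_snp: str,
    gene_scores: Sequence[TargetScore],
    snp_scores: Sequence[TargetScore] = (),
    nearest_genes: Iterable[str] = (),
    gene_distance: Mapping[str, float] | None = None,
    snp_distance: Mapping[str, float] | None = None,
    k: int = 10,
) -> LocusReport:
    """Assemble a :class:`LocusReport` from scored targets.

    ``gene_distance`` / ``snp_distance`` supply bp distances to the index SNP
    for deterministic tie-breaking.
    """
    genes = _ranked(gene_scores, gene_distance, k)
    snps = _ranked(snp_scores, snp_distance, k)
    totals = [g.score for g in genes]
    near = {normalize_symbol(g) for g in nearest_genes}
    top_is_near = None
    if genes and near:
        top_is_near = normalize_symbol(genes[0].target_id) in near
    top_snp_is_index = None
    if snps:
        top_snp_is_index = snps[0].target_id == index_snp
    decay = None
    if len(genes) >= 3 and genes[2].score > 0:
        decay = genes[0].score / genes[2].score
    return LocusReport(
        locus_id=locus_id,
        index_snp=index_snp,
        genes=genes,
        snps=snps,
        classification=classify_locus(totals, k=k),
        nearest_genes=set(nearest_genes),
        nearest_gene_is_top=top_is_near,
        index_snp_is_top=top_snp_is_index,
        score_decay=decay,
    )


def crosslocus_summary(reports: Sequence[LocusReport]) -> dict:
    """Cross-locus counts plus a one-row-per-locus digest table.

    Counts: loci whose top gene is not among the nearest genes; loci whose
    top SNP differs from the index SNP (among loci with SNP rankings);
    standout and shared-pair loci; min/max of the top-gene totals.
    """
    rows = []
    for rep in reports:
        top = rep.top_gene
        rows.append(
            {
                "locus": rep.locus_id,
                "index_snp": rep.index_snp,
                "nearest_genes": "/".join(sorted(rep.nearest_genes)),
                "top1": top.target_id if top else "",
                "top1_score": top.score if top else 0.0,
                "top1_share": round_half_up(top.share) if top else 0,
                "top2": rep.genes[1].target_id if len(rep.genes) > 1 else "",
                "top2_cum_share": round_half_up(rep.top2_cumulative_share()),
                "classification": rep.classification.value,
                "nearest_gene_is_top": rep.nearest_gene_is_top,
                "index_snp_is_top": rep.index_snp_is_top,
            }
        )
    digest = pd.DataFrame(rows)
    with_genes = [r for r in reports if r.genes]
    return {
        "n_loci": len(reports),
        "n_nearest_gene_mismatch": sum(1 for r in reports if r.nearest_gene_is_top is False),
        "n_top_snp_not_index": sum(1 for r in reports if r.index_snp_is_top is False),
        "n_standout": sum(1 for r in reports if r.classification is Classification.STANDOUT),
        "n_shared_pair": sum(1 for r in reports if r.classification is Classification.SHARED_PAIR),
        "top_gene_score_min": min((r.top_gene.score for r in with_genes), default=0.0),
        "top_gene_score_max": max((r.top_gene.score for r in with_genes), default=0.0),
        "top_gene_share_max": max((r.top_gene.share for r in with_genes), default=0.0),
        "digest": digest,
    }
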