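"""Score and rank candidate genes at one locus from a hand-built evidence set.

Builds a small locus (four candidate genes around an index SNP), assembles a
mixed evidence table — a colocalization posterior, a TWAS hit, an eQTL
lookup, an enhancer-loop overlap and a machine-learning prediction — and
prints each gene's prioritization score with its breakdown factors.
"""

from genetriage import EvidenceClass, EvidenceRecord, LocusDefinition, score_locus
from genetriage.report import build_locus_report

locus = LocusDefinition(
    locus_id="demo",
    index_snp="rs111",
    chrom="11",
    index_pos=35_300_000,
    interval=(35_100_000, 35_500_000),
    gene_window=(33_800_000, 36_800_000),
    candidate_genes=["PRR5L", "TRAF6", "COMMD9", "ARL14EP"],
    nearest_genes={"PRR5L"},
)

def rec(target, study_id, study_type, ec, magnitude, n_sig=1, **kw):
    return EvidenceRecord(
        locus_id="demo", target_type=kw.pop("target_type", "gene"), target_id=target,
        study_id=study_id, study_type=study_type, evidence_class=ec,
        magnitude=magnitude, n_sig=n_sig, **kw,
    )

evidence = [
    rec("PRR5L", "eqtlgen_blood", "coloc", EvidenceClass.STAT_FULL, 0.97),
    rec("PRR5L", "gtex_skin_twas", "twas", EvidenceClass.STAT_FULL, 0.81),
    rec("PRR5L", "blueprint_tcell", "eqtl", EvidenceClass.OVERLAP, 1.0, n_sig=240),
    rec("rs111", "hic_tcell", "enhancer_loop", EvidenceClass.OVERLAP, 1.0,
        target_type="snp", linked_gene="PRR5L"),
    rec("TRAF6", "kgg_pred", "regulatory_pred", EvidenceClass.PREDICTION, 0.66),
    rec("TRAF6", "gtex_skin_twas", "twas", EvidenceClass.STAT_FULL, 0.22),
]

gene_scores, snp_scores = score_locus(locus, evidence)
report = build_locus_report("demo", "rs111", gene_scores, snp_scores, nearest_genes=locus.nearest_genes)

print(f"{'rank':>4} {'gene':<8} {'score':>8} {'share%':>7}  breakdown (class x magnitude x specificity / sqrt(k))")
for g in report.genes:
    ts = next(s for s in gene_scores if s.target_id == g.target_id)
    parts = "; ".join(
        f"{c.record.study_type}:{c.value:.2f}" for c in ts.components
    ) or "no evidence"
    print(f"{g.rank:>4} {g.target_id:<8} {g.score:>8.2f} {g.share:>7.1f}  {parts}")
print(f"\nclassification: {report.classification.value} "
      f"(top gene carries {report.genes[0].share:.0f}% of the top-10 score sum)")

# Full-summary-statistic tests dominate: one colocalization at H4 = 0.97
# contributes 19.4 before heterogeneity, ten times an equivalent lookup.
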