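import logging
import math

import pytest

from genetriage.evidence import EvidenceClass
from genetriage.locus import LocusDefinition
from genetriage.scoring import (
    component_score,
    heterogeneity_multiplier,
    independence_divisor,
    score_locus,
    score_target,
    specificity_factor,
)


class TestComponentScore:
    def test_stat_full_vs_overlap_ratio_is_exactly_ten(self, make_record):
        coloc = make_record(evidence_class=EvidenceClass.STAT_FULL, magnitude=0.8)
        lookup = make_record(evidence_class=EvidenceClass.OVERLAP, magnitude=0.8)
        v1 = component_score(coloc).value
        v2 = component_score(lookup).value
        assert v1 / v2 == 10.0

    def test_overlap_vs_prediction_ratio_is_exactly_two(self, make_record):
        v1 = component_score(make_record(evidence_class=EvidenceClass.OVERLAP, magnitude=0.8)).value
        v2 = component_score(make_record(evidence_class=EvidenceClass.PREDICTION, magnitude=0.8)).value
        assert v1 / v2 == 2.0

    def test_zero_magnitude_zeroes_the_component(self, make_record):
        assert component_score(make_record(magnitude=0.0)).value == 0.0

    def test_all_factors_combine_multiplicatively(self, make_record):
        # 20 * 0.9 * 1/(1+log10(100)) / sqrt(4) = 20 * 0.9 / 3 / 2
        rec = make_record(evidence_class=EvidenceClass.STAT_FULL, magnitude=0.9, n_sig=100)
        comp = component_score(rec, n_same_study=4)
        assert comp.value == pytest.approx(3.0, rel=1e-12)
        assert comp.specificity_factor == pytest.approx(1 / 3)
        assert comp.independence_divisor == 2.0

    def test_value_never_exceeds_class_weight(self, make_record):
        comp = component_score(make_record(evidence_class=EvidenceClass.STAT_FULL, magnitude=1.0))
        assert comp.value == 20.0


def test_specificity_damps_nonspecific_experiments():
    assert specificity_factor(1) == 1.0
    assert specificity_factor(100) == pytest.approx(1 / 3)
    prev = specificity_factor(1)
    for n in (2, 10, 100, 10_000, 1_000_000):
        cur = specificity_factor(n)
        assert cur < prev
        prev = cur


def test_independence_divisor_is_sqrt_k():
    assert independence_divisor(1) == 1.0
    assert independence_divisor(4) == 2.0
    with pytest.raises(ValueError):
        independence_divisor(0)


class TestHeterogeneityMultiplier:
    def test_four_types_four_studies_doubles(self, make_record):
        recs = [
            make_record(study_type=t, study_id=f"s{i}")
            for i, t in enumerate(["eqtl", "pqtl", "twas", "coloc"])
        ]
        assert heterogeneity_multiplier(recs) == 2.0

    def test_single_source_is_identity(self, make_record):
        assert heterogeneity_multiplier([make_record()]) == 1.0

    def test_two_types_eight_studies(self, make_record):
        recs = [
            make_record(study_type="eqtl" if i % 2 else "pqtl", study_id=f"s{i}")
            for i in range(8)
        ]
        assert heterogeneity_multiplier(recs) == pytest.approx(math.sqrt(5))

    def test_empty_set_is_identity(self):
        assert heterogeneity_multiplier([]) == 1.0


class TestScoreTarget:
    def test_no_records_scores_zero(self):
        ts = score_target("GENE0", "gene", [])
        assert ts.total == 0.0 and ts.raw_sum == 0.0

    def test_single_full_weight_record(self, make_record):
        rec = make_record(evidence_class=EvidenceClass.STAT_FULL, magnitude=1.0)
        assert score_target("GENE0", "gene", [rec]).total == 20.0

    def test_three_source_example(self, make_record):
        recs = [
            make_record(evidence_class=EvidenceClass.STAT_FULL, magnitude=0.8, study_id="s1", study_type="coloc"),
            make_record(evidence_class=EvidenceClass.OVERLAP, magnitude=1.0, study_id="s2", study_type="eqtl"),
            make_record(evidence_class=EvidenceClass.PREDICTION, magnitude=0.5, study_id="s3", study_type="regulatory_pred"),
        ]
        ts = score_target("GENE0", "gene", recs)
        assert ts.raw_sum == pytest.approx(18.5)
        assert ts.heterogeneity == pytest.approx(math.sqrt(3))
        assert ts.total == pytest.approx(32.043, abs=1e-3)

    def test_same_study_records_share_independence_divisor(self, make_record):
        recs = [
            make_record(magnitude=1.0, study_id="s1", study_type="eqtl"),
            make_record(magnitude=1.0, study_id="s1", study_type="mqtl"),
        ]
        ts = score_target("GENE0", "gene", recs)
        # each of the two same-study components is divided by sqrt(2);
        # heterogeneity sqrt((2 types + 1 study)/2)
        assert ts.raw_sum == pytest.approx(2 * 2.0 / math.sqrt(2))
        assert ts.total == pytest.approx(ts.raw_sum * math.sqrt(1.5))

    def test_adding_positive_evidence_never_decreases_total(self, make_record):
        base = [make_record(magnitude=0.5, study_id="s1")]
        extra_cases = [
            make_record(magnitude=0.2, study_id="s2", study_type="pqtl"),
            make_record(magnitude=0.9, study_id="s1", study_type="eqtl", target_id="GENE0"),
            make_record(evidence_class=EvidenceClass.PREDICTION, magnitude=0.05, study_id="s9"),
        ]
        t0 = score_target("GENE0", "gene", base).total
        for extra in extra_cases:
            assert score_target("GENE0", "gene", base + [extra]).total >= t0

    def test_total_nonincreasing_in_n_sig(self, make_record):
        totals = [
            score_target("GENE0", "gene", [make_record(magnitude=0.7, n_sig=n)]).total
            for n in (1, 5, 50, 5000)
        ]
        assert totals == sorted(totals, reverse=True)

    def test_determinism(self, make_record):
        recs = [make_record(magnitude=0.3, study_id=f"s{i}", study_type="eqtl") for i in range(5)]
        a = score_target("GENE0", "gene", recs)
        b = score_target("GENE0", "gene", list(recs))
        assert a.total == b.total and a.raw_sum == b.raw_sum


def _locus(genes=("A", "B"), interval=(1_000_000, 2_000_000)):
    return LocusDefinition(
        locus_id="L1",
        index_snp="rs_idx",
        chrom="1",
        index_pos=(interval[0] + interval[1]) // 2,
        interval=interval,
        gene_window=(1, 3_000_000),
        candidate_genes=list(genes),
        nearest_genes={genes[0]},
    )


class TestScoreLocus:
    def test_gene_without_evidence_scores_zero(self, make_record):
        gene_scores, _ = score_locus(_locus(), [make_record(target_id="A")])
        by_id = {s.target_id: s.total for s in gene_scores}
        assert by_id["B"] == 0.0 and by_id["A"] > 0

    def test_snp_outside_interval_contributes_nothing(self, make_record):
        rec = make_record(target_type="snp", target_id="rs_out")
        _, snp_scores = score_locus(_locus(), [rec], snp_positions={"rs_out": 5_000_000})
        assert snp_scores == []

    def test_snp_record_propagates_to_linked_gene(self, make_record):
        rec = make_record(target_type="snp", target_id="rs_in", linked_gene="A")
        gene_scores, snp_scores = score_locus(_locus(), [rec], snp_positions={"rs_in": 1_500_000})
        by_id = {s.target_id: s.total for s in gene_scores}
        assert by_id["A"] == pytest.approx(component_score(rec).value)
        assert len(snp_scores) == 1 and snp_scores[0].target_id == "rs_in"

    def test_evidence_for_gene_outside_window_skipped_with_warning(self, make_record, caplog):
        with caplog.at_level(logging.WARNING):
            gene_scores, _ = score_locus(_locus(), [make_record(target_id="ELSEWHERE")])
        assert all(s.total == 0 for s in gene_scores)
        assert any("ELSEWHERE" in m for m in caplog.messages)

    def test_planted_gene_outranks_decoys(self, make_record):
        locus = _locus(genes=("P", "D1", "D2", "D3"))
        records = [
            make_record(
                target_id="P",
                evidence_class=EvidenceClass.STAT_FULL,
                magnitude=0.9,
                study_id=f"s{i}",
                study_type=t,
            )
            for i, t in enumerate(["coloc", "twas", "finemap"])
        ] + [
            make_record(target_id=d, evidence_class=EvidenceClass.OVERLAP, magnitude=1.0, study_id=f"d_{d}")
            for d in ("D1", "D2", "D3")
        ]
        gene_scores, _ = score_locus(locus, records)
        best = max(gene_scores, key=lambda s: s.total)
        assert best.target_id == "P"
        # direct arithmetic: 3 * 20 * 0.9 * sqrt(3) vs 2 * 1
        assert best.total == pytest.approx(54 * math.sqrt(3))
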