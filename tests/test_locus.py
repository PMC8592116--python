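import logging

import numpy as np
import pytest

from genetriage.locus import (
    GeneModel,
    build_locus,
    candidate_genes,
    define_locus_interval,
    gene_window,
    nearest_genes,
    read_gene_annotation,
)
from oracles import brute_candidates, brute_interval, brute_nearest

IDX = 102_000_000


class TestLocusInterval:
    def test_furthest_qualifying_snps_bound_the_interval(self):
        pos = [101_700_000, 102_300_000, 102_800_000]
        r2 = [0.35, 0.21, 0.9]  # third is beyond the 500-kb cap
        assert define_locus_interval(IDX, pos, r2) == (101_700_000, 102_300_000)

    def test_cap_truncates_one_side_only(self):
        pos = [101_400_000, 102_300_000]  # 5' qualifier 600 kb away
        r2 = [0.5, 0.3]
        assert define_locus_interval(IDX, pos, r2) == (IDX, 102_300_000)

    def test_empty_ld_table_degenerates_to_index(self, caplog):
        with caplog.at_level(logging.WARNING):
            assert define_locus_interval(IDX, [], []) == (IDX, IDX)
        assert any("degenerate" in m for m in caplog.messages)

    def test_subthreshold_r2_ignored(self):
        assert define_locus_interval(IDX, [101_900_000], [0.19]) == (IDX, IDX)

    def test_r2_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            define_locus_interval(IDX, [101_900_000], [1.2])

    def test_monotone_in_r2_threshold_and_cap(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = rng.integers(1, 40)
            pos = IDX + rng.integers(-800_000, 800_000, size=n)
            r2 = rng.uniform(0, 1, size=n)
            lo1, hi1 = define_locus_interval(IDX, pos, r2, r2_min=0.2)
            lo2, hi2 = define_locus_interval(IDX, pos, r2, r2_min=0.5)
            assert lo2 >= lo1 and hi2 <= hi1  # stricter r2 never widens
            lo3, hi3 = define_locus_interval(IDX, pos, r2, max_dist=700_000)
            assert lo3 <= lo1 and hi3 >= hi1  # larger cap never narrows

    def test_matches_brute_force_on_randomized_fixtures(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            n = rng.integers(0, 30)
            pos = IDX + rng.integers(-900_000, 900_000, size=n)
            r2 = rng.uniform(0, 1, size=n)
            assert define_locus_interval(IDX, pos, r2) == brute_interval(IDX, pos, r2)


class TestGeneWindow:
    def test_three_megabase_window_centered_on_index(self):
        assert gene_window(IDX) == (IDX - 1_500_000, IDX + 1_500_000)

    def test_clipped_at_chromosome_start(self):
        assert gene_window(1_000_000) == (1, 2_500_000)


class TestCandidateGenes:
    def test_gene_outside_window_excluded(self):
        g = GeneModel("A", "1", IDX - 1_600_000, IDX - 1_550_000)
        assert candidate_genes(gene_window(IDX), "1", [g]) == []

    def test_gene_straddling_window_edge_included(self):
        g = GeneModel("A", "1", IDX - 1_501_000, IDX - 1_499_000)
        assert candidate_genes(gene_window(IDX), "1", [g]) == [g]

    def test_locus_fixture_returns_all_three_known_genes(self, toy_annotation):
        idx = 35_300_000
        ids = [g.gene_id for g in candidate_genes(gene_window(idx), "11", toy_annotation)]
        assert ids == ["PRR5L", "COMMD9", "TRAF6"]  # ordered by start

    def test_wrong_chromosome_yields_empty_with_warning(self, caplog):
        g = GeneModel("A", "2", IDX, IDX + 1000)
        with caplog.at_level(logging.WARNING):
            assert candidate_genes(gene_window(IDX), "1", [g]) == []
        assert any("chromosome" in m for m in caplog.messages)

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            genes = []
            for k in range(rng.integers(0, 25)):
                start = int(rng.integers(IDX - 3_000_000, IDX + 3_000_000))
                genes.append(GeneModel(f"G{k}", "1", start, start + int(rng.integers(1, 400_000))))
            win = gene_window(IDX)
            assert candidate_genes(win, "1", genes) == brute_candidates(win, "1", genes)


class TestNearestGenes:
    def test_index_inside_gene_is_unique_nearest(self):
        genes = [GeneModel("A", "1", IDX - 1000, IDX + 1000), GeneModel("B", "1", IDX + 5000, IDX + 9000)]
        assert nearest_genes(IDX, genes) == {"A"}

    def test_one_nearest_per_direction(self):
        genes = [
            GeneModel("UP", "1", IDX - 20_000, IDX - 5_000),  # 5 kb upstream
            GeneModel("UP_FAR", "1", IDX - 90_000, IDX - 60_000),
            GeneModel("DOWN", "1", IDX + 12_000, IDX + 30_000),  # 12 kb downstream
        ]
        assert nearest_genes(IDX, genes) == {"UP", "DOWN"}

    def test_equidistant_tie_returns_both(self):
        genes = [
            GeneModel("T1", "1", IDX - 15_000, IDX - 5_000),
            GeneModel("T2", "1", IDX - 25_000, IDX - 5_000),
            GeneModel("D", "1", IDX + 40_000, IDX + 50_000),
        ]
        assert nearest_genes(IDX, genes) == brute_nearest(IDX, genes) == {"T1", "T2", "D"}

    def test_empty_annotation_rejected(self):
        with pytest.raises(ValueError):
            nearest_genes(IDX, [])

    def test_matches_brute_force_on_random_annotations(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            genes = []
            for k in range(rng.integers(1, 20)):
                start = int(rng.integers(IDX - 2_000_000, IDX + 2_000_000))
                genes.append(GeneModel(f"G{k}", "1", start, start + int(rng.integers(1, 100_000))))
            assert nearest_genes(IDX, genes) == brute_nearest(IDX, genes)


class TestBuildLocus:
    def test_nearest_genes_within_candidates_for_nondegenerate_window(self, toy_annotation):
        import pandas as pd

        idx = 35_300_000
        ld = pd.DataFrame({"pos": [35_100_000, 35_500_000], "r2": [0.4, 0.3]})
        locus = build_locus("11p13", "rs2592555", "11", idx, ld, toy_annotation)
        assert locus.interval == (35_100_000, 35_500_000)
        assert locus.nearest_genes <= set(locus.candidate_genes)

    def test_secondary_signal_merges_interval_and_window(self, toy_annotation):
        import pandas as pd

        idx, idx2 = 35_300_000, 36_400_000
        ld1 = pd.DataFrame({"pos": [35_200_000], "r2": [0.5]})
        ld2 = pd.DataFrame({"pos": [36_600_000], "r2": [0.5]})
        locus = build_locus(
            "11p13", "rs2592555", "11", idx, ld1, toy_annotation,
            secondary=[("rs12295535", idx2, ld2)],
        )
        assert locus.interval == (35_200_000, 36_600_000)
        assert locus.gene_window == (idx - 1_500_000, idx2 + 1_500_000)
        assert locus.secondary_index_snps == ["rs12295535"]


class TestAnnotationReaders:
    def test_bed_is_converted_to_one_based_inclusive(self, tmp_path):
        p = tmp_path / "genes.bed"
        p.write_text("1\t999\t2000\tA\t0\t-\n1\t5000\t6000\tB\n")
        genes = read_gene_annotation(p)
        assert genes[0] == GeneModel("A", "1", 1000, 2000, "-")
        assert genes[1].start == 5001 and genes[1].strand == "+"

    def test_gff3_gene_features_parsed(self, tmp_path):
        p = tmp_path / "genes.gff3"
        p.write_text(
            "##gff-version 3\n"
            "1\tsrc\tgene\t1000\t2000\t.\t-\t.\tID=A;Name=ALPHA\n"
            "1\tsrc\texon\t1000\t1200\t.\t-\t.\tID=A.e1\n"
        )
        genes = read_gene_annotation(p)
        assert len(genes) == 1
        g = genes[0]
        assert (g.gene_id, g.start, g.end, g.strand, g.symbol) == ("A", 1000, 2000, "-", "ALPHA")
        assert g.tss == 2000  # minus strand


def test_tss_follows_strand():
    assert GeneModel("A", "1", 100, 200, "+").tss == 100
    assert GeneModel("A", "1", 100, 200, "-").tss == 200
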