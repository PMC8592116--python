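import numpy as np
import pytest

from genetriage import EvidenceClass, EvidenceRecord, GeneModel
from genetriage.coloc import SummaryStats


@pytest.fixture
def make_record():
    """Factory for evidence records with sensible defaults."""

    def _make(**kwargs):
        base = dict(
            locus_id="L1",
            target_type="gene",
            target_id="GENE0",
            study_id="study_a",
            study_type="eqtl",
            evidence_class=EvidenceClass.OVERLAP,
            magnitude=0.5,
        )
        base.update(kwargs)
        return EvidenceRecord(**base)

    return _make


@pytest.fixture
def make_stats():
    """Factory for a SummaryStats panel from z-scores (se = 0.1)."""

    def _make(z, trait="t", trait_type="quant", se=0.1, ids=None):
        z = np.asarray(z, dtype=float)
        n = len(z)
        ids = np.array(ids if ids is not None else [f"rs{i}" for i in range(n)], dtype=object)
        se_arr = np.full(n, se)
        return SummaryStats(
            trait=trait,
            ids=ids,
            pos=np.arange(n) * 1000 + 1_000_000,
            beta=z * se_arr,
            se=se_arr,
            trait_type=trait_type,
        )

    return _make


@pytest.fixture
def toy_annotation():
    """Five genes on chr11 around an index at 35,000,000 (11p13-like)."""
    return [
        GeneModel("PRR5L", "11", 35_026_000, 35_082_000, "+"),
        GeneModel("TRAF6", "11", 36_483_000, 36_510_000, "-"),
        GeneModel("COMMD9", "11", 36_294_000, 36_310_000, "+"),
        GeneModel("FAR_GENE", "11", 39_000_000, 39_050_000, "+"),
        GeneModel("OTHER_CHR", "12", 35_000_000, 35_050_000, "+"),
    ]
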