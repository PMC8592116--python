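"""Evidence-record data model and the TSV dialect through which evidence enters.

Every external result that supports a gene or a variant at a GWAS locus —
a colocalization posterior, a TWAS hit, a QTL lookup, a promoter–enhancer
loop overlap, an in-silico regulatory prediction — is ingested as one row of
a tab-delimited *evidence table*.  A row is one unit of support: a
study × experiment × target triple carrying

* an evidence class (``stat_full`` / ``overlap`` / ``prediction``) that
  determines its base weight,
* a magnitude normalized to [0, 1] by the producer before ingestion,
* specificity metadata (``n_sig``: how many SNPs/genes the source experiment
  reported significant) and independence metadata (``n_exp``: how many
  experiments the same study contributed).

The scoring engine is agnostic to the source statistic; the closed [0, 1]
magnitude scale keeps the class weights dominant.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "EvidenceClass",
    "EvidenceRecord",
    "WeightScheme",
    "DEFAULT_WEIGHTS",
    "STUDY_TYPES",
    "EVIDENCE_COLUMNS",
    "EvidenceSchemaError",
    "EvidenceValidationError",
    "class_weight",
    "read_evidence_table",
    "write_evidence_table",
]


class EvidenceClass(str, enum.Enum):
    """Three-tier classification of evidence strength.

    ``STAT_FULL``
        Statistical tests run on a full set of summary statistics
        (colocalization, TWAS/SMR, fine-mapping).
    ``OVERLAP``
        Positional overlap with significant experimental results
        (QTL lookups, enhancer loops, differential expression hits).
    ``PREDICTION``
        In-silico predictions from machine-learning models.
    """

    STAT_FULL = "stat_full"
    OVERLAP = "overlap"
    PREDICTION = "prediction"


#: Closed (but configurable) controlled vocabulary of study types.  Unknown
#: types are accepted with a warning and counted as their own unique type,
#: so the pipeline extends to other diseases without code changes.
STUDY_TYPES: frozenset[str] = frozenset(
    {
        "eqtl",
        "pqtl",
        "mqtl",
        "hqtl",
        "caqtl",
        "twas",
        "coloc",
        "finemap",
        "dge",
        "dna_methylation_diff",
        "proteome_diff",
        "enhancer_loop",
        "tad",
        "ctcf",
        "ncrna",
        "tf_binding",
        "splice_pred",
        "regulatory_pred",
        "gwas_catalog",
    }
)

_DIRECTIONS = {"up", "down", "na"}


class EvidenceSchemaError(ValueError):
    """The evidence table is structurally invalid (e.g. a missing column)."""


class EvidenceValidationError(ValueError):
    """A row violates a field invariant (reported with its line number)."""


@dataclass(frozen=True)
class EvidenceRecord:
    """One unit of support for a SNP or gene target.

    ``linked_gene`` is only meaningful for SNP-level evidence that names a
    target gene (an eQTL lookup, a promoter–enhancer loop); such records
    propagate to that gene's score as well as the SNP's.  Gene-level records
    must leave it unset.
    """

    locus_id: str
    target_type: str  # "snp" | "gene"
    target_id: str
    study_id: str
    study_type: str
    evidence_class: EvidenceClass
    magnitude: float
    linked_gene: str | None = None
    n_sig: int = 1
    n_exp: int = 1
    tissue: str | None = None
    direction: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "evidence_class", EvidenceClass(self.evidence_class))
        if self.target_type not in ("snp", "gene"):
            raise EvidenceValidationError(
                f"target_type must be 'snp' or 'gene', got {self.target_type!r}"
            )
        m = float(self.magnitude)
        if not (math.isfinite(m) and 0.0 <= m <= 1.0):
            raise EvidenceValidationError(f"magnitude must be in [0, 1], got {self.magnitude!r}")
        object.__setattr__(self, "magnitude", m)
        if int(self.n_sig) < 1:
            raise EvidenceValidationError(f"n_sig must be >= 1, got {self.n_sig!r}")
        if int(self.n_exp) < 1:
            raise EvidenceValidationError(f"n_exp must be >= 1, got {self.n_exp!r}")
        object.__setattr__(self, "n_sig", int(self.n_sig))
        object.__setattr__(self, "n_exp", int(self.n_exp))
        if self.target_type == "gene" and self.linked_gene:
            raise EvidenceValidationError("gene-level records must not set linked_gene")
        if self.linked_gene == "":
            object.__setattr__(self, "linked_gene", None)
        if self.direction == "":
            object.__setattr__(self, "direction", None)
        if self.direction is not None and self.direction not in _DIRECTIONS:
            raise EvidenceValidationError(
                f"direction must be one of {sorted(_DIRECTIONS)}, got {self.direction!r}"
            )
        if self.tissue == "":
            object.__setattr__(self, "tissue", None)


@dataclass(frozen=True)
class WeightScheme:
    """Per-class base weights; defaults are the 20/2/1 three-tier scheme."""

    stat_full: float = 20.0
    overlap: float = 2.0
    prediction: float = 1.0

    def __post_init__(self) -> None:
        if not (self.stat_full > self.overlap > self.prediction > 0):
            raise ValueError(
                "weights must satisfy stat_full > overlap > prediction > 0, got "
                f"({self.stat_full}, {self.overlap}, {self.prediction})"
            )

    def weight(self, evidence_class: EvidenceClass) -> float:
        return class_weight(evidence_class, self)


DEFAULT_WEIGHTS = WeightScheme()


def class_weight(evidence_class: EvidenceClass | str, scheme: WeightScheme = DEFAULT_WEIGHTS) -> float:
    """Base weight of an evidence class under ``scheme`` (defaults 20/2/1)."""
    ec = EvidenceClass(evidence_class)
    return {
        EvidenceClass.STAT_FULL: scheme.stat_full,
        EvidenceClass.OVERLAP: scheme.overlap,
        EvidenceClass.PREDICTION: scheme.prediction,
    }[ec]


#: Mandatory evidence-table header, in order.
EVIDENCE_COLUMNS = [
    "locus_id",
    "target_type",
    "target_id",
    "linked_gene",
    "study_id",
    "study_type",
    "evidence_class",
    "magnitude",
    "n_sig",
    "n_exp",
    "tissue",
    "direction",
]

def _record_from_row(row: dict[str, str]) -> EvidenceRecord:
    def opt_int(key: str) -> int:
        v = row.get(key, "")
        return int(v) if v != "" else 1

    return EvidenceRecord(
        locus_id=row["locus_id"],
        target_type=row["target_type"],
        target_id=row["target_id"],
        linked_gene=row.get("linked_gene") or None,
        study_id=row["study_id"],
        study_type=row["study_type"],
        evidence_class=row["evidence_class"],
        magnitude=float(row["magnitude"]),
        n_sig=opt_int("n_sig"),
        n_exp=opt_int("n_exp"),
        tissue=row.get("tissue") or None,
        direction=row.get("direction") or None,
    )


def read_evidence_table(path) -> list[EvidenceRecord]:
    """Read and validate an evidence table, preserving row order.

    Unknown extra columns are ignored with a logged warning; an empty file
    yields an empty list.  A missing mandatory column raises
    :class:`EvidenceSchemaError`; an invalid field raises
    :class:`EvidenceValidationError` citing the 1-based file line number.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        return []
    missing = [c for c in EVIDENCE_COLUMNS if c not in df.columns]
    if missing:
        raise EvidenceSchemaError(f"evidence table missing mandatory column(s): {', '.join(missing)}")
    extra = [c for c in df.columns if c not in EVIDENCE_COLUMNS]
    if extra:
        logger.warning("ignoring unknown evidence-table column(s): %s", ", ".join(extra))

    records: list[EvidenceRecord] = []
    unknown_types: set[str] = set()
    for i, row in enumerate(df.to_dict(orient="records")):
        line = i + 2  # 1-based, after the header line
        try:
            rec = _record_from_row(row)
        except (EvidenceValidationError, ValueError) as exc:
            raise EvidenceValidationError(f"line {line}: {exc}") from exc
        if rec.study_type not in STUDY_TYPES:
            unknown_types.add(rec.study_type)
        records.append(rec)
    for st in sorted(unknown_types):
        logger.warning("study_type %r is not in the controlled vocabulary; treated as its own type", st)
    return records


def write_evidence_table(records, path) -> None:
    """Write records as an evidence-table TSV; round-trips all fields exactly.

    Floats are written with ``repr`` so that reading the file back
    reproduces the magnitude bit-exactly.
    """
    rows = []
    for rec in records:
        rows.append(
            {
                "locus_id": rec.locus_id,
                "target_type": rec.target_type,
                "target_id": rec.target_id,
                "linked_gene": rec.linked_gene or "",
                "study_id": rec.study_id,
                "study_type": rec.study_type,
                "evidence_class": rec.evidence_class.value,
                "magnitude": repr(rec.magnitude),
                "n_sig": rec.n_sig,
                "n_exp": rec.n_exp,
                "tissue": rec.tissue or "",
                "direction": rec.direction or "",
            }
        )
    pd.DataFrame(rows, columns=EVIDENCE_COLUMNS).to_csv(path, sep="\t", index=False)


# Default producer -> evidence-class mapping for the ingestion boundary:
# full-summary-statistic tests -> stat_full; experimental lookups/overlaps and
# case-control comparisons -> overlap; in-silico predictors -> prediction.
# Configurable because the tiers, not the membership list, are the contract.
DEFAULT_CLASS_BY_STUDY_TYPE: dict[str, EvidenceClass] = {
    "coloc": EvidenceClass.STAT_FULL,
    "twas": EvidenceClass.STAT_FULL,
    "finemap": EvidenceClass.STAT_FULL,
    "eqtl": EvidenceClass.OVERLAP,
    "pqtl": EvidenceClass.OVERLAP,
    "mqtl": EvidenceClass.OVERLAP,
    "hqtl": EvidenceClass.OVERLAP,
    "caqtl": EvidenceClass.OVERLAP,
    "dge": EvidenceClass.OVERLAP,
    "dna_methylation_diff": EvidenceClass.OVERLAP,
    "proteome_diff": EvidenceClass.OVERLAP,
    "enhancer_loop": EvidenceClass.OVERLAP,
    "tad": EvidenceClass.OVERLAP,
    "ctcf": EvidenceClass.OVERLAP,
    "ncrna": EvidenceClass.OVERLAP,
    "tf_binding": EvidenceClass.OVERLAP,
    "gwas_catalog": EvidenceClass.OVERLAP,
    "splice_pred": EvidenceClass.PREDICTION,
    "regulatory_pred": EvidenceClass.PREDICTION,
}
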