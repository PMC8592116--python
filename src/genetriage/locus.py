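"""LD-based locus geometry: intervals, gene windows, nearest genes.

Two regions are attached to every GWAS index SNP:

* the **locus interval** — spanned by the furthest 5' and 3' SNPs with
  r² >= 0.2 to the index SNP, capped at 500 kb per side.  SNP-level evidence
  and SNP rankings are restricted to this interval.
* the **candidate-gene window** — the 3-Mb region centered on the index SNP
  (clipped at position 1).  Every gene overlapping it is scored.

Coordinates are 1-based inclusive throughout; BED input (0-based half-open)
is converted at the reader boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GeneModel",
    "LocusDefinition",
    "LD_R2_MIN",
    "LD_MAX_DIST",
    "GENE_WINDOW_HALF",
    "define_locus_interval",
    "gene_window",
    "candidate_genes",
    "nearest_genes",
    "build_locus",
    "read_ld_table",
    "read_gene_annotation",
]

#: Minimum r² to the index SNP for a variant to extend the locus interval.
LD_R2_MIN = 0.2
#: Hard cap on the interval, in bp per side of the index SNP.
LD_MAX_DIST = 500_000
#: Half-width of the candidate-gene window (3 Mb centered on the index SNP).
GENE_WINDOW_HALF = 1_500_000


@dataclass(frozen=True)
class GeneModel:
    """A gene body on one chromosome; ``tss`` follows strand orientation."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    symbol: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        if not self.symbol:
            object.__setattr__(self, "symbol", self.gene_id)

    @property
    def tss(self) -> int:
        """Transcription start site: gene start on '+', gene end on '-'."""
        return self.start if self.strand == "+" else self.end

    def edge_distance(self, pos: int) -> int:
        """bp distance from ``pos`` to the closer gene edge; 0 if inside."""
        if self.start <= pos <= self.end:
            return 0
        return self.start - pos if pos < self.start else pos - self.end


def define_locus_interval(
    index_pos: int,
    positions: Sequence[int],
    r2: Sequence[float],
    r2_min: float = LD_R2_MIN,
    max_dist: int = LD_MAX_DIST,
) -> tuple[int, int]:
    """LD-defined locus interval around an index SNP.

    A neighbor qualifies if its r² to the index is at least ``r2_min`` and it
    lies within ``max_dist`` bp of the index; the interval runs from the
    furthest qualifying 5' SNP to the furthest qualifying 3' SNP and always
    contains the index position.  With no qualifying neighbors the interval
    degenerates to ``[index_pos, index_pos]`` (logged, not an error).
    """
    pos = np.asarray(positions, dtype=np.int64)
    rr = np.asarray(r2, dtype=float)
    if pos.shape != rr.shape:
        raise ValueError("positions and r2 must have equal length")
    if rr.size and (np.nanmin(rr) < 0 or np.nanmax(rr) > 1):
        raise ValueError("r2 values must lie in [0, 1]")
    qual = (rr >= r2_min) & (np.abs(pos - index_pos) <= max_dist)
    if not qual.any():
        logger.warning(
            "no SNP with r2 >= %g within %d bp of index at %d; degenerate interval",
            r2_min, max_dist, index_pos,
        )
        return (index_pos, index_pos)
    qp = pos[qual]
    return (int(min(qp.min(), index_pos)), int(max(qp.max(), index_pos)))


def gene_window(index_pos: int, half_width: int = GENE_WINDOW_HALF) -> tuple[int, int]:
    """Candidate-gene window centered on the index SNP, clipped at 1."""
    return (max(1, index_pos - half_width), index_pos + half_width)


def candidate_genes(
    window: tuple[int, int],
    chrom: str,
    annotation: Iterable[GeneModel],
) -> list[GeneModel]:
    """All genes whose body overlaps ``window`` (inclusive ends), by start.

    Genes on other chromosomes are ignored; if the annotation contains no
    gene on ``chrom`` at all, an empty list is returned with a warning.
    """
    genes = list(annotation)
    same_chrom = [g for g in genes if g.chrom == chrom]
    if genes and not same_chrom:
        logger.warning("no annotated gene on chromosome %s; empty candidate list", chrom)
        return []
    lo, hi = window
    hits = [g for g in same_chrom if g.start <= hi and g.end >= lo]
    return sorted(hits, key=lambda g: (g.start, g.gene_id))


def nearest_genes(index_pos: int, annotation: Iterable[GeneModel], chrom: str | None = None) -> set[str]:
    """The nearest gene(s) to the index position, per direction.

    If the index falls inside a gene body that gene is the unique nearest
    gene.  Otherwise the closest gene upstream and the closest downstream
    (by distance to the nearer gene edge) are both returned; exact distance
    ties within a direction return every tied gene, with a log message.
    """
    genes = [g for g in annotation if chrom is None or g.chrom == chrom]
    if not genes:
        raise ValueError("nearest_genes requires a non-empty annotation")
    inside = {g.gene_id for g in genes if g.start <= index_pos <= g.end}
    if inside:
        if len(inside) > 1:
            logger.info("index at %d inside %d overlapping genes", index_pos, len(inside))
        return inside
    out: set[str] = set()
    for side in ("5p", "3p"):
        if side == "5p":
            cands = [g for g in genes if g.end < index_pos]
        else:
            cands = [g for g in genes if g.start > index_pos]
        if not cands:
            continue
        best = min(g.edge_distance(index_pos) for g in cands)
        tied = {g.gene_id for g in cands if g.edge_distance(index_pos) == best}
        if len(tied) > 1:
            logger.info("nearest-gene tie at %d bp on %s side: %s", best, side, sorted(tied))
        out |= tied
    return out


@dataclass
class LocusDefinition:
    """Geometry of one GWAS locus: interval, gene window, candidates.

    Loci with secondary independent signals are merged into a single
    definition whose interval and window are the unions of the per-index
    regions; nearest genes are taken from the primary index SNP.
    """

    locus_id: str
    index_snp: str
    chrom: str
    index_pos: int
    interval: tuple[int, int]
    gene_window: tuple[int, int]
    candidate_genes: list[str] = field(default_factory=list)
    nearest_genes: set[str] = field(default_factory=set)
    secondary_index_snps: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        lo, hi = self.interval
        if not (lo <= self.index_pos <= hi):
            raise ValueError(f"locus {self.locus_id}: interval {self.interval} excludes index position")
        wlo, whi = self.gene_window
        if wlo > whi:
            raise ValueError(f"locus {self.locus_id}: empty gene window")

    def contains(self, pos: int) -> bool:
        return self.interval[0] <= pos <= self.interval[1]


def build_locus(
    locus_id: str,
    index_snp: str,
    chrom: str,
    index_pos: int,
    ld: pd.DataFrame | None,
    annotation: Iterable[GeneModel],
    secondary: Sequence[tuple[str, int, pd.DataFrame | None]] = (),
    r2_min: float = LD_R2_MIN,
    max_dist: int = LD_MAX_DIST,
) -> LocusDefinition:
    """Assemble a full :class:`LocusDefinition` from LD and annotation.

    ``ld`` is a frame with ``pos`` and ``r2`` columns (r² to the index SNP).
    ``secondary`` lists additional independent signals at the locus as
    ``(snp_id, pos, ld)`` triples; their intervals and windows are unioned
    into one merged locus, as such pairs are reported on a single row.
    """
    genes = list(annotation)

    def one_interval(pos: int, tab: pd.DataFrame | None) -> tuple[int, int]:
        if tab is None or len(tab) == 0:
            return define_locus_interval(pos, [], [], r2_min, max_dist)
        return define_locus_interval(pos, tab["pos"].to_numpy(), tab["r2"].to_numpy(), r2_min, max_dist)

    intervals = [one_interval(index_pos, ld)]
    windows = [gene_window(index_pos)]
    sec_ids = []
    for snp_id, pos, tab in secondary:
        intervals.append(one_interval(pos, tab))
        windows.append(gene_window(pos))
        sec_ids.append(snp_id)
    interval = (min(i[0] for i in intervals), max(i[1] for i in intervals))
    window = (min(w[0] for w in windows), max(w[1] for w in windows))
    cand = candidate_genes(window, chrom, genes)
    near = nearest_genes(index_pos, genes, chrom=chrom) if any(g.chrom == chrom for g in genes) else set()
    return LocusDefinition(
        locus_id=locus_id,
        index_snp=index_snp,
        chrom=chrom,
        index_pos=index_pos,
        interval=interval,
        gene_window=window,
        candidate_genes=[g.gene_id for g in cand],
        nearest_genes=near,
        secondary_index_snps=sec_ids,
    )


def read_ld_table(path) -> pd.DataFrame:
    """Read an LD TSV ``snp_id chrom pos r2`` (r² relative to the index SNP).

    An optional ``locus_id`` column allows several loci in one file.
    """
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "chrom": str})
    for col in ("snp_id", "chrom", "pos", "r2"):
        if col not in df.columns:
            raise ValueError(f"LD table missing column {col!r}")
    df["pos"] = df["pos"].astype(np.int64)
    df["r2"] = df["r2"].astype(float)
    return df


def _genes_from_bed(path) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 4:
        raise ValueError("BED gene annotation needs at least 4 columns (chrom start end name)")
    genes = []
    for row in df.itertuples(index=False):
        chrom, start, end, name = row[0], int(row[1]), int(row[2]), row[3]
        strand = row[5] if len(row) > 5 and row[5] in ("+", "-") else "+"
        # BED is 0-based half-open; internal coordinates are 1-based inclusive
        genes.append(GeneModel(gene_id=name, chrom=chrom, start=start + 1, end=end, strand=strand))
    return genes


def _genes_from_gff3(path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            gid = attrs.get("ID") or attrs.get("gene_id") or attrs.get("Name")
            if gid is None:
                raise ValueError(f"GFF3 gene feature without ID/gene_id/Name: {line!r}")
            genes.append(
                GeneModel(
                    gene_id=gid,
                    chrom=parts[0],
                    start=int(parts[3]),
                    end=int(parts[4]),
                    strand=parts[6] if parts[6] in ("+", "-") else "+",
                    symbol=attrs.get("Name", ""),
                )
            )
    return genes


def read_gene_annotation(path, fmt: str | None = None) -> list[GeneModel]:
    """Read gene models from BED (>=4 columns) or a minimal GFF3 subset.

    Format is inferred from the file extension unless ``fmt`` ("bed" or
    "gff3") is given.
    """
    p = str(path)
    if fmt is None:
        fmt = "gff3" if p.endswith((".gff", ".gff3")) else "bed"
    if fmt == "bed":
        return _genes_from_bed(path)
    if fmt == "gff3":
        return _genes_from_gff3(path)
    raise ValueError(f"unknown annotation format {fmt!r}")
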