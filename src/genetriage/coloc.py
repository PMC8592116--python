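"""Approximate-Bayes-factor colocalization of two association signals.

Given per-variant summary statistics (beta, SE) for two traits at one locus,
the model assumes at most one causal variant per trait and weighs five
hypotheses:

* H0 — neither trait associated,
* H1 / H2 — only trait 1 / only trait 2 associated,
* H3 — both associated, distinct causal variants,
* H4 — both associated, one shared causal variant.

Per-variant evidence is the Wakefield approximate Bayes factor

    log ABF = 0.5 * [ln(1 - r) + r * z**2],   r = w / (w + se**2),

with z = beta/se and w the prior variance of the true effect.  Hypothesis
sums run over all single-causal configurations in log space.  A result whose
shared-variant posterior exceeds 0.5 (strictly) qualifies as full-weight
statistical evidence for the gene whose molecular trait was tested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .evidence import EvidenceClass, EvidenceRecord

logger = logging.getLogger(__name__)

__all__ = [
    "SummaryStats",
    "ColocResult",
    "ColocPriors",
    "DEFAULT_PRIOR_SD",
    "CIS_WINDOW",
    "log_abf",
    "coloc_posteriors",
    "coloc_to_evidence",
    "harmonize",
    "read_sumstats",
    "cis_eligible",
]

#: Prior SD of the true effect, by trait type (quantitative / case-control).
DEFAULT_PRIOR_SD = {"quant": 0.15, "cc": 0.2}

#: cis-eligibility window: gene TSS within 1.5 Mb of the QTL variant.
CIS_WINDOW = 1_500_000

_AMBIGUOUS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


@dataclass(frozen=True)
class ColocPriors:
    """Per-variant prior probabilities of causality configurations."""

    p1: float = 1e-4  # causal for trait 1 only
    p2: float = 1e-4  # causal for trait 2 only
    p12: float = 1e-5  # shared causal variant

    def __post_init__(self) -> None:
        if not (0 < self.p1 < 1 and 0 < self.p2 < 1 and 0 < self.p12 < 1):
            raise ValueError("priors must lie strictly in (0, 1)")


@dataclass
class SummaryStats:
    """Per-variant association summary statistics for one trait at a locus."""

    trait: str
    ids: np.ndarray
    pos: np.ndarray
    beta: np.ndarray
    se: np.ndarray
    trait_type: str = "quant"  # "quant" | "cc"
    eaf: np.ndarray | None = None
    n: np.ndarray | None = None
    effect_allele: np.ndarray | None = None
    other_allele: np.ndarray | None = None
    chrom: str = ""

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.beta = np.asarray(self.beta, dtype=float)
        self.se = np.asarray(self.se, dtype=float)
        k = len(self.ids)
        for name in ("pos", "beta", "se"):
            if len(getattr(self, name)) != k:
                raise ValueError(f"{name} length differs from ids")
        if np.any(self.se <= 0):
            raise ValueError(f"trait {self.trait}: all standard errors must be > 0")
        if self.trait_type not in DEFAULT_PRIOR_SD:
            raise ValueError(f"trait_type must be one of {sorted(DEFAULT_PRIOR_SD)}")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def z(self) -> np.ndarray:
        return self.beta / self.se

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, trait: str, trait_type: str = "quant") -> "SummaryStats":
        kwargs = {}
        for col, attr in (("eaf", "eaf"), ("n", "n")):
            if col in df.columns:
                kwargs[attr] = df[col].to_numpy(dtype=float)
        for col, attr in (("effect_allele", "effect_allele"), ("other_allele", "other_allele")):
            if col in df.columns:
                kwargs[attr] = df[col].to_numpy(dtype=object)
        chrom = str(df["chrom"].iloc[0]) if "chrom" in df.columns and len(df) else ""
        return cls(
            trait=trait,
            ids=df["snp_id"].to_numpy(dtype=object),
            pos=df["pos"].to_numpy(dtype=np.int64),
            beta=df["beta"].to_numpy(dtype=float),
            se=df["se"].to_numpy(dtype=float),
            trait_type=trait_type,
            chrom=chrom,
            **kwargs,
        )

    def restrict(self, mask: np.ndarray) -> "SummaryStats":
        """Subset of variants selected by a boolean mask."""
        sub = {}
        for name in ("eaf", "n", "effect_allele", "other_allele"):
            arr = getattr(self, name)
            sub[name] = arr[mask] if arr is not None else None
        return SummaryStats(
            trait=self.trait,
            ids=self.ids[mask],
            pos=self.pos[mask],
            beta=self.beta[mask],
            se=self.se[mask],
            trait_type=self.trait_type,
            chrom=self.chrom,
            **sub,
        )


def read_sumstats(path, trait: str | None = None, trait_type: str = "quant") -> SummaryStats:
    """Read the summary-statistics TSV dialect.

    Columns: ``snp_id chrom pos effect_allele other_allele beta se p eaf n``
    (allele, p, eaf and n columns optional).
    """
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "chrom": str})
    for col in ("snp_id", "pos", "beta", "se"):
        if col not in df.columns:
            raise ValueError(f"summary statistics missing column {col!r}")
    return SummaryStats.from_dataframe(df, trait=trait or str(path), trait_type=trait_type)


@dataclass(frozen=True)
class ColocResult:
    """Posterior probabilities over H0..H4 for one GWAS × QTL pair."""

    h0: float
    h1: float
    h2: float
    h3: float
    h4: float
    n_variants: int
    priors: ColocPriors = field(default_factory=ColocPriors)
    top_shared_variant: str = ""
    trait1: str = ""
    trait2: str = ""

    def __post_init__(self) -> None:
        h = self.posteriors
        if np.any(h < -1e-12) or np.any(h > 1 + 1e-12):
            raise ValueError("posteriors must lie in [0, 1]")
        if abs(h.sum() - 1.0) > 1e-9:
            raise ValueError(f"posteriors must sum to 1, got {h.sum()!r}")

    @property
    def posteriors(self) -> np.ndarray:
        return np.array([self.h0, self.h1, self.h2, self.h3, self.h4])


def log_abf(beta, se, prior_sd: float) -> np.ndarray | float:
    """Wakefield log approximate Bayes factor against the null.

    ``0.5 * [ln(1 - r) + r z**2]`` with ``r = prior_sd**2 / (se**2 + prior_sd**2)``.
    Vectorized over beta/se.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("standard errors must be > 0")
    if prior_sd < 0:
        raise ValueError("prior_sd must be >= 0")
    r = prior_sd**2 / (se**2 + prior_sd**2)
    z = beta / se
    out = 0.5 * (np.log1p(-r) + r * z**2)
    return float(out) if out.ndim == 0 else out


def harmonize(t1: SummaryStats, t2: SummaryStats) -> tuple[SummaryStats, SummaryStats]:
    """Inner-join two traits on variant id and align effect alleles.

    When both traits carry allele columns, variants whose alleles are swapped
    between the traits have trait-2 betas sign-flipped; strand-ambiguous
    (A/T, C/G) variants and variants with irreconcilable alleles are dropped
    with a warning.  Without allele information the join is by id alone.
    """
    common, i1, i2 = np.intersect1d(t1.ids.astype(str), t2.ids.astype(str), return_indices=True)
    if common.size == 0:
        raise ValueError(f"traits {t1.trait!r} and {t2.trait!r} share no variant ids")
    a = t1.restrict(i1)
    b = t2.restrict(i2)
    if a.effect_allele is None or b.effect_allele is None:
        return a, b

    keep = np.ones(len(a), dtype=bool)
    flip = np.zeros(len(a), dtype=bool)
    for k in range(len(a)):
        ea1, oa1 = str(a.effect_allele[k]).upper(), str(a.other_allele[k]).upper()
        ea2, oa2 = str(b.effect_allele[k]).upper(), str(b.other_allele[k]).upper()
        if (ea1, oa1) in _AMBIGUOUS:
            keep[k] = False
        elif (ea1, oa1) == (ea2, oa2):
            pass
        elif (ea1, oa1) == (oa2, ea2):
            flip[k] = True
        else:
            keep[k] = False
    dropped = int((~keep).sum())
    if dropped:
        logger.warning("dropped %d strand-ambiguous or mismatched variants during harmonization", dropped)
    a = a.restrict(keep)
    b = b.restrict(keep)
    flip = flip[keep]
    if flip.any():
        b.beta = np.where(flip, -b.beta, b.beta)
        if b.eaf is not None:
            b.eaf = np.where(flip, 1 - b.eaf, b.eaf)
    return a, b


def _log_diff_exp(la: float, lb: float) -> float:
    """log(exp(la) - exp(lb)) for la >= lb, -inf on underflow."""
    if lb >= la:
        return -np.inf
    return la + np.log1p(-np.exp(lb - la))


def coloc_posteriors(
    trait1: SummaryStats,
    trait2: SummaryStats,
    priors: ColocPriors = ColocPriors(),
    prior_sd1: float | None = None,
    prior_sd2: float | None = None,
) -> ColocResult:
    """H0..H4 posteriors for a pair of traits sharing a variant panel.

    Traits are inner-joined (and allele-harmonized) on variant id; at least
    two shared variants are required.  Per-hypothesis evidence sums over all
    single-causal-variant configurations are accumulated with log-sum-exp and
    normalized to a posterior simplex.
    """
    a, b = harmonize(trait1, trait2)
    m = len(a)
    if m < 2:
        raise ValueError(
            f"colocalization needs >= 2 shared variants between {trait1.trait!r} "
            f"and {trait2.trait!r}, got {m}"
        )
    sd1 = DEFAULT_PRIOR_SD[a.trait_type] if prior_sd1 is None else prior_sd1
    sd2 = DEFAULT_PRIOR_SD[b.trait_type] if prior_sd2 is None else prior_sd2
    l1 = np.asarray(log_abf(a.beta, a.se, sd1))
    l2 = np.asarray(log_abf(b.beta, b.se, sd2))
    if not (np.all(np.isfinite(l1)) and np.all(np.isfinite(l2))):
        raise ValueError("non-finite log Bayes factors; check betas and SEs")

    lse1 = logsumexp(l1)
    lse2 = logsumexp(l2)
    lse12 = logsumexp(l1 + l2)
    lp1, lp2, lp12 = np.log(priors.p1), np.log(priors.p2), np.log(priors.p12)

    lh = np.empty(5)
    lh[0] = 0.0
    lh[1] = lp1 + lse1
    lh[2] = lp2 + lse2
    # sum over i != j factorizes as the product of marginal sums minus the diagonal
    lh[3] = lp1 + lp2 + _log_diff_exp(lse1 + lse2, lse12)
    lh[4] = lp12 + lse12
    post = np.exp(lh - logsumexp(lh))
    post /= post.sum()

    top = str(a.ids[int(np.argmax(l1 + l2))])
    return ColocResult(
        h0=float(post[0]),
        h1=float(post[1]),
        h2=float(post[2]),
        h3=float(post[3]),
        h4=float(post[4]),
        n_variants=m,
        priors=priors,
        top_shared_variant=top,
        trait1=a.trait,
        trait2=b.trait,
    )


def coloc_to_evidence(
    result: ColocResult,
    locus_id: str,
    gene_id: str,
    study_id: str,
    study_type: str = "coloc",
    tissue: str | None = None,
    n_sig: int = 1,
    n_exp: int = 1,
    h4_min: float = 0.5,
) -> EvidenceRecord | None:
    """Convert a qualifying colocalization into full-weight gene evidence.

    Emits a gene-level ``stat_full`` record with magnitude = H4 when H4
    strictly exceeds ``h4_min`` (default 0.5); returns ``None`` otherwise.
    """
    if not result.h4 > h4_min:
        return None
    return EvidenceRecord(
        locus_id=locus_id,
        target_type="gene",
        target_id=gene_id,
        study_id=study_id,
        study_type=study_type,
        evidence_class=EvidenceClass.STAT_FULL,
        magnitude=result.h4,
        n_sig=n_sig,
        n_exp=n_exp,
        tissue=tissue,
    )


def cis_eligible(gene_tss: int, variant_pos: int, window: int = CIS_WINDOW) -> bool:
    """Whether a variant lies within the cis window of a gene's TSS."""
    return abs(variant_pos - gene_tss) <= window
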