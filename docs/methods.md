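# Methods

## Problem setting

A GWAS locus is an LD-correlated region tagged by an index SNP; the causal
gene behind the association is usually uncertain because most trait
variants are regulatory. `genetriage` formalizes a triangulation procedure:
collect every available piece of molecular evidence linking variants or
genes at the locus to the trait, weight each piece by how trustworthy its
evidence class is, and sum into a per-gene (and per-SNP) prioritization
score. The score is a relative ranking device, not a calibrated
probability.

## Locus geometry

Coordinates are 1-based inclusive internally; BED input (0-based half-open)
is converted at the reader boundary, which matches summary-statistics
conventions and keeps interval arithmetic uniform.

* **Locus interval**: bounded by the furthest 5′ and 3′ SNPs with r² ≥ 0.2
  to the index SNP, subject to a hard cap of 500 kb per side. The cap
  truncates the boundary rather than discarding the locus, and the bounds
  are the qualifying SNP positions themselves, with no padding. With no
  qualifying neighbor the interval degenerates to the index position
  (logged, not an error).
* **Candidate-gene window**: 3 Mb centered on the index SNP, clipped at
  position 1. Gene membership is inclusive overlap of the gene body with
  the window.
* **Nearest genes**: the closest gene per direction by distance to the
  nearer *gene-body edge* (distance 0 if the index falls inside a gene,
  which is then the unique nearest gene; exact ties return all tied
  genes). TSS-based distance is deliberately reserved for cis-QTL
  eligibility (TSS within 1.5 Mb of the variant), where transcription
  start, not gene extent, is the biologically relevant anchor.
* **Secondary signals**: a locus with independent index SNPs is merged into
  one definition whose interval and window are unions of the per-index
  regions, mirroring how such loci are reported on a single row.

## Colocalization model

The engine assumes at most one causal variant per trait per locus.
Per-variant evidence is the Wakefield approximate Bayes factor
ln ABF = ½[ln(1 − r) + r z²] with r = w/(w + se²); the shrinkage prior
standard deviation √w defaults to 0.15 for quantitative molecular traits
and 0.2 for case-control GWAS, both configurable. Hypothesis sums (H0–H4)
run over all single-causal configurations: the H3 cross-sum factorizes into
the product of marginal sums minus the shared diagonal and is evaluated in
log space with `log1p`-guarded differences, so posteriors are stable for
panels of thousands of variants. Posterior simplex membership is asserted
at construction (tolerance 1e-9).

Traits are inner-joined on variant id after allele harmonization: swapped
effect/other alleles flip the trait-2 beta (and fold the allele frequency);
strand-ambiguous A/T and C/G variants are dropped with a warning. Without
allele columns the join is by id alone. Fewer than two shared variants is
an error — a single variant cannot distinguish H3 from H4.

A result qualifies as evidence only when P(H4) strictly exceeds 0.5; the
record enters the scoring layer as class `stat_full` with magnitude = H4.
Priors (p1 = p2 = 1e-4, p12 = 1e-5) are the conventional single-variant
defaults; the source analysis did not publish its settings, so these are
package defaults, not asserted reproductions.

## Scoring model

Component value = W · m · s(n_sig) / √k with:

* **W** — class weight: 20 (full-summary-statistic tests: colocalization,
  TWAS/SMR, fine-mapping), 2 (positional overlap with significant
  experimental results: QTL lookups, enhancer loops, differential
  expression/methylation/proteome hits, GWAS-catalog entries), 1
  (machine-learning predictions). The ordering stat_full > overlap >
  prediction > 0 is enforced at construction.
* **m** — magnitude in [0, 1], normalized by the producer at ingestion
  (colocalization → H4; significance-based sources → a capped −log₁₀ p
  mapping; binary overlaps → 1; predictors → provider-normalized score;
  fine-mapping → posterior inclusion probability). The closed interval
  keeps class weights dominant regardless of source statistic.
* **s(n) = 1/(1 + log₁₀ n)** — specificity damping by the number of
  SNPs/genes the source experiment reported significant. Logarithmic
  damping penalizes genome-wide sources (n ~ 10⁴ → factor ~1/5) without
  eliminating them. The exact functional form is a package choice — the
  source describes the concept, not a formula — and is isolated behind the
  scoring configuration.
* **√k** — independence discount, k = number of records the same study
  contributes for the same target (e.g. expression and methylation from
  one cohort). Also a package choice in form, mirroring the square-root
  style of the heterogeneity rule.

Target total = Σ components × √((U_type + U_id)/2), with U_type/U_id the
counts of unique study types and unique study identifiers supporting the
target. The "absolute number of studies" influence is carried implicitly by
summation plus U_id; no additional explicit factor is applied, to avoid
triple-counting study multiplicity. SNP-level records with a `linked_gene`
propagate to that gene at full component value; records without one
contribute only to SNP scores. No score floor is imposed on SNPs or genes.

A consequence of the count-based √k discount worth knowing: adding evidence
from a *new* study can never lower a target's total (existing components
are untouched, U_id cannot fall), but adding a much weaker record from an
*already-counted* study can, because it raises k for its stronger siblings.
This is intentional redundancy discounting, and the property tests
distinguish the two cases.

## Ranking and classification

Per-locus rankings sort by total descending; ties break by distance to the
index SNP, then lexicographic id, so outputs are bit-deterministic. Shares
are percentages of the summed top-10 totals. Classification uses unrounded
shares with strict thresholds: standout (> 50% top-1), shared pair (> 75%
top-1+2), else ambiguous. Display rounding is half-up to integer percent,
matching how the published table prints shares (its 77 = 39 + 38 identity
only holds on rounded values). An all-zero locus has shares defined as 0
with a warning. The report annotates score decay (top-1/top-3 ratio) but
attaches no threshold to it.

The packaged locus summary fixture stores the published 26 rows verbatim —
integer scores and shares, split a/b loci as separate rows, merged
secondary-signal loci as single rows, and closest-gene flags as printed.
One nearest-gene cell is flagged `nearest_suspect` because the printed
symbol lies on a different chromosome; the value is preserved as printed
and never silently corrected. Nearest-gene/top-gene comparisons normalize
symbols case- and hyphen-insensitively because the printed table is
internally inconsistent (IL2RA vs IL-2RA).

## Synthetic data

The generator emulates the minimal structure the method depends on:

* **LD**: R[i,j] = ρ^|i−j| (AR(1) structure, positive-definite for
  ρ ∈ [0, 1)), 50 equally spaced SNPs at 5-kb spacing, ρ = 0.9 by default —
  a strong but realistic local LD block.
* **Association**: z ~ MVN(Rλ, R) with λ carrying noncentrality β√n at the
  causal variant; β defaults to 0.0566 with n = 20,000 so the causal z is
  ~8, typical of a replicated GWAS hit. Betas/SEs are back-computed with
  SE = 1/√n. Shared vs distinct causal variants toggles whether the QTL
  reuses the GWAS causal position or one half a block away (negligible LD).
* **Evidence**: a per-gene plan of (study type, class, magnitude bounds,
  n_sig) templates. The strong-support plan gives the planted gene three
  full-weight records (magnitude 0.8–1.0, three study types/studies) and
  each decoy one weak overlap; the null plan gives every gene one uniform
  prediction record, making top ranks exchangeable.

All randomness flows from one seed through named child streams
(SeedSequence spawning), so modules are independently reproducible.

What the generator does **not** emulate: genotype-level sampling, allele
frequencies' effect on power, realistic effect-size or magnitude
distributions across the evidence corpus, correlated evidence between
neighboring genes, or tissue structure. Passing the planted-gene and
colocalization suites therefore demonstrates internal correctness of the
machinery and its discrimination under clean conditions — not expected
performance on real, confounded evidence corpora.

## Problem sizes and numerical choices

The test and acceptance workloads use 100 replicates for recovery and
colocalization-rate experiments, 1,000 replicates for null calibration and
simplex/symmetry sweeps, 60 seeded 3–5-variant panels for brute-force
posterior equivalence (tolerance 1e-8), and 200 randomized geometry
fixtures — sizes chosen so each suite pins its property with comfortable
statistical margin while the whole run stays interactive. Degenerate inputs
are contracts, not errors, wherever the upstream data could legitimately
produce them (empty LD tables, all-zero score vectors, empty evidence
files); genuinely malformed inputs (non-positive SEs, magnitudes outside
[0, 1], misordered weights) fail fast with named errors.

## Limitations

* Single-causal-variant colocalization only; loci with allelic
  heterogeneity will split posterior mass toward H3.
* Scores are not comparable across diseases unless the evidence corpus and
  normalization registry are held fixed.
* The specificity and independence functional forms are reasonable
  defaults, not estimated quantities; rankings are robust to monotone
  changes of these forms far more than raw scores are.
* The packaged published table carries only the printed top-3 genes and
  integer shares, so fixture-derived summaries inherit print rounding.
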