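"""Independent brute-force oracles used to cross-check the implementation.

These deliberately use naive enumeration (O(n^2) loops, full scans) and do
not share code with the package internals they validate.
"""

import math

import numpy as np
from scipy.special import logsumexp


def brute_coloc_posteriors(l1, l2, p1=1e-4, p2=1e-4, p12=1e-5):
    """H0..H4 posteriors by explicit enumeration of every single-causal
    configuration: the null, each trait-1-only variant, each trait-2-only
    variant, every ordered distinct pair, and every shared variant."""
    l1 = np.asarray(l1, dtype=float)
    l2 = np.asarray(l2, dtype=float)
    n = len(l1)
    terms = {0: [0.0], 1: [], 2: [], 3: [], 4: []}
    for i in range(n):
        terms[1].append(math.log(p1) + l1[i])
        terms[2].append(math.log(p2) + l2[i])
        terms[4].append(math.log(p12) + l1[i] + l2[i])
        for j in range(n):
            if i != j:
                terms[3].append(math.log(p1) + math.log(p2) + l1[i] + l2[j])
    lh = np.array([logsumexp(terms[k]) if terms[k] else -np.inf for k in range(5)])
    post = np.exp(lh - logsumexp(lh))
    return post / post.sum()


def brute_interval(index_pos, positions, r2, r2_min=0.2, max_dist=500_000):
    """Locus interval by scanning every SNP for qualification."""
    lo = hi = index_pos
    for p, r in zip(positions, r2):
        if r >= r2_min and abs(p - index_pos) <= max_dist:
            lo = min(lo, p)
            hi = max(hi, p)
    return (lo, hi)


def brute_candidates(window, chrom, genes):
    """Candidate genes by full scan with inclusive-overlap arithmetic."""
    lo, hi = window
    hits = [g for g in genes if g.chrom == chrom and not (g.end < lo or g.start > hi)]
    return sorted(hits, key=lambda g: (g.start, g.gene_id))


def brute_nearest(index_pos, genes):
    """Nearest gene set by exhaustive distance comparison."""
    inside = {g.gene_id for g in genes if g.start <= index_pos <= g.end}
    if inside:
        return inside
    out = set()
    for cands in (
        [g for g in genes if g.end < index_pos],
        [g for g in genes if g.start > index_pos],
    ):
        if not cands:
            continue
        dist = {g.gene_id: min(abs(g.start - index_pos), abs(g.end - index_pos)) for g in cands}
        best = min(dist.values())
        out |= {gid for gid, d in dist.items() if d == best}
    return out
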