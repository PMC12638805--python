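"""Exact test for Hardy–Weinberg equilibrium.

Two-sided exact test on hard-called genotypes: given the observed minor-allele
count, every possible heterozygote count is enumerated and the p-value is the
summed probability of all configurations no more likely than the observed one
(the "SNP-HWE" convention of Wigginton, Cutler & Abecasis).
"""

from __future__ import annotations

import numpy as np

__all__ = ["hwe_exact_test"]


def _het_probabilities(n_het_obs: int, n_minor: int, n_genotypes: int) -> np.ndarray:
    """Probabilities of each feasible heterozygote count given allele counts.

    Uses the standard recurrence on the conditional distribution of the number
    of heterozygotes given the minor-allele count, normalised at the end so no
    factorials are needed.
    """
    n_major = 2 * n_genotypes - n_minor
    # heterozygote count must have the parity of the minor allele count
    het_counts = np.arange(n_minor % 2, min(n_minor, n_major) + 1, 2)
    probs = np.zeros(het_counts.size)
    # start at the mid-range het count and recur outwards for stability
    mid = int(round(n_minor * n_major / (2.0 * n_genotypes)))
    if mid % 2 != n_minor % 2:
        mid += 1
    mid = min(mid, het_counts[-1])
    idx_mid = int(np.searchsorted(het_counts, mid))
    probs[idx_mid] = 1.0
    # downward: P(h-2)/P(h) = h(h-1) / ((hom_minor+1)(hom_major+1)) with
    # hom_minor = (n_minor-h)/2, hom_major = (n_major-h)/2 evaluated at h-2
    for i in range(idx_mid, 0, -1):
        h = het_counts[i]
        hom_minor = (n_minor - h) / 2.0
        hom_major = (n_major - h) / 2.0
        probs[i - 1] = probs[i] * h * (h - 1.0) / (4.0 * (hom_minor + 1.0) * (hom_major + 1.0))
    for i in range(idx_mid, het_counts.size - 1):
        h = het_counts[i]
        hom_minor = (n_minor - h) / 2.0
        hom_major = (n_major - h) / 2.0
        probs[i + 1] = probs[i] * 4.0 * hom_minor * hom_major / ((h + 2.0) * (h + 1.0))
    probs /= probs.sum()
    return het_counts, probs


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided exact HWE p-value from genotype counts.

    Parameters are counts of the three genotype classes at a biallelic site.
    Returns 1.0 for monomorphic sites (no minor alleles present).
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        raise ValueError("no genotypes")
    n_alt = 2 * n_hom_alt + n_het
    n_minor = min(n_alt, 2 * n - n_alt)
    if n_minor == 0:
        return 1.0
    het_counts, probs = _het_probabilities(n_het, n_minor, n)
    p_obs = probs[np.searchsorted(het_counts, n_het)]
    # sum all configurations at most as probable as observed
    return float(min(1.0, probs[probs <= p_obs * (1.0 + 1e-12)].sum()))
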