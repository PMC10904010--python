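"""Sample- and variant-level quality control.

Filters mirror standard GWAS practice on hard-call data: samples are removed
when their missing-genotype rate exceeds 10%; variants are removed for low
minor allele frequency (MAF <= 0.01), high missingness (>= 10%) or departure
from Hardy-Weinberg equilibrium (exact-test p < 1e-7).  Boundary semantics
are literal: sample missingness strictly greater than the threshold removes;
MAF equal to the threshold removes; HWE strictly below alpha removes.

The HWE exact test follows the standard conditional-enumeration construction:
given the observed allele counts, every heterozygote count with the same
parity is enumerated, and the two-sided p-value is the total probability of
configurations no more probable than the observed one.  Probabilities are
accumulated in log space so large sample sizes do not underflow.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .genotypes import GenotypeMatrix

__all__ = [
    "hwe_exact_test",
    "filter_samples_by_missingness",
    "filter_snps",
]


def _log_het_probs(n: int, n_minor: int) -> tuple[np.ndarray, np.ndarray]:
    """Log conditional probabilities of each attainable heterozygote count.

    Conditions on the total genotype count ``n`` and minor-allele count
    ``n_minor``; heterozygote counts share the parity of ``n_minor``.
    """
    n_major = 2 * n - n_minor
    h_max = min(n_minor, n_major)
    hets = np.arange(n_minor % 2, h_max + 1, 2)
    n_aa = (n_minor - hets) // 2
    n_AA = (n_major - hets) // 2
    # P(h) = n! / (n_AA! h! n_aa!) * n_minor! n_major! / (2n)! * 2^h
    logp = (
        gammaln(n + 1)
        - gammaln(n_AA + 1)
        - gammaln(hets + 1)
        - gammaln(n_aa + 1)
        + gammaln(n_minor + 1)
        + gammaln(n_major + 1)
        - gammaln(2 * n + 1)
        + hets * np.log(2.0)
    )
    return hets, logp


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided Hardy-Weinberg exact test p-value from genotype counts.

    Parameters are counts of the three genotype classes (either homozygote
    may be listed first).  The p-value sums, over all heterozygote counts
    compatible with the observed allele totals, the probabilities of
    configurations no more probable than the observed one; it lies in (0, 1].
    """
    counts = (n_AA, n_Aa, n_aa)
    if any(c < 0 or c != int(c) for c in counts):
        raise ValueError(f"genotype counts must be nonnegative integers, got {counts}")
    n_AA, n_Aa, n_aa = (int(c) for c in counts)
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("total genotype count must be >= 1")
    n_minor = min(2 * n_AA + n_Aa, 2 * n_aa + n_Aa)
    hets, logp = _log_het_probs(n, n_minor)
    obs = np.flatnonzero(hets == n_Aa)
    if obs.size == 0:  # cannot happen for valid counts, guard anyway
        raise ValueError("observed heterozygote count incompatible with allele totals")
    # include ties up to a relative tolerance so equal-probability
    # configurations computed in floating point are not dropped
    keep = logp <= logp[obs[0]] + 1e-10
    p = float(np.exp(logsumexp(logp[keep])))
    return min(p, 1.0)


def filter_samples_by_missingness(
    gm: GenotypeMatrix, max_missing: float = 0.10
) -> GenotypeMatrix:
    """Drop samples whose missing-call fraction is strictly above the threshold.

    A sample at exactly the threshold is retained; sample order is preserved.
    """
    if not 0.0 < max_missing <= 1.0:
        raise ValueError(f"max_missing must be in (0, 1], got {max_missing}")
    rate = gm.sample_missing_rate()
    keep = np.flatnonzero(rate <= max_missing + 1e-12)
    if len(keep) == gm.n_samples:
        return gm
    return gm.take_samples(keep)


def _hwe_pvalues(gm: GenotypeMatrix) -> np.ndarray:
    p = np.ones(gm.n_snps)
    for j in range(gm.n_snps):
        col = gm.dosages[:, j]
        col = col[np.isfinite(col)]
        if col.size == 0:
            continue
        n2 = int((col == 2).sum())
        n1 = int((col == 1).sum())
        n0 = int((col == 0).sum())
        p[j] = hwe_exact_test(n0, n1, n2)
    return p


def filter_snps(
    gm: GenotypeMatrix,
    maf_min: float = 0.01,
    max_missing: float = 0.10,
    hwe_alpha: float = 1e-7,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Apply the three variant-level filters; return retained matrix + report.

    Removal rules (each evaluated on the input matrix, so ordering is
    immaterial): MAF <= ``maf_min``; missing rate >= ``max_missing``;
    HWE exact p < ``hwe_alpha``.  The report lists one row per failed check
    with columns ``snp_id reason value threshold``; a SNP failing several
    checks appears once per reason.
    """
    if not (0.0 <= maf_min < 0.5 and 0.0 < max_missing <= 1.0 and 0.0 < hwe_alpha <= 1.0):
        raise ValueError("invalid filter thresholds")
    maf = gm.maf()
    miss = gm.snp_missing_rate()
    hwe_p = _hwe_pvalues(gm)
    ids = gm.snp_ids

    rows = []
    drop = np.zeros(gm.n_snps, dtype=bool)
    fail_maf = np.isnan(maf) | (maf <= maf_min + 1e-12)
    fail_miss = miss >= max_missing - 1e-12
    fail_hwe = hwe_p < hwe_alpha
    for j in range(gm.n_snps):
        if fail_maf[j]:
            rows.append((ids[j], "maf", maf[j], maf_min))
        if fail_miss[j]:
            rows.append((ids[j], "missing", miss[j], max_missing))
        if fail_hwe[j]:
            rows.append((ids[j], "hwe", hwe_p[j], hwe_alpha))
    drop = fail_maf | fail_miss | fail_hwe
    report = pd.DataFrame(rows, columns=["snp_id", "reason", "value", "threshold"])
    retained = gm if not drop.any() else gm.take_snps(np.flatnonzero(~drop))
    return retained, report
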