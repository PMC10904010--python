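"""External validation and sample-size-weighted meta-analysis.

A retained supervariant's frozen SNP list is re-aggregated on each external
cohort (after minor-allele harmonization to the discovery orientation) and
regressed on the phenotype with that cohort's own covariate design.  The
per-cohort evidence is then combined with the classic sample-size-weighted
scheme: each two-sided p-value becomes a signed Z via the effect direction,

    Z_i = sign_i · Φ⁻¹(1 − p_i / 2),      Z = Σ √n_i · Z_i / √(Σ n_i),

and the combined two-sided p is 2(1 − Φ(|Z|)).  Weights are √n_i, not n_i
and not equal — splitting one cohort into two half-size duplicates does NOT
leave Z unchanged, by design of the scheme.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .builder import aggregate_score, test_supervariant
from .genotypes import OrientationTable, harmonize_to_reference
from .scan import build_design
from .simulate import Cohort

__all__ = [
    "CohortAssociation",
    "MetaResult",
    "harmonize_cohort",
    "external_validate",
    "meta_analyze",
    "summarize_external",
]

# smallest p that still maps to a finite Z through the inverse normal CDF
_P_FLOOR = 1e-300


@dataclass(frozen=True)
class CohortAssociation:
    """One cohort's association result for one supervariant."""

    cohort: str
    n: int
    beta: float
    se: float
    t: float
    p: float
    n_snps_used: int
    n_snps_dropped: int = 0
    zero_beta: bool = False  # sign of an exactly-zero effect defaulted to +1

    @property
    def sign(self) -> int:
        return -1 if self.beta < 0 else 1


@dataclass(frozen=True)
class MetaResult:
    """Sample-size-weighted combination of per-cohort associations."""

    cohorts: tuple[CohortAssociation, ...]
    z: float
    p: float
    n_total: int
    p_clamped: bool = False  # some input p underflowed and was floored


def harmonize_cohort(
    cohort: Cohort, orientation: OrientationTable
) -> tuple[Cohort, pd.DataFrame]:
    """Re-orient an external cohort's dosages to the discovery orientation.

    Returns the harmonized cohort (SNPs restricted to usable shared ones)
    and the per-SNP action report from the underlying harmonization.
    """
    gm, report = harmonize_to_reference(cohort.genotypes, orientation)
    return Cohort(cohort.label, gm, cohort.covariates, cohort.phenotypes), report


def external_validate(
    cohort: Cohort,
    snp_list,
    phenotype_name: str,
) -> CohortAssociation:
    """Test a frozen supervariant on one (already harmonized) external cohort.

    SNPs absent from the cohort are dropped (count reported); with zero
    shared SNPs the pair is an error.  The design is built from the cohort's
    own covariate table, so site terms appear only where the cohort has a
    site column.
    """
    present = set(cohort.genotypes.snps["id"])
    shared = [s for s in snp_list if s in present]
    dropped = len(list(snp_list)) - len(shared)
    if not shared:
        raise ValueError(
            f"no SNPs of the supervariant are present in cohort {cohort.label!r}"
        )
    design = build_design(cohort.covariates)
    score = aggregate_score(cohort.genotypes.select_samples(design.index), shared)
    assoc = test_supervariant(
        pd.Series(score, index=design.index),
        cohort.phenotypes[phenotype_name],
        design,
    )
    return CohortAssociation(
        cohort=cohort.label,
        n=assoc.n,
        beta=assoc.beta,
        se=assoc.se,
        t=assoc.t,
        p=assoc.p,
        n_snps_used=len(shared),
        n_snps_dropped=dropped,
        zero_beta=(assoc.beta == 0.0),
    )


def meta_analyze(results) -> MetaResult:
    """Combine per-cohort results with √n weights on signed Z-scores."""
    results = tuple(results)
    if not results:
        raise ValueError("meta-analysis needs at least one cohort result")
    if any(r.n < 1 for r in results):
        raise ValueError("every cohort must have n >= 1")
    clamped = False
    zs, ws = [], []
    for r in results:
        p = r.p
        if p <= 0.0:
            p = _P_FLOOR
            clamped = True
        zs.append(r.sign * norm.isf(p / 2.0))
        ws.append(np.sqrt(r.n))
    zs, ws = np.array(zs), np.array(ws)
    n_total = int(sum(r.n for r in results))
    z = float(ws @ zs / np.sqrt(n_total))
    p_meta = float(min(1.0, 2.0 * norm.sf(abs(z))))
    return MetaResult(results, z, max(p_meta, _P_FLOOR), n_total, clamped)


def summarize_external(
    meta_results: dict[str, MetaResult],
    discovery_directions: dict[str, int] | None = None,
    fwer: float = 0.05,
) -> pd.DataFrame:
    """Per-supervariant external report with family-wise pass/fail flags.

    The Bonferroni family level is ``fwer / N`` for the N retained
    supervariants under test.  ``concordant`` is true when every cohort's
    effect sign equals the discovery direction (+1/-1 per supervariant in
    ``discovery_directions``); without directions the flag requires all
    cohorts to agree with each other.  An empty input yields an empty frame.
    """
    n_tests = len(meta_results)
    alpha_family = fwer / n_tests if n_tests else np.nan
    rows = []
    for name, res in meta_results.items():
        signs = [c.sign for c in res.cohorts]
        if discovery_directions and name in discovery_directions:
            ref = discovery_directions[name]
            concordant = all(s == ref for s in signs)
        else:
            concordant = len(set(signs)) == 1
        rows.append(
            {
                "supervariant": name,
                "n_total": res.n_total,
                "n_cohorts": len(res.cohorts),
                "z_meta": res.z,
                "p_meta": res.p,
                "pass_bonferroni": res.p < alpha_family,
                "pass_nominal": res.p < fwer,
                "concordant": concordant,
                "alpha_family": alpha_family,
                "snps_dropped_per_cohort": ",".join(
                    f"{c.cohort}:{c.n_snps_dropped}" for c in res.cohorts
                ),
            }
        )
    cols = [
        "supervariant", "n_total", "n_cohorts", "z_meta", "p_meta",
        "pass_bonferroni", "pass_nominal", "concordant", "alpha_family",
        "snps_dropped_per_cohort",
    ]
    return pd.DataFrame(rows, columns=cols)
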