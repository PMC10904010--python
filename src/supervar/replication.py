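"""Repeated split-sample discovery / internal-validation of supervariants.

One replication: the cohort is randomly halved; supervariants are
constructed on the first half (minor-allele orientation is fixed there and
propagated to the second half); candidates whose construction p-value beats
the Bonferroni discovery threshold 0.05/(n_sets × 2 × n_phenotypes) are
"discovered"; each discovered candidate's SNP membership is frozen,
re-aggregated on the held-out half, and regressed with a design refit on
that half; it is "validated" when the held-out p-value beats 0.05 /
n_phenotypes.  The procedure repeats R times (default 10) with derived
seeds; a supervariant — identified across replications by (phenotype,
set_id, direction), membership may vary — is retained when validated in at
least ``retention_min`` (default 6) replications.  For retained
supervariants, SNPs selected in at least ``snp_retention_min`` (default 3)
validated replications form the frozen list carried to external validation.

Under the global null with uniform held-out p-values, the chance of one
candidate being validated in ≥6 of 10 replications is the binomial upper
tail at p = 0.05/n_phenotypes per trial — about 2.9e-14 for 22 phenotypes —
which is what makes the retention rule a strong reproducibility guard.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import binom

from .builder import SupervariantCandidate, aggregate_score, build_supervariants, \
    test_supervariant
from .genotypes import GenotypeMatrix, harmonize_to_reference, orient_to_minor
from .scan import build_design, marginal_stats
from .simulate import Cohort
from .snp_sets import SnpSet

__all__ = [
    "Thresholds",
    "discovery_threshold",
    "binomial_validation_probability",
    "split_cohort",
    "run_replication",
    "run_study",
    "ReplicationSummary",
]


def discovery_threshold(
    n_sets: int, n_directions: int, n_phenotypes: int, fwer: float = 0.05
) -> float:
    """Bonferroni candidacy threshold: fwer / (sets × directions × phenotypes)."""
    if n_sets < 1 or n_directions < 1 or n_phenotypes < 1:
        raise ValueError("counts must be positive")
    return fwer / (n_sets * n_directions * n_phenotypes)


def binomial_validation_probability(p_trial: float, n: int, k_min: int) -> float:
    """P(at least ``k_min`` successes in ``n`` trials at per-trial ``p_trial``).

    The chance a null supervariant with uniform held-out p-values clears the
    retention rule.  Computed by log-space summation of binomial point
    masses so tails far below double precision's comfortable range (e.g.
    ~1e-14) keep full relative accuracy.
    """
    if not 0.0 <= p_trial <= 1.0:
        raise ValueError("p_trial must be in [0, 1]")
    if not 0 <= k_min <= n:
        raise ValueError("need 0 <= k_min <= n")
    if k_min == 0:
        return 1.0
    if p_trial == 0.0:
        return 0.0
    ks = np.arange(k_min, n + 1)
    return float(np.exp(logsumexp(binom.logpmf(ks, n, p_trial))))


@dataclass
class Thresholds:
    """All knobs of the discovery/validation procedure.

    ``alpha_discovery`` defaults to 0.05/(n_sets × 2 × n_phenotypes) and
    ``alpha_validation`` to 0.05/n_phenotypes, both computable via
    :meth:`for_study`.  ``require_sign_match`` additionally demands the
    held-out effect sign agree with the direction label; off by default
    (concordance is recorded either way).
    """

    alpha_discovery: float
    alpha_validation: float
    n_replications: int = 10
    retention_min: int = 6
    snp_retention_min: int = 3
    split_fraction: float = 0.5
    require_sign_match: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha_discovery <= 1.0 and 0.0 < self.alpha_validation <= 1.0):
            raise ValueError("alpha levels must be in (0, 1]")
        if not 0.0 < self.split_fraction < 1.0:
            raise ValueError("split_fraction must be in (0, 1)")
        if self.retention_min > self.n_replications:
            raise ValueError("retention_min cannot exceed n_replications")
        if min(self.n_replications, self.retention_min, self.snp_retention_min) < 1:
            raise ValueError("counts must be positive")

    @classmethod
    def for_study(
        cls, n_sets: int, n_phenotypes: int, fwer: float = 0.05, **kwargs
    ) -> "Thresholds":
        return cls(
            alpha_discovery=discovery_threshold(n_sets, 2, n_phenotypes, fwer),
            alpha_validation=fwer / n_phenotypes,
            **kwargs,
        )


def split_cohort(
    cohort: Cohort, fraction: float, seed: int
) -> tuple[Cohort, Cohort]:
    """Random disjoint exhaustive split; part1 gets ⌊fraction·n⌋ samples.

    Minor-allele orientation is determined on part1 and propagated to part2,
    so both halves count the same allele for every SNP.  Deterministic per
    seed.
    """
    n = cohort.genotypes.n_samples
    if n < 2:
        raise ValueError("cannot split a cohort with fewer than 2 samples")
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n1 = int(np.floor(fraction * n))
    idx1, idx2 = np.sort(perm[:n1]), np.sort(perm[n1:])

    gm1, orientation = orient_to_minor(cohort.genotypes.take_samples(idx1))
    gm2, _ = harmonize_to_reference(cohort.genotypes.take_samples(idx2), orientation)
    part1 = Cohort(
        f"{cohort.label}#1",
        gm1,
        cohort.covariates.iloc[idx1],
        cohort.phenotypes.iloc[idx1],
    )
    part2 = Cohort(
        f"{cohort.label}#2",
        gm2,
        cohort.covariates.iloc[idx2],
        cohort.phenotypes.iloc[idx2],
    )
    return part1, part2


def run_replication(
    cohort: Cohort,
    sets: list[SnpSet],
    phenotypes: list[str],
    thresholds: Thresholds,
    seed: int,
) -> pd.DataFrame:
    """One split → construct → validate pass.

    Returns one row per (phenotype, set, direction) candidate with its
    cutoff, selected SNPs, construction p, and — for discovered candidates —
    the held-out validation statistics.
    """
    part1, part2 = split_cohort(cohort, thresholds.split_fraction, seed)
    design1 = build_design(part1.covariates)
    design2 = build_design(part2.covariates)

    rows = []
    for pheno in phenotypes:
        y1 = part1.phenotypes[pheno]
        y2 = part2.phenotypes[pheno]
        stats = marginal_stats(part1.genotypes, y1, design1)
        for snp_set in sets:
            for cand in build_supervariants(
                part1.genotypes, snp_set, y1, design1, stats=stats
            ):
                discovered = cand.construction.p < thresholds.alpha_discovery
                row = {
                    "phenotype": pheno,
                    "set_id": snp_set.set_id,
                    "direction": cand.direction,
                    "name": cand.name,
                    "k": cand.k,
                    "snps": cand.selected_snps,
                    "p_construction": cand.construction.p,
                    "beta_construction": cand.construction.beta,
                    "discovered": discovered,
                    "p_validation": np.nan,
                    "beta_validation": np.nan,
                    "validated": False,
                    "sign_concordant": False,
                }
                if discovered:
                    shared = [
                        s for s in cand.selected_snps
                        if s in set(part2.genotypes.snps["id"])
                    ]
                    if shared:
                        score = aggregate_score(part2.genotypes, shared)
                        assoc = test_supervariant(
                            pd.Series(score, index=part2.covariates.index),
                            y2,
                            design2,
                        )
                        row["p_validation"] = assoc.p
                        row["beta_validation"] = assoc.beta
                        concordant = assoc.sign == (1 if cand.direction == "+" else -1)
                        row["sign_concordant"] = concordant
                        ok = assoc.p < thresholds.alpha_validation
                        if thresholds.require_sign_match:
                            ok = ok and concordant
                        row["validated"] = ok
                rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class ReplicationSummary:
    """Aggregate of all replications plus retention decisions.

    ``candidates``: per (phenotype, set, direction) counts and median cutoff;
    ``retained``: the subset clearing ``retention_min``; ``snp_counts``:
    per-(supervariant, SNP) selection counts over validated replications;
    ``frozen_snps``: retained supervariant -> SNPs selected at least
    ``snp_retention_min`` times (the external-validation membership);
    ``replications``: the per-replication record frames.
    """

    candidates: pd.DataFrame
    retained: pd.DataFrame
    snp_counts: pd.DataFrame
    frozen_snps: dict[str, list[str]]
    replications: list[pd.DataFrame] = field(repr=False, default_factory=list)

    @property
    def retained_names(self) -> list[str]:
        return self.retained["name"].tolist()


def run_study(
    cohort: Cohort,
    sets: list[SnpSet],
    phenotypes: list[str],
    thresholds: Thresholds,
    master_seed: int,
    progress: bool = False,
) -> ReplicationSummary:
    """Run the full R-replication study and apply the retention rules."""
    reps = []
    for r in range(thresholds.n_replications):
        rep = run_replication(cohort, sets, phenotypes, thresholds, master_seed + r)
        rep.insert(0, "replication", r)
        reps.append(rep)
        if progress:
            n_disc = int(rep["discovered"].sum())
            n_val = int(rep["validated"].sum())
            print(f"replication {r}: discovered={n_disc} validated={n_val}")
    allreps = pd.concat(reps, ignore_index=True)

    grouped = allreps.groupby(["phenotype", "set_id", "direction", "name"], sort=False)
    candidates = grouped.agg(
        times_discovered=("discovered", "sum"),
        times_validated=("validated", "sum"),
        times_sign_concordant=("sign_concordant", "sum"),
        median_k=("k", "median"),
    ).reset_index()
    retained = candidates[
        candidates["times_validated"] >= thresholds.retention_min
    ].reset_index(drop=True)

    # per-SNP selection counts over replications where the candidate validated
    counts: dict[tuple[str, str], int] = {}
    validated_rows = allreps[allreps["validated"]]
    for name, snps in zip(validated_rows["name"], validated_rows["snps"]):
        for s in snps:
            counts[(name, s)] = counts.get((name, s), 0) + 1
    snp_counts = pd.DataFrame(
        [(n, s, c) for (n, s), c in counts.items()],
        columns=["supervariant", "snp_id", "times_selected"],
    )
    frozen: dict[str, list[str]] = {}
    retained_set = set(retained["name"])
    for name in retained_set:
        sel = snp_counts[
            (snp_counts["supervariant"] == name)
            & (snp_counts["times_selected"] >= thresholds.snp_retention_min)
        ]
        frozen[name] = sorted(sel["snp_id"])
    return ReplicationSummary(candidates, retained, snp_counts, frozen, reps)
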