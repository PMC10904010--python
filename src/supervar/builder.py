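"""Supervariant construction: rank, cut adaptively, aggregate, test.

Within a SNP set, SNPs are ordered by their covariate-adjusted marginal t
statistic — descending for the positive-effect supervariant, ascending for
the negative one — then every cutoff k = 1..M is evaluated: the top-k SNPs
are summed into an additive burden score (minor-allele counts) and the score
is regressed on the phenotype with covariate adjustment.  The cutoff with
the smallest association p-value wins (ties break toward smaller k, so the
construction is parsimonious and deterministic).  The minimum over k is an
optimized statistic; no multiplicity correction is applied inside the sweep
— the split-sample validation stage is the guard against its optimism.

Two supervariants are always constructed per (phenotype, set): one per
direction, named ``{pheno}_{set}+`` and ``{pheno}_{set}-``, even when every
marginal t shares one sign (the doomed direction is simply never validated).
The sweep uses prefix sums of the ranked dosage columns, so aggregation over
all cutoffs costs one cumulative sum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .scan import CovariateDesign, _stats_from_residuals, ols_single
from .snp_sets import SnpSet

__all__ = [
    "AssociationResult",
    "SupervariantCandidate",
    "rank_snps",
    "aggregate_score",
    "select_cutoff",
    "test_supervariant",
    "conditional_test",
    "build_supervariants",
    "candidates_to_frame",
]


@dataclass(frozen=True)
class AssociationResult:
    """OLS statistics for a burden score's coefficient."""

    beta: float
    se: float
    t: float
    p: float
    n: int
    collinear: bool = False

    @property
    def sign(self) -> int:
        return -1 if self.beta < 0 else 1


@dataclass(frozen=True)
class SupervariantCandidate:
    """A constructed supervariant: ranked SNPs, chosen cutoff, statistics.

    ``selected_snps`` is always the first ``k`` entries of ``ranked_snps``;
    the name follows the ``{phenotype}_{set_id}{+|-}`` convention.
    """

    phenotype: str
    set_id: str
    direction: str  # "+" or "-"
    ranked_snps: tuple[str, ...]
    k: int
    construction: AssociationResult

    def __post_init__(self) -> None:
        if self.direction not in ("+", "-"):
            raise ValueError(f"direction must be '+' or '-', got {self.direction!r}")
        if not 1 <= self.k <= len(self.ranked_snps):
            raise ValueError(f"cutoff k={self.k} outside 1..{len(self.ranked_snps)}")

    @property
    def name(self) -> str:
        return f"{self.phenotype}_{self.set_id}{self.direction}"

    @property
    def selected_snps(self) -> tuple[str, ...]:
        return self.ranked_snps[: self.k]


def rank_snps(stats: pd.DataFrame, direction: str) -> list[str]:
    """Order a set's SNPs by marginal t: "+" descending, "-" ascending.

    ``stats`` is the :func:`supervar.scan.marginal_stats` frame restricted to
    the set.  Ties break by (chromosome, position, id) so the order is total
    and reproducible.
    """
    if direction not in ("+", "-"):
        raise ValueError(f"direction must be '+' or '-', got {direction!r}")
    if len(stats) == 0:
        raise ValueError("cannot rank an empty SNP set")
    key = stats.assign(
        _t=-stats["t"] if direction == "+" else stats["t"],
        _chrom=stats["chrom"].astype(str),
    )
    ordered = key.sort_values(["_t", "_chrom", "pos", "snp_id"], kind="mergesort")
    return ordered["snp_id"].tolist()


def aggregate_score(gm: GenotypeMatrix, snp_ids) -> np.ndarray:
    """Additive burden score: per-sample sum of minor-allele counts.

    Missing calls are mean-imputed per SNP; with complete hard calls the
    score lies in [0, 2k] for k SNPs.  Raises if any SNP is absent.
    """
    cols = gm.snp_indexer(snp_ids)
    return gm.imputed(cols).sum(axis=1)


def select_cutoff(
    gm: GenotypeMatrix,
    ranked_snps,
    phenotype: pd.Series,
    design: CovariateDesign,
) -> tuple[int, AssociationResult]:
    """Exhaustive cutoff sweep; returns (k*, association at k*).

    Evaluates every prefix of the ranking with a covariate-adjusted
    regression of the phenotype on the prefix burden score and returns the
    cutoff minimizing the two-sided p; p-ties break toward smaller k.
    Prefix scores are cumulative sums of the ranked dosage columns, and the
    whole sweep shares one residualization of the design.
    """
    ranked = list(ranked_snps)
    if not ranked:
        raise ValueError("ranked SNP list is empty")
    sub = gm.select_samples(design.index)
    cols = sub.snp_indexer(ranked)
    G = sub.imputed(cols)
    scores = np.cumsum(G, axis=1)  # column k-1 = burden of top-k SNPs
    y = phenotype.loc[design.index].to_numpy(dtype=float)
    df = design.n - design.p - 1
    yr = design.residualize(y)
    Sr = design.residualize(scores)
    beta, se, t, p, mono = _stats_from_residuals(Sr, yr, df)
    best = int(np.argmin(p))  # argmin takes the first minimum -> smallest k
    result = AssociationResult(
        beta=float(beta[best]),
        se=float(se[best]),
        t=float(t[best]),
        p=float(p[best]),
        n=design.n,
        collinear=bool(mono[best]),
    )
    return best + 1, result


def test_supervariant(
    score: np.ndarray, phenotype: pd.Series, design: CovariateDesign
) -> AssociationResult:
    """Covariate-adjusted association of an already-built burden score."""
    return conditional_test(score, phenotype, design, extra_snp_dosages=None)


def conditional_test(
    score: np.ndarray,
    phenotype: pd.Series,
    design: CovariateDesign,
    extra_snp_dosages: np.ndarray | None,
) -> AssociationResult:
    """Association of a score adjusting for extra SNP dosage columns.

    Used to ask whether a supervariant carries signal beyond SNPs already
    reported by earlier single-SNP studies: the extra dosages join the
    covariates, and the score's own coefficient is reported.  A score lying
    in the span of design + extras is flagged collinear with t = 0, p = 1.
    With no extras this reduces to the plain supervariant test.
    """
    y = phenotype.loc[design.index]
    res = ols_single(np.asarray(score, dtype=float), y.to_numpy(), design,
                     extra=extra_snp_dosages)
    return AssociationResult(
        beta=res["beta"], se=res["se"], t=res["t"], p=res["p"], n=res["n"],
        collinear=res["collinear"],
    )


def build_supervariants(
    gm: GenotypeMatrix,
    snp_set: SnpSet,
    phenotype: pd.Series,
    design: CovariateDesign,
    stats: pd.DataFrame | None = None,
) -> tuple[SupervariantCandidate, SupervariantCandidate]:
    """Construct the "+" and "-" supervariants of one set for one phenotype.

    ``stats`` may carry a precomputed marginal scan (covering at least the
    set's SNPs); otherwise the scan is run on the set here.  Both directions
    are always built; output is deterministic for fixed inputs.
    """
    from .scan import marginal_stats

    if stats is None:
        cols = gm.snp_indexer(snp_set.snp_ids)
        stats = marginal_stats(gm.take_snps(cols), phenotype, design)
    set_stats = stats[stats["snp_id"].isin(snp_set.snp_ids)]
    if set(set_stats["snp_id"]) != set(snp_set.snp_ids):
        missing = sorted(set(snp_set.snp_ids) - set(set_stats["snp_id"]))
        raise ValueError(f"marginal stats missing SNPs {missing} of set {snp_set.set_id}")

    out = []
    for direction in ("+", "-"):
        ranked = rank_snps(set_stats, direction)
        k, assoc = select_cutoff(gm, ranked, phenotype, design)
        out.append(
            SupervariantCandidate(
                phenotype=str(phenotype.name),
                set_id=snp_set.set_id,
                direction=direction,
                ranked_snps=tuple(ranked),
                k=k,
                construction=assoc,
            )
        )
    return out[0], out[1]


def candidates_to_frame(candidates) -> pd.DataFrame:
    """Candidate table: one row per supervariant, SNPs comma-joined."""
    rows = [
        {
            "name": c.name,
            "phenotype": c.phenotype,
            "set_id": c.set_id,
            "direction": c.direction,
            "k": c.k,
            "p_construction": c.construction.p,
            "beta_construction": c.construction.beta,
            "snps": ",".join(c.selected_snps),
        }
        for c in candidates
    ]
    return pd.DataFrame(rows)
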