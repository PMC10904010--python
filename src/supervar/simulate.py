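"""Multi-cohort genotype/covariate/phenotype simulation.

Generates hard-call genotype cohorts with the statistical structure the
supervariant pipeline assumes, so every downstream stage is testable without
access-controlled biobank data.

Genotype model
--------------
Each sample carries two independent haplotypes.  Within an LD block a
haplotype is a latent AR(1) Gaussian vector with lag-one correlation ``rho``;
the allele at SNP *j* is "minor" when the latent value falls below the
standard-normal quantile of that SNP's target minor-allele frequency.  The
genotype is the sum of the two haplotype indicators, so every SNP is in exact
Hardy-Weinberg proportions by construction, and squared genotype correlation
(r²) between SNPs decays monotonically with latent distance inside a block
while distinct blocks are independent.

Phenotype model
---------------
``y = Σ_j β_j · g_j + loading_age · age + loading_sex · sex + ε`` with
``ε ~ N(0, noise_sd²)``; effects β are per copy of the minor allele.  Age and
sex loadings default to nonzero so covariate adjustment is consequential.

Cohorts drawn from one :class:`SimulationConfig` share the SNP map, target
allele frequencies and true effects but have independent samples — the
discovery + external-validation design of a multi-cohort replication study.
One cohort may store a subset of SNPs with swapped allele labels (dosage
complemented, same underlying haplotypes) to keep the minor-allele
harmonization path permanently exercised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .genotypes import GenotypeMatrix

__all__ = [
    "CohortScheme",
    "SimulationConfig",
    "Cohort",
    "default_snp_map",
    "simulate_genotypes",
    "simulate_covariates",
    "simulate_phenotype",
    "simulate_multi_cohort",
]


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class CohortScheme:
    """Per-cohort sample size and covariate design.

    ``n_sites`` of 0 means the cohort has no site column (single-scanner
    studies); the design builder then omits site terms.  Ages are drawn
    N(age_mean, age_sd²) so cohorts can mimic studies of different age
    ranges.
    """

    n_samples: int
    age_mean: float = 55.0
    age_sd: float = 7.5
    n_sites: int = 3
    has_pcs: bool = True
    swap_alleles: tuple[str, ...] = ()  # SNP ids stored with swapped labels

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ConfigError("cohort n_samples must be positive")
        if self.n_sites < 0:
            raise ConfigError("n_sites must be >= 0")


@dataclass
class SimulationConfig:
    """Full specification of a multi-cohort simulation.

    Parameters
    ----------
    cohorts
        Ordered mapping label -> :class:`CohortScheme`.  Defaults mimic the
        four-cohort discovery/validation design: one large middle-aged
        discovery cohort and three smaller external cohorts, the second of
        which stores part of its SNPs with swapped allele labels.
    snp_map
        DataFrame with columns ``id chrom pos``; positions strictly
        increasing within a chromosome.  Built by :func:`default_snp_map`
        when omitted.
    maf_range
        Uniform sampling range for per-SNP target minor allele frequencies.
    ld_block_lengths
        Block sizes summing to the number of SNPs; ``None`` = single block
        per chromosome.
    rho
        Latent AR(1) lag-one correlation within a block, in [0, 1).
    effects
        phenotype name -> list of ``(snp_id, beta)`` additive effects per
        minor allele.
    covariate_loadings
        Fixed (age, sex) loadings added to every phenotype.
    noise_sd
        Residual standard deviation of the phenotypes.
    """

    cohorts: dict[str, CohortScheme] | None = None
    n_snps: int = 100
    snp_map: pd.DataFrame | None = None
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_lengths: list[int] | None = None
    rho: float = 0.0
    effects: dict[str, list[tuple[str, float]]] = field(default_factory=dict)
    covariate_loadings: tuple[float, float] = (0.01, 0.1)
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cohorts is None:
            self.cohorts = default_cohorts(swap_first=min(5, self.n_snps))
        labels = list(self.cohorts)
        if len(set(labels)) != len(labels):
            raise ConfigError("duplicate cohort labels")
        if self.snp_map is None:
            self.snp_map = default_snp_map(self.n_snps)
        else:
            self.snp_map = self.snp_map.reset_index(drop=True)
            self.n_snps = len(self.snp_map)
        for chrom, grp in self.snp_map.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if (pos < 1).any():
                raise ConfigError(f"positions must be >= 1 on chromosome {chrom}")
            if (np.diff(pos) <= 0).any():
                raise ConfigError(
                    f"positions must be strictly increasing on chromosome {chrom}"
                )
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigError(f"maf_range must lie in (0, 0.5], got {self.maf_range}")
        if not 0.0 <= self.rho < 1.0:
            raise ConfigError(f"rho must be in [0, 1), got {self.rho}")
        if self.ld_block_lengths is not None:
            if any(b < 1 for b in self.ld_block_lengths):
                raise ConfigError("ld_block_lengths must be positive")
            if sum(self.ld_block_lengths) != self.n_snps:
                raise ConfigError(
                    f"ld_block_lengths sum to {sum(self.ld_block_lengths)}, "
                    f"expected n_snps={self.n_snps}"
                )
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be positive")
        known = set(self.snp_map["id"])
        for pheno, eff in self.effects.items():
            missing = [s for s, _ in eff if s not in known]
            if missing:
                raise ConfigError(
                    f"effect SNPs absent from the map for {pheno!r}: {missing}"
                )
        for label, scheme in self.cohorts.items():
            missing = [s for s in scheme.swap_alleles if s not in known]
            if missing:
                raise ConfigError(
                    f"swap_alleles SNPs absent from the map for cohort {label!r}: "
                    f"{missing}"
                )


def default_cohorts(swap_first: int = 5) -> dict[str, CohortScheme]:
    """Four cohorts mirroring a large-biobank replication design.

    Sizes follow the discovery (30,842), biobank-holdout (1927), adolescent
    (4399) and young-adult (319) cohorts of a multi-study white-matter GWAS
    design; age distributions differ accordingly, and the smallest cohort has
    no site column.  The second cohort stores its first ``swap_first`` SNPs
    with swapped allele labels.
    """
    swap = tuple(f"snp{j}" for j in range(swap_first))
    return {
        "discovery": CohortScheme(30842, age_mean=55, age_sd=7.5, n_sites=3),
        "holdout": CohortScheme(1927, age_mean=55, age_sd=7.5, n_sites=3,
                                swap_alleles=swap),
        "adolescent": CohortScheme(4399, age_mean=10, age_sd=0.6, n_sites=4),
        "young_adult": CohortScheme(319, age_mean=29, age_sd=3.5, n_sites=0),
    }


def default_snp_map(
    n_snps: int, chrom: str = "1", start: int = 10_000, spacing: int = 20_000
) -> pd.DataFrame:
    """Evenly spaced SNPs on one chromosome: ids ``snp0..snp{n-1}``."""
    return pd.DataFrame(
        {
            "id": [f"snp{j}" for j in range(n_snps)],
            "chrom": chrom,
            "pos": start + spacing * np.arange(n_snps),
        }
    )


@dataclass
class Cohort:
    """One simulated cohort: genotypes + covariates + phenotypes.

    All three tables index the same samples in the same order.
    """

    label: str
    genotypes: GenotypeMatrix
    covariates: pd.DataFrame
    phenotypes: pd.DataFrame

    def __post_init__(self) -> None:
        ids = list(self.genotypes.samples)
        if list(self.covariates.index) != ids or list(self.phenotypes.index) != ids:
            raise ValueError(
                f"cohort {self.label!r}: genotype/covariate/phenotype sample ids differ"
            )


# ---------------------------------------------------------------------------
# genotypes


def _block_lengths(config: SimulationConfig) -> list[int]:
    if config.ld_block_lengths is not None:
        return list(config.ld_block_lengths)
    return [len(g) for _, g in config.snp_map.groupby("chrom", sort=False)]


def _latent_haplotype(rng: np.random.Generator, n: int, m: int, rho: float) -> np.ndarray:
    """AR(1) latent Gaussian, one row per haplotype, one column per SNP."""
    e = rng.standard_normal((n, m))
    if rho == 0.0 or m == 1:
        return e
    x = np.empty_like(e)
    x[:, 0] = e[:, 0]
    c = np.sqrt(1.0 - rho * rho)
    for j in range(1, m):
        x[:, j] = rho * x[:, j - 1] + c * e[:, j]
    return x


def simulate_genotypes(
    config: SimulationConfig,
    n_samples: int,
    rng: np.random.Generator,
    mafs: np.ndarray,
    sample_prefix: str = "S",
) -> GenotypeMatrix:
    """Draw hard-call genotypes for one cohort.

    Two independent latent haplotypes per sample are thresholded at each
    SNP's MAF quantile and summed, giving {0,1,2} dosages of the minor allele
    in exact Hardy-Weinberg proportions; LD blocks are mutually independent.
    """
    m = config.n_snps
    thresholds = norm.ppf(np.asarray(mafs))
    dosage = np.empty((n_samples, m))
    start = 0
    for block in _block_lengths(config):
        sl = slice(start, start + block)
        h1 = _latent_haplotype(rng, n_samples, block, config.rho)
        h2 = _latent_haplotype(rng, n_samples, block, config.rho)
        dosage[:, sl] = (h1 < thresholds[sl]).astype(float) + (
            h2 < thresholds[sl]
        ).astype(float)
        start += block
    samples = np.array([f"{sample_prefix}{i:06d}" for i in range(n_samples)], dtype=object)
    snps = pd.DataFrame(
        {
            "id": config.snp_map["id"],
            "chrom": config.snp_map["chrom"].astype(str),
            "pos": config.snp_map["pos"],
            "a1": "A",  # counted (target-minor) allele
            "a2": "G",
        }
    )
    return GenotypeMatrix(samples, snps, dosage)


# ---------------------------------------------------------------------------
# covariates and phenotypes


def simulate_covariates(
    config: SimulationConfig, cohort_label: str, rng: np.random.Generator,
    samples: np.ndarray,
) -> pd.DataFrame:
    """Raw covariate table for one cohort: age, sex, optional site, PCs.

    Derived terms (age², age×sex, age²×sex) are *not* stored — the design
    builder forms them, so they always stay consistent with the raw columns.
    """
    if cohort_label not in config.cohorts:
        raise ConfigError(f"unknown cohort label {cohort_label!r}")
    scheme = config.cohorts[cohort_label]
    n = len(samples)
    cov = pd.DataFrame(index=pd.Index(samples, name="IID"))
    cov["age"] = rng.normal(scheme.age_mean, scheme.age_sd, size=n)
    cov["sex"] = rng.integers(0, 2, size=n).astype(float)
    if scheme.n_sites >= 1:
        sites = rng.integers(0, scheme.n_sites, size=n)
        cov["site"] = pd.Categorical([f"site{k}" for k in sites],
                                     categories=[f"site{k}" for k in range(scheme.n_sites)])
    if scheme.has_pcs:
        for k in range(1, 11):
            cov[f"PC{k}"] = rng.standard_normal(n)
    return cov


def simulate_phenotype(
    genotypes: GenotypeMatrix,
    covariates: pd.DataFrame,
    config: SimulationConfig,
    phenotype_name: str,
    rng: np.random.Generator,
) -> pd.Series:
    """One continuous phenotype: sparse additive SNP effects + covariates + noise."""
    n = genotypes.n_samples
    y = np.zeros(n)
    effects = config.effects.get(phenotype_name, [])
    if effects:
        ids = [s for s, _ in effects]
        betas = np.array([b for _, b in effects])
        cols = genotypes.snp_indexer(ids)  # raises naming absent SNPs
        y += genotypes.imputed(cols) @ betas
    a_load, s_load = config.covariate_loadings
    if "age" in covariates:
        y += a_load * covariates["age"].to_numpy()
    if "sex" in covariates:
        y += s_load * covariates["sex"].to_numpy()
    y += rng.normal(0.0, config.noise_sd, size=n)
    return pd.Series(y, index=covariates.index, name=phenotype_name)


# ---------------------------------------------------------------------------
# full multi-cohort draw


def simulate_multi_cohort(config: SimulationConfig) -> list[Cohort]:
    """Draw every cohort of the design; deterministic given ``config.seed``.

    All cohorts share the SNP map, target MAFs and true effects; samples are
    independent across cohorts.  Cohorts whose scheme lists ``swap_alleles``
    store those SNPs with complemented dosages and swapped allele labels —
    the same underlying haplotypes under the opposite counting convention.
    """
    root = np.random.default_rng(config.seed)
    lo, hi = config.maf_range
    mafs = root.uniform(lo, hi, size=config.n_snps)
    phenos = list(config.effects) or ["trait"]

    cohorts: list[Cohort] = []
    for label, scheme in config.cohorts.items():
        rng = np.random.default_rng(root.integers(2**31))
        prefix = f"{label}_"
        gm = simulate_genotypes(config, scheme.n_samples, rng, mafs, prefix)
        cov = simulate_covariates(config, label, rng, gm.samples)
        phe = pd.DataFrame(
            {p: simulate_phenotype(gm, cov, config, p, rng) for p in phenos}
        )
        if scheme.swap_alleles:
            mask = gm.snps["id"].isin(scheme.swap_alleles).to_numpy()
            gm.dosages[:, mask] = 2.0 - gm.dosages[:, mask]
            gm.snps.loc[mask, ["a1", "a2"]] = gm.snps.loc[
                mask, ["a2", "a1"]
            ].to_numpy()
        cohorts.append(Cohort(label, gm, cov, phe))
    return cohorts
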