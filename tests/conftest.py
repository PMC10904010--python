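import numpy as np
import pandas as pd
import pytest

import supervar as sv


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_genotype_matrix(rng, n_samples=30, n_snps=10, missing_rate=0.0,
                           prefix="S", chrom="1"):
    """Ad-hoc hard-call matrix with unique biallelic SNPs."""
    dos = rng.integers(0, 3, size=(n_samples, n_snps)).astype(float)
    if missing_rate:
        mask = rng.random(dos.shape) < missing_rate
        dos[mask] = np.nan
    snps = pd.DataFrame(
        {
            "id": [f"rs{j}" for j in range(n_snps)],
            "chrom": chrom,
            "pos": 1000 + 500 * np.arange(n_snps),
            "a1": "A",
            "a2": "G",
        }
    )
    samples = np.array([f"{prefix}{i:04d}" for i in range(n_samples)], dtype=object)
    return sv.GenotypeMatrix(samples, snps, dos)


@pytest.fixture
def small_gm(rng):
    return random_genotype_matrix(rng, 30, 10, missing_rate=0.1)


@pytest.fixture
def scan_fixture(rng):
    """200 samples x 50 SNPs with a full covariate table and one phenotype."""
    gm = random_genotype_matrix(rng, 200, 50)
    cov = pd.DataFrame(index=pd.Index(gm.samples, name="IID"))
    cov["age"] = rng.normal(50, 8, 200)
    cov["sex"] = rng.integers(0, 2, 200).astype(float)
    cov["site"] = pd.Categorical(rng.choice(["s1", "s2", "s3"], 200))
    for k in range(1, 11):
        cov[f"PC{k}"] = rng.standard_normal(200)
    y = pd.Series(
        0.02 * cov["age"].to_numpy()
        + 0.3 * gm.dosages[:, 0]
        + rng.standard_normal(200),
        index=cov.index,
        name="trait",
    )
    return gm, cov, y


def planted_config(n_discovery=4000, n_external=(1000, 500), beta=0.16,
                   n_causal=5, seed=0):
    """Multi-cohort config with one causal 5-SNP block in the first window.

    Effect size 0.16 per minor allele over 5 SNPs of MAF ~U(0.2, 0.4) puts
    the aggregate score near 5% of phenotype variance, the planted-signal
    condition used throughout the recovery tests.
    """
    snp_map = pd.concat(
        [
            sv.default_snp_map(10, chrom="1", start=10_000, spacing=20_000),
            sv.default_snp_map(10, chrom="1", start=1_010_000, spacing=20_000)
            .assign(id=lambda d: "b" + d["id"]),
            sv.default_snp_map(10, chrom="2", start=10_000, spacing=20_000)
            .assign(id=lambda d: "c" + d["id"]),
        ],
        ignore_index=True,
    )
    cohorts = {"disc": sv.CohortScheme(n_discovery, n_sites=2)}
    for i, n in enumerate(n_external):
        swap = ("snp0", "snp3") if i == 0 else ()
        cohorts[f"ext{i}"] = sv.CohortScheme(n, n_sites=0, swap_alleles=swap)
    return sv.SimulationConfig(
        cohorts=cohorts,
        snp_map=snp_map,
        maf_range=(0.2, 0.4),
        effects={"fa": [(f"snp{j}", beta) for j in range(n_causal)]},
        noise_sd=1.0,
        seed=seed,
    )
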