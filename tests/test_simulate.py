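import numpy as np
import pandas as pd
import pytest
from scipy.stats import f as f_dist
from scipy.stats import ncf

import supervar as sv
from supervar.simulate import ConfigError


def one_cohort(n, seed=0, **kwargs):
    defaults = dict(cohorts={"a": sv.CohortScheme(n, n_sites=2)}, seed=seed)
    defaults.update(kwargs)
    return sv.simulate_multi_cohort(sv.SimulationConfig(**defaults))[0]


# ---------------------------------------------------------------------------
# genotypes


def test_empirical_maf_matches_target_within_binomial_error():
    # 2n = 100,000 allele draws per SNP: 3 binomial SEs of a 0.3 target
    co = one_cohort(50_000, n_snps=3, maf_range=(0.3, 0.3), seed=5)
    se = np.sqrt(0.3 * 0.7 / (2 * 50_000))
    assert np.all(np.abs(co.genotypes.maf() - 0.3) < 3 * se)


def test_ld_blocks_create_within_block_r2_only():
    """rho=0.9 gives strong adjacent r² inside blocks, ~0 across blocks."""
    within, between = [], []
    for seed in range(10):
        co = one_cohort(400, n_snps=10, ld_block_lengths=[5, 5], rho=0.9,
                        seed=100 + seed)
        c = np.corrcoef(co.genotypes.dosages.T) ** 2
        within += [c[i, i + 1] for i in range(9) if i != 4]
        between += [c[i, j] for i in range(5) for j in range(5, 10)]
    assert np.mean(within) > 0.2
    assert np.mean(between) < 0.05
    assert np.mean(within) > 10 * np.mean(between)


def test_single_snp_matrix_is_hard_calls():
    co = one_cohort(200, n_snps=1, rho=0.0, seed=1)
    assert co.genotypes.dosages.shape == (200, 1)
    assert set(np.unique(co.genotypes.dosages)) <= {0.0, 1.0, 2.0}


def test_hwe_proportions_hold_in_simulated_genotypes():
    """Exact-test p-values on independent simulated SNPs behave like nulls.

    The exact test is discrete hence conservative, so the rejection fraction
    at 0.05 sits at or just below 0.05; 3 binomial SEs bound the upside.
    """
    co = one_cohort(500, n_snps=2000, rho=0.0, seed=3)
    ps = []
    for j in range(2000):
        col = co.genotypes.dosages[:, j]
        ps.append(
            sv.hwe_exact_test(
                int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum())
            )
        )
    frac = np.mean(np.array(ps) < 0.05)
    se = np.sqrt(0.05 * 0.95 / 2000)
    assert 0.02 < frac <= 0.05 + 3 * se


def test_invalid_configurations_rejected():
    with pytest.raises(ConfigError):
        sv.SimulationConfig(rho=1.0)
    with pytest.raises(ConfigError):
        sv.SimulationConfig(maf_range=(0.0, 0.3))
    with pytest.raises(ConfigError):
        sv.SimulationConfig(n_snps=10, ld_block_lengths=[4, 4])
    with pytest.raises(ConfigError):
        sv.SimulationConfig(effects={"y": [("nope", 0.1)]})


# ---------------------------------------------------------------------------
# covariates


def test_site_levels_and_missing_site_scheme():
    cfg = sv.SimulationConfig(
        cohorts={
            "threesites": sv.CohortScheme(300, n_sites=3),
            "nosite": sv.CohortScheme(100, n_sites=0),
        },
        n_snps=4,
        seed=2,
    )
    three, none = sv.simulate_multi_cohort(cfg)
    assert three.covariates["site"].nunique() == 3
    assert "site" not in none.covariates.columns
    d = sv.build_design(none.covariates)
    assert not any(c.startswith("site") for c in d.columns)


def test_determinism_under_fixed_seed():
    cfg = dict(cohorts={"a": sv.CohortScheme(80, n_sites=2)}, n_snps=12,
               effects={"y": [("snp1", 0.5)]}, seed=77)
    c1 = sv.simulate_multi_cohort(sv.SimulationConfig(**cfg))[0]
    c2 = sv.simulate_multi_cohort(sv.SimulationConfig(**cfg))[0]
    np.testing.assert_array_equal(c1.genotypes.dosages, c2.genotypes.dosages)
    pd.testing.assert_frame_equal(c1.covariates, c2.covariates)
    pd.testing.assert_frame_equal(c1.phenotypes, c2.phenotypes)


# ---------------------------------------------------------------------------
# phenotypes


def test_null_phenotype_gives_uniform_marginal_pvalues():
    """With no effects and no loadings, per-SNP p-values are uniform."""
    co = one_cohort(400, n_snps=2000, covariate_loadings=(0.0, 0.0), seed=9)
    design = sv.build_design(co.covariates)
    stats = sv.marginal_stats(co.genotypes, co.phenotypes["trait"], design)
    frac = (stats["p"] < 0.05).mean()
    se = np.sqrt(0.05 * 0.95 / 2000)
    assert abs(frac - 0.05) < 3 * se


def test_noiseless_single_snp_recovers_beta():
    co = one_cohort(300, n_snps=5, effects={"y": [("snp2", 1.0)]},
                    covariate_loadings=(0.0, 0.0), noise_sd=1e-10, seed=4)
    design = sv.build_design(co.covariates)
    stats = sv.marginal_stats(co.genotypes, co.phenotypes["y"], design)
    assert stats.loc[stats["snp_id"] == "snp2", "beta"].iloc[0] == pytest.approx(
        1.0, abs=1e-6
    )


def test_planted_block_detected_by_joint_f_test():
    """10 equal effects explaining ~2% of variance at n=4000.

    The non-central F oracle puts power at essentially 1 for the joint test
    of the 10 true SNPs (λ = n·R²/(1−R²) ≈ 80), so at least 95 of 100 seeds
    must reject at 0.05.
    """
    n, m, beta = 4000, 10, 0.0695  # 10 · 2·0.3·0.7 · β² ≈ 2% of variance
    lam = n * 0.02 / 0.98
    analytic_power = ncf.sf(f_dist.isf(0.05, m, n - m - 1), m, n - m - 1, lam)
    assert analytic_power > 0.999

    hits = 0
    for seed in range(100):
        cfg = sv.SimulationConfig(
            cohorts={"a": sv.CohortScheme(n, n_sites=0)},
            n_snps=m,
            maf_range=(0.2, 0.4),
            effects={"y": [(f"snp{j}", beta) for j in range(m)]},
            covariate_loadings=(0.0, 0.0),
            seed=500 + seed,
        )
        co = sv.simulate_multi_cohort(cfg)[0]
        y = co.phenotypes["y"].to_numpy()
        X = np.column_stack([np.ones(n), co.genotypes.dosages])
        b, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss1 = ((y - X @ b) ** 2).sum()
        rss0 = ((y - y.mean()) ** 2).sum()
        F = ((rss0 - rss1) / m) / (rss1 / (n - m - 1))
        hits += f_dist.sf(F, m, n - m - 1) < 0.05
    assert hits >= 95


def test_phenotype_variance_decomposition():
    """Var(y) ≈ Σβ²·2·maf(1−maf) + loading² terms + noise²."""
    beta, maf = 0.4, 0.3
    a_load, s_load = 0.05, 0.3
    cfg = sv.SimulationConfig(
        cohorts={"a": sv.CohortScheme(40_000, age_sd=8.0, n_sites=2)},
        n_snps=3,
        maf_range=(maf, maf),
        effects={"y": [("snp0", beta)]},
        covariate_loadings=(a_load, s_load),
        noise_sd=1.0,
        seed=21,
    )
    co = sv.simulate_multi_cohort(cfg)[0]
    expected = (
        beta**2 * 2 * maf * (1 - maf)
        + a_load**2 * 8.0**2
        + s_load**2 * 0.25
        + 1.0
    )
    observed = co.phenotypes["y"].var()
    assert observed == pytest.approx(expected, rel=0.05)


def test_effect_snp_absent_names_the_snp():
    cfg = sv.SimulationConfig(
        cohorts={"a": sv.CohortScheme(50, n_sites=0)}, n_snps=3,
        effects={"y": [("snp2", 0.5)]}, seed=6,
    )
    co = sv.simulate_multi_cohort(cfg)[0]
    gm_missing = co.genotypes.take_snps(np.array([0, 1]))
    with pytest.raises(KeyError, match="snp2"):
        sv.simulate_phenotype(
            gm_missing, co.covariates, cfg, "y", np.random.default_rng(0)
        )


# ---------------------------------------------------------------------------
# multi-cohort structure


def test_four_cohort_default_sizes_match_study_design():
    cfg = sv.SimulationConfig(n_snps=5, seed=8)
    cohorts = sv.simulate_multi_cohort(cfg)
    assert [c.genotypes.n_samples for c in cohorts] == [30842, 1927, 4399, 319]
    assert len({c.label for c in cohorts}) == 4


def test_swap_fixture_complements_dosages():
    base = dict(
        cohorts={"a": sv.CohortScheme(60, n_sites=0)}, n_snps=6, seed=13
    )
    plain = sv.simulate_multi_cohort(sv.SimulationConfig(**base))[0]
    base["cohorts"] = {
        "a": sv.CohortScheme(60, n_sites=0, swap_alleles=("snp0", "snp5"))
    }
    swapped = sv.simulate_multi_cohort(sv.SimulationConfig(**base))[0]
    np.testing.assert_array_equal(
        swapped.genotypes.dosages[:, 0], 2.0 - plain.genotypes.dosages[:, 0]
    )
    np.testing.assert_array_equal(
        swapped.genotypes.dosages[:, 5], 2.0 - plain.genotypes.dosages[:, 5]
    )
    np.testing.assert_array_equal(
        swapped.genotypes.dosages[:, 1:5], plain.genotypes.dosages[:, 1:5]
    )


def test_single_cohort_config_yields_one_cohort():
    cfg = sv.SimulationConfig(cohorts={"only": sv.CohortScheme(10)}, n_snps=2, seed=1)
    assert len(sv.simulate_multi_cohort(cfg)) == 1


def test_duplicate_cohort_labels_impossible_by_construction():
    # dict keys are unique; the config still validates the invariant
    cfg = sv.SimulationConfig(
        cohorts={"a": sv.CohortScheme(5), "b": sv.CohortScheme(5)}, n_snps=2, seed=0
    )
    assert len(cfg.cohorts) == 2
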