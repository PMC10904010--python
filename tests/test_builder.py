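import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import supervar as sv

from conftest import planted_config, random_genotype_matrix


def brute_force_cutoff(gm, ranked, y, design):
    """From-scratch sweep: re-aggregate at every k, joint OLS, first minimum."""
    yv = y.loc[design.index].to_numpy()
    sub = gm.select_samples(design.index)
    best = None
    for k in range(1, len(ranked) + 1):
        score = np.zeros(len(yv))
        for s in ranked[:k]:
            j = int(np.flatnonzero(sub.snps["id"].to_numpy() == s)[0])
            col = sub.dosages[:, j].copy()
            if np.isnan(col).any():
                col[np.isnan(col)] = np.nanmean(col)
            score += col
        fit = sm.OLS(yv, np.column_stack([design.X, score])).fit()
        p = fit.pvalues[-1]
        if best is None or p < best[1]:  # strict < keeps the smaller k on ties
            best = (k, p, fit.params[-1])
    return best


def stats_frame(t_values, chrom="1"):
    m = len(t_values)
    return pd.DataFrame(
        {
            "snp_id": [f"r{j}" for j in range(m)],
            "chrom": chrom,
            "pos": 100 * (1 + np.arange(m)),
            "t": t_values,
        }
    )


# ---------------------------------------------------------------------------
# ranking


def test_rank_orders_by_t_per_direction():
    stats = stats_frame([2.1, -0.3, 5.0])
    assert sv.rank_snps(stats, "+") == ["r2", "r0", "r1"]
    assert sv.rank_snps(stats, "-") == ["r1", "r0", "r2"]


def test_rank_tie_breaks_by_genomic_position():
    stats = stats_frame([1.5, 1.5, 0.0])
    assert sv.rank_snps(stats, "+")[:2] == ["r0", "r1"]


def test_rank_rejects_empty_set():
    with pytest.raises(ValueError):
        sv.rank_snps(stats_frame([]), "+")


# ---------------------------------------------------------------------------
# aggregation


def test_aggregate_score_sums_minor_allele_counts():
    dos = np.array([[0.0, 1.0, 2.0], [0.0, 0.0, 0.0]])
    snps = pd.DataFrame(
        {"id": ["a", "b", "c"], "chrom": "1", "pos": [1, 2, 3], "a1": "A", "a2": "G"}
    )
    gm = sv.GenotypeMatrix(np.array(["x", "y"], dtype=object), snps, dos)
    np.testing.assert_array_equal(sv.aggregate_score(gm, ["a", "b", "c"]), [3.0, 0.0])
    with pytest.raises(KeyError, match="nope"):
        sv.aggregate_score(gm, ["a", "nope"])


# ---------------------------------------------------------------------------
# cutoff selection


def _fixture_with_design(rng, n=120, m=12, missing_rate=0.0):
    gm = random_genotype_matrix(rng, n, m, missing_rate=missing_rate)
    cov = pd.DataFrame(
        {"age": rng.normal(50, 6, n), "sex": rng.integers(0, 2, n).astype(float)},
        index=pd.Index(gm.samples, name="IID"),
    )
    design = sv.build_design(cov)
    y = pd.Series(
        0.3 * gm.imputed()[:, :4].sum(axis=1) + rng.standard_normal(n),
        index=cov.index, name="ph",
    )
    return gm, design, y


@pytest.mark.parametrize("missing_rate", [0.0, 0.1])
def test_select_cutoff_matches_brute_force(rng, missing_rate):
    gm, design, y = _fixture_with_design(rng, missing_rate=missing_rate)
    stats = sv.marginal_stats(gm, y, design)
    for direction in ("+", "-"):
        ranked = sv.rank_snps(stats, direction)
        k, assoc = sv.select_cutoff(gm, ranked, y, design)
        bk, bp, bbeta = brute_force_cutoff(gm, ranked, y, design)
        assert k == bk
        assert assoc.p == pytest.approx(bp, rel=1e-8, abs=1e-12)
        assert assoc.beta == pytest.approx(bbeta, rel=1e-8)


def test_select_cutoff_tie_takes_smaller_k(rng):
    """Two identical ranked columns give identical t at k=1 and k=2."""
    n = 60
    col = rng.integers(0, 3, n).astype(float)
    dos = np.column_stack([col, col])
    snps = pd.DataFrame(
        {"id": ["a", "b"], "chrom": "1", "pos": [1, 2], "a1": "A", "a2": "G"}
    )
    gm = sv.GenotypeMatrix(
        np.array([f"s{i}" for i in range(n)], dtype=object), snps, dos
    )
    cov = pd.DataFrame(index=pd.Index(gm.samples, name="IID"))
    design = sv.build_design(cov)
    y = pd.Series(col + rng.standard_normal(n), index=cov.index)
    k, _ = sv.select_cutoff(gm, ["a", "b"], y, design)
    assert k == 1


def test_single_snp_set_forces_k1(rng):
    gm, design, y = _fixture_with_design(rng, m=1)
    k, assoc = sv.select_cutoff(gm, ["rs0"], y, design)
    assert k == 1
    assert 0.0 < assoc.p <= 1.0


def test_planted_prefix_recovered_in_most_seeds():
    """5 equal strong effects among 30 SNPs: k* should land near 5."""
    hits = 0
    for seed in range(50):
        cfg = planted_config(n_discovery=4000, n_external=(), beta=0.25, seed=seed)
        co = sv.simulate_multi_cohort(cfg)[0]
        design = sv.build_design(co.covariates)
        y = co.phenotypes["fa"]
        window = sv.partition_genome(co.genotypes.snps)[0]
        stats = sv.marginal_stats(co.genotypes, y, design)
        ranked = sv.rank_snps(stats[stats["snp_id"].isin(window.snp_ids)], "+")
        k, _ = sv.select_cutoff(co.genotypes, ranked, y, design)
        hits += 4 <= k <= 6
    assert hits >= 45


# ---------------------------------------------------------------------------
# candidate construction


def test_build_supervariants_totality_and_names(rng):
    gm, design, y = _fixture_with_design(rng)
    window = sv.partition_genome(gm.snps)[0]
    plus, minus = sv.build_supervariants(gm, window, y, design)
    assert plus.name == f"ph_{window.set_id}+"
    assert minus.name == f"ph_{window.set_id}-"
    for cand in (plus, minus):
        assert cand.selected_snps == cand.ranked_snps[: cand.k]
        assert 1 <= cand.k <= len(window)
    # deterministic rerun
    again = sv.build_supervariants(gm, window, y, design)
    assert again == (plus, minus)


def test_minus_candidate_built_even_when_all_effects_positive(rng):
    n = 200
    gm = random_genotype_matrix(rng, n, 4)
    cov = pd.DataFrame(index=pd.Index(gm.samples, name="IID"))
    design = sv.build_design(cov)
    y = pd.Series(gm.imputed().sum(axis=1) + 0.1 * rng.standard_normal(n),
                  index=cov.index, name="ph")
    stats = sv.marginal_stats(gm, y, design)
    assert (stats["t"] > 0).all()
    window = sv.partition_genome(gm.snps)[0]
    _, minus = sv.build_supervariants(gm, window, y, design, stats=stats)
    assert minus.direction == "-"
    assert minus.ranked_snps[0] == stats.sort_values("t").iloc[0]["snp_id"]


def test_top_ranked_positive_snp_gives_positive_k1_beta(rng):
    gm, design, y = _fixture_with_design(rng)
    stats = sv.marginal_stats(gm, y, design)
    assert (stats["t"] > 0).any()
    ranked = sv.rank_snps(stats, "+")
    score = sv.aggregate_score(gm, ranked[:1])
    assoc = sv.test_supervariant(pd.Series(score, index=design.index), y, design)
    assert assoc.beta > 0


# ---------------------------------------------------------------------------
# conditional test


def test_conditional_with_no_extras_reduces_to_plain_test(rng):
    gm, design, y = _fixture_with_design(rng)
    score = pd.Series(sv.aggregate_score(gm, ["rs0", "rs1"]), index=design.index)
    plain = sv.test_supervariant(score, y, design)
    cond = sv.conditional_test(score, y, design, None)
    assert plain == cond


def test_conditioning_on_own_snps_flags_collinearity(rng):
    gm, design, y = _fixture_with_design(rng)
    ids = ["rs0", "rs1"]
    score = pd.Series(sv.aggregate_score(gm, ids), index=design.index)
    extra = gm.imputed(gm.snp_indexer(ids))
    res = sv.conditional_test(score, y, design, extra)
    assert res.collinear
    assert res.p == 1.0
    assert res.t == 0.0


def test_conditioning_on_the_true_driver_weakens_the_score(rng):
    """When one conditioned-on SNP carries all signal, conditional p rises."""
    n = 600
    gm = random_genotype_matrix(rng, n, 6)
    cov = pd.DataFrame(index=pd.Index(gm.samples, name="IID"))
    design = sv.build_design(cov)
    driver = gm.imputed()[:, 0]
    y = pd.Series(0.8 * driver + rng.standard_normal(n), index=cov.index, name="ph")
    score = pd.Series(sv.aggregate_score(gm, ["rs0", "rs1", "rs2"]),
                      index=design.index)
    marginal = sv.test_supervariant(score, y, design)
    conditional = sv.conditional_test(score, y, design, driver[:, None])
    assert conditional.p > marginal.p
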