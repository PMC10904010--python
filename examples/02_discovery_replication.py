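"""Discover and internally validate supervariants by repeated split-sample runs.

Plants a 5-SNP additive effect (~5% of phenotype variance) inside the first
1-Mbp window of a 30-SNP map, then runs the full procedure: 10 random
half-splits; on each first half, SNPs in every window are ranked by
covariate-adjusted marginal t and aggregated at the p-minimizing cutoff; a
candidate is discovered at the Bonferroni level 0.05/(n_sets x 2 x
n_phenotypes) and validated on the held-out half at 0.05/n_phenotypes.
Supervariants validated in >= 6 of 10 replications are retained, and their
SNPs selected in >= 3 validated replications form the frozen external list.
"""

import supervar as sv

cfg = sv.SimulationConfig(
    cohorts={"discovery": sv.CohortScheme(4000, n_sites=2)},
    snp_map=sv.default_snp_map(30, spacing=100_000),
    maf_range=(0.2, 0.4),
    effects={"fa": [(f"snp{j}", 0.16) for j in range(5)]},
    seed=3,
)
cohort = sv.simulate_multi_cohort(cfg)[0]
sets = sv.partition_genome(cohort.genotypes.snps)
print(f"{len(sets)} window sets -> {2 * len(sets)} candidates per phenotype")

th = sv.Thresholds.for_study(n_sets=len(sets), n_phenotypes=1)
print(f"alpha_discovery = {th.alpha_discovery:.2e}, "
      f"alpha_validation = {th.alpha_validation:.3f}")

summary = sv.run_study(cohort, sets, ["fa"], th, master_seed=11, progress=True)
print("\nretained supervariants (validated >= 6/10):")
print(summary.retained[["name", "times_discovered", "times_validated",
                        "median_k"]].to_string(index=False))
for name, snps in summary.frozen_snps.items():
    print(f"frozen SNPs for {name}: {sorted(snps)}")

chance = sv.binomial_validation_probability(th.alpha_validation,
                                            th.n_replications, th.retention_min)
print(f"\nchance of a null supervariant clearing >= {th.retention_min}/"
      f"{th.n_replications} validations: {chance:.2e}")
# The retained entry should be fa_Chr1_1+ covering snp0..snp4 — the planted
# block — while every null window stays out; the chance level shows why
# six-of-ten retention is a stringent reproducibility guard.
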