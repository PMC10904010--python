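# Methods

## The supervariant procedure

A supervariant over a SNP set S is built in four steps for a given
phenotype y and covariate matrix C:

1. **Marginal scan.** For each SNP g in S, fit y ~ C + g by ordinary least
   squares and record the t-statistic of g's coefficient.  The scan
   residualizes y and all dosage columns against C once (Frisch–Waugh), so
   the per-SNP statistics are numerically identical to the joint fits at a
   fraction of the cost; residual degrees of freedom are n − p − 1 with p
   the number of design columns, and two-sided p-values use the exact t
   distribution rather than a normal approximation (it matters at the
   sample sizes the tests use).
2. **Ranking.** Sort SNPs by t descending (positive direction) or ascending
   (negative direction).  Ties break by (chromosome, position, id), making
   the order total and reproducible across runs and platforms.
3. **Adaptive cutoff.** For every k = 1..|S|, sum the top-k minor-allele
   dosages into a burden score and fit y ~ C + score; keep the k with the
   smallest p.  Prefix scores are cumulative sums of the ranked columns, so
   the whole sweep costs one cumulative sum and one shared residualization.
   Exact p ties resolve to the smaller k (parsimony).
4. **Candidate.** The pair (ranked list, k) with its association statistics
   is the supervariant candidate, named `{pheno}_{set}{+|-}`.  Both
   directions are always built, even when all marginal t share one sign:
   totality keeps the candidate space fixed, and a hopeless direction simply
   fails validation.

The minimum over k is an optimized statistic and is deliberately left
uncorrected within the sweep — the split-sample validation is the guard.

## Split-sample internal validation

Each of R = 10 replications randomly halves the discovery cohort (sizes
⌊n/2⌋ and n − ⌊n/2⌋; the split fraction is configurable because unbalanced
designs are worth probing, but 0.5 is the default).  Minor-allele
orientation is determined on the construction half and propagated to the
held-out half, so both count the same allele.  A candidate is *discovered*
when its construction p beats 0.05/(n_sets × 2 × n_phenotypes); its SNP
membership is then frozen, re-aggregated on the held-out half, and tested
against a design refit on that half; it is *validated* at 0.05/n_phenotypes.
Validation demands significance only — sign concordance is recorded and can
be required via a strict flag, but is not part of the default criterion.
A supervariant, identified by (phenotype, set, direction) with membership
free to vary across replications, is retained when validated ≥ 6 of 10
times.  For retained supervariants, SNPs selected in ≥ 3 validated
replications form the frozen external-validation list; the count is taken
over validated replications because those are the replications whose
membership the procedure endorses.

Under the global null with uniform held-out p-values the chance of clearing
the retention rule is the binomial upper tail P(X ≥ 6), X ~ Bin(10,
0.05/n_phenotypes) — computed in log space so values near 1e-14 keep full
relative precision.

## External validation and meta-analysis

External cohorts are first harmonized: each shared SNP whose counted allele
differs from the discovery minor allele has its dosage complemented
(g → 2 − g); SNPs absent from a cohort or with unmatchable allele labels are
excluded and reported, never silently dropped.  A supervariant absent from
some cohorts is meta-analyzed over the cohorts that do carry it, with the
attrition visible in the report.  Per-cohort associations use each cohort's
own covariate design (site terms only where a site column exists).  The
combination is the sample-size-weighted Z scheme (weights √n_i on signed
Z_i); inverse-variance weighting and heterogeneity statistics are out of
scope.  Input p-values of exactly zero are floored at 1e-300 — the smallest
value whose inverse-normal image is finite — and flagged.

## Quality control

Boundary semantics are literal: samples are removed when their missing-call
rate is **strictly greater** than 0.10; variants are removed when MAF is
**≤** 0.01, missing rate **≥** 0.10, or the Hardy–Weinberg exact p is
**<** 1e-7.  All three variant filters are evaluated on the input matrix, so
their order cannot matter.  The HWE test enumerates every heterozygote count
compatible with the observed allele totals and sums the probabilities of
configurations no more probable than the observed one, in log space;
probability ties are recognized up to a 1e-10 relative log tolerance so
floating-point noise cannot split an exact tie.  Missing dosages are
mean-imputed per SNP at regression/aggregation time only and never
persisted.  An imputation INFO-score filter is accepted in configuration but
inert: synthetic hard calls carry no INFO field.

## Synthetic cohorts

The generator emulates the statistical structure the pipeline assumes, not
real genomes.  Each sample receives two independent haplotypes; within an LD
block a haplotype is a latent AR(1) Gaussian with lag-one correlation rho,
and the allele at SNP j is minor when the latent value is below
Φ⁻¹(MAF_j).  Summing the two haplotype indicators yields {0,1,2} dosages in
exact Hardy–Weinberg proportions, with r² decaying monotonically in latent
distance inside a block and independence across blocks.  The AR(1) choice
(over an equicorrelated block) gives distance-decaying LD with a single
parameter.  Cohorts share the SNP map, target MAFs and true effects;
samples are independent.  Default cohort sizes (30,842 / 1,927 / 4,399 /
319) and age distributions mirror a four-cohort discovery-plus-replication
imaging-genetics design; the second cohort stores part of its SNPs under
swapped allele labels by default so the harmonization path is permanently
exercised.  Phenotypes are Gaussian: y = Σβ_j g_j + 0.01·age + 0.1·sex + ε,
ε ~ N(0, noise_sd²), with the age/sex loadings nonzero by default so that
covariate adjustment is consequential in tests.  Phenotypes are emitted
untransformed; an inverse-normal transform is a user-side choice and off by
default.

What the generator does **not** model: imputation dosages or INFO scores,
population structure beyond synthetic PC columns, relatedness (cohorts are
unrelated by construction, so no kinship pruning is provided), realistic
recombination maps, or non-Gaussian phenotype tails.  Passing tests
therefore certify the procedure's statistical behavior under its own
assumptions, not robustness to those real-data complications.

## Covariate design

The design is intercept, age, sex, site indicators (first observed level is
the reference), age², age×sex, age²×sex, and PC1–PC10 — each term present
only when its raw columns exist, so a single-site cohort simply has no site
terms.  Derived terms are formed inside the builder from raw age/sex and
never stored, keeping them consistent by construction.  Rows with any
missing covariate are dropped (count recorded).  A rank-deficient design is
an error naming the collinear terms (pivoted-QR diagnosis) rather than a
silent near-singular fit.

## Numerical and design choices

- Window index k = ⌊pos/10⁶⌋ + 1, so positions 1–999,999 form set 1 and
  1,000,000–1,999,999 set 2; the first window of each chromosome is one
  position shorter than the rest, which the indexing formula accepts as
  ground truth.
- MAF exactly 0.5 breaks the minor-allele tie toward the lexicographically
  smaller allele label, making orientation deterministic across cohorts.
- Monomorphic SNPs (zero dosage variance after imputation) report beta 0,
  t 0, p 1 with a flag: rankings stay total and such SNPs can never head a
  ranking.
- A supervariant score collinear with the conditioning SNPs in a
  conditional test returns p = 1 with a collinearity flag instead of an
  exploding coefficient.
- Per-replication seeds are master_seed + replication index: reproducible,
  with independent splits.
- PLINK .bed I/O is implemented in-package (SNP-major v1.00; 00 = two
  copies of A1, 10 = het, 11 = zero, 01 = missing) and round-trips hard
  calls bit-exactly; a single-file TSV dosage dialect
  (`#CHROM POS ID A1 A2 <IID...>`) serves tiny fixtures.

## Problem sizes used by the test suite

The calibration and recovery suites run at desk scale by design: null
calibration uses 50 window sets × 1 phenotype at n = 2,000 over 20
replications plus a 2,000-SNP uniformity scan; signal recovery plants a
5-SNP block carrying ~5% of phenotype variance (β = 0.16 per minor allele at
MAF 0.2–0.4) at n = 4,000 discovery and n = 1,500 external across 20 study
draws.  These sizes give the binomial/KS assertions comfortable power while
keeping the full suite under a minute of compute.

## Known limitations

The pipeline tests additive burden scores only; indicator coding and
tree-based importance ranking for epistatic effects are out of scope, as are
mixed models, relatedness correction, FDR-based alternatives to Bonferroni,
inverse-variance meta-analysis, and VCF input.
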