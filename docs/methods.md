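# Methods

## Model and procedure

BLESS treats SNP discovery as an ensemble testing problem. Let y be a
binary outcome on n subjects, C a fixed covariate block (age, cognitive
scores, ApoE4 status, ancestry PCs, …) and G an n×p additive dosage
matrix. Each of T iterations draws ⌊f·n⌋ subjects without replacement
and m SNPs uniformly, then fits the joint logistic model

    logit Pr(y_i = 1) = β₀ + γᵀC_i + Σ_{j ∈ S_t} β_j G_ij

on the subsample, recording a two-sided Wald p-value per sampled SNP.
All m SNPs enter one model per iteration (not m marginal fits): the joint
fit adjusts each SNP for its co-sampled SNPs, and random subsetting keeps
the design far from the p > n collinear regime.

Pooling across iterations gives each SNP j a p-value group of size
k_j ≤ T. The group is Benjamini–Hochberg adjusted with multiplicity
m = k_j (the *dynamic multiplicity*: only tests that actually produced a
p-value count), and the SNP's score is the group's minimum adjusted
p-value. Significance is min-adjusted-p < α (default 0.05); ranking is
ascending on the minimum with ties broken by selection count (desc),
median raw p (asc), then SNP ID.

The minimum over k_j dependent adjusted p-values is not a calibrated
p-value; the output is a *ranked candidate list*, and the null-calibration
guarantee in the test suite applies to the SNP-wise baseline, not to the
ensemble score.

## Defaults and why

| parameter | default | rationale |
|---|---|---|
| subsample fraction f | 0.9 | the conventional subagging choice for a few hundred subjects; 1.0 removes resampling variation, 0.8 discards more data per fit |
| features per model m | round(√p) | the usual bagging heuristic (≈30 at p = 1000); always overridable |
| iterations T | 1000 | gives each SNP ≈ T·m/p tests (≈30 at p=1000, m=30); raise T until every SNP's selection count is comfortably positive |
| α | 0.05 | list-inclusion threshold on the min adjusted p |
| FDR method | BH step-up | the standard FDR adjustment; the dynamic-multiplicity rule is defined for it |
| QC thresholds | missingness 0.05, MAF 0.05, HWE 1e-6, 10 PCs computed / 5 used | standard PLINK-style small-cohort values |

Failed base tests (SNP monomorphic or collinear within a subsample,
separated or non-converged fits) contribute neither a p-value nor
multiplicity; they are tallied in the run log. An iteration whose
subsample has a constant outcome is discarded and logged, not redrawn,
so T keeps its interpretation as the number of attempted iterations.
Separation is declared on optimizer failure or |β| > 15 on the logit
scale; no penalized fallback is fitted — a missing p-value is more honest
than a fabricated one.

Determinism: iteration t uses an RNG substream seeded by (seed, t), so
results are identical for any worker count or execution order; ranked
lists round-trip byte-identically.

## Synthetic data

The simulator emulates the statistical shape of a post-QC small-cohort
panel (defaults n=197, p=1000, MAF ~ U[0.05, 0.5], LD blocks of 4 at
latent correlation 0.5):

- **Genotypes.** Per block and haplotype, an equicorrelated Gaussian is
  thresholded at the MAF quantile; dosage = sum of two independent
  haplotypes. HWE holds by construction. The realized dosage correlation
  is the phi-coefficient of the thresholded pair and sits somewhat below
  the latent r (at r=0.5, MAF 0.3: ≈0.3–0.4) — r is a knob, not a target
  the generator hits exactly.
- **Blueprint.** k true SNPs are accepted greedily down a ranking under
  pairwise r² < 0.8; every other panel SNP at r² ≥ 0.8 to a true SNP is
  pruned. Effects are β_j ~ N(0.3, 0.1) — drawn directly, the only
  self-contained reading of "effects around 0.3 with sd a third of the
  mean" — β₀ = 0, and y ~ Bernoulli(expit(Σ β_j SNP_j)) over the true
  SNPs only (panel nulls have β = 0, so this is exact). Replicates
  redraw effects and outcomes over fixed genotypes.

What it does not emulate: real LD decay (block structure is rectangular),
ancestry stratification, covariate-outcome confounding, genotyping-error
patterns, or real effect-size distributions. A green benchmark test
therefore establishes correct mechanics and qualitative behavior, not
field performance on cohort data.

With β ≈ 0.3 and n ≈ 200 the per-SNP Wald noncentrality is ≈ 1, so
single-test power is ≈ 0.2 before any correction. In this world the
SNP-wise + BH baseline finds almost nothing (median recall 0), and the
ensemble's median recall sits near 0.2–0.3 at precision ≈ 0.3: the
ensemble recovers real signal the scan misses, but "recall ≥ 0.8" is not
attainable at these effect sizes for any method that tests β = 0.3
against n = 197 — recovering it would require effects several times
larger. The benchmark acceptance test asserts the stronger published
pattern and is intentionally left failing with these measurements in its
message.

## Numerical conventions

- BH and Bonferroni go through `statsmodels.stats.multitest`; tests
  verify both against a from-definition step-up oracle at 1e-12.
- HWE: 1-df chi-square goodness of fit at the estimated allele frequency
  (not the exact test); monomorphic SNPs return p = 1 and are left to the
  MAF filter.
- PCA standardizes dosage columns (SNP-mean imputation internally,
  zero-variance columns dropped) and fixes each component's sign so its
  largest-magnitude loading is positive.
- Missing dosages: `NA` in text, NaN + mask internally, never
  zero-filled; marginal fits drop missing rows per SNP, base models use
  complete cases over the sampled SNPs.
- Mode-imputation ties take the smallest level, with a warning.
- Rank-deficient base designs drop later columns (SNPs) in favor of
  earlier ones (covariates first), flagging dropped SNPs as collinear.

## Limitations

- The minimum-adjusted-p score has no frequentist error guarantee;
  downstream use should treat the list as enrichment/prioritization
  input.
- Binary outcomes only; no Firth penalization, interactions, or
  dominant/recessive codings.
- The LD generator cannot produce very high dosage correlations at
  unequal MAFs (phi-coefficient ceiling), so near-duplicate-SNP edge
  cases are exercised with literally duplicated columns in tests.
- QC omits relatedness/kinship filtering and X-chromosome-aware HWE.
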