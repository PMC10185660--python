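# Methods

This note documents the statistical model, the synthetic-data generator and
the numerical choices behind `rorp-prs`. It is the package's own account of
its science; every number quoted here is computed by the tests or the
acceptance script.

## The phenotype: ROR-P from expression

ROR-P is a continuous tumor-aggressiveness score derived from the PAM50
intrinsic-subtype signature. The implementation follows the standard
nearest-centroid workflow:

1. **Probe collapse.** Genes measured by several probes are collapsed to the
   arithmetic mean across probes. Probes mapping to more than one gene are an
   input error; unmapped probes are dropped and counted.
2. **ER-balanced normalization.** Centroid-based subtyping assumes the target
   set resembles the ER mix of the signature's training set. Each repetition
   of the balancing procedure takes all ER-negative tumors plus an equal
   number of ER-positive tumors drawn without replacement and records the
   per-gene median; after 1000 repetitions the reference is the per-gene
   median of medians, which is subtracted from the (collapsed) expression.
   If ER-positive tumors are scarcer than ER-negative ones, the draw falls
   back to sampling with replacement and warns. The procedure is vectorized
   and chunked; it is deterministic given its seed.
3. **Centroid correlations.** Per sample, Spearman rank correlation with the
   five subtype centroids over the shared genes (≥3 required). The call is
   the argmax; exact ties resolve in the fixed label order Basal, Her2,
   LumA, LumB, Normal. Constant expression vectors have undefined rank
   correlations and are excluded from calls with a warning.
4. **Score.**
   `ROR-P = −0.001·Basal + 0.7·Her2 − 0.95·LumA + 0.49·LumB + 0.34·Prolif`,
   with `Prolif` the mean normalized expression of the flagged proliferation
   genes. The Normal-like correlation participates in the call only. The raw
   combination lives on roughly [−2.2, 2.2]; clinical reports use a 0–100
   scale whose affine transform is not part of the published combination, so
   the raw value is canonical here and `affine_rescale_to_0_100()` provides a
   clearly-labeled optional mapping (correlation terms bounded by ±1,
   proliferation clamped to a configurable range, default [−2, 2]).
   Low/Medium/High cutoffs are configuration, not defaults: published group
   assignments exist but the cutpoints on the raw scale do not.

The centroid matrix shipped by the generator is **synthetic** (seeded
standard-normal profiles, near-flat rows for the proliferation subset so
those genes track proliferation rather than subtype). Users supply published
centroids as TSV for real data.

## PRS construction

* **LD clumping**: greedy, visiting candidates by ascending published GWAS
  p-value (ties by SNP id); a SNP is kept iff r² < 0.2 with every kept SNP.
  Pairs absent from the LD table count as r² = 0. The output is maximal:
  every dropped SNP conflicts with a kept one.
* **Missingness**: SNPs with >5% missing genotypes are excluded; remaining
  missing entries are drawn from (q², 2pq, p²) at the SNP's observed allele
  frequency among non-missing samples.
* **Residualization**: OLS of ROR-P on PC1–10 plus study dummies (first
  level dropped). Rank deficiency raises an error naming the collinear
  columns (QR with pivoting).
* **Scan**: one simple linear regression of the residual per SNP, vectorized;
  two-sided p from the t distribution; monomorphic SNPs flagged and excluded.
* **Threshold selection**: grid 0.1–0.6 in steps of 0.025 (21 points; the
  grid the published analysis tested is not printed, so the step is chosen to
  include its selected 0.375), 5-fold CV repeated 10×. Within each training
  fold the covariate model, the scan and the per-SNP weights are all refit —
  nothing estimated on held-out samples leaks in. The fold metric is the
  squared Pearson correlation between the held-out PRS and the held-out
  residual (training-fold covariate model applied to held-out covariates);
  correlation-r² is used rather than regression-R² because the PRS scale is
  arbitrary per fold. Thresholds where no SNP passes score 0 with a warning.
  Ties select the smaller threshold. The final SNP set comes from a full-data
  scan at the selected threshold.
* **Weights**: per selected SNP, the dosage coefficient of a single-SNP model
  `ROR-P ~ dosage + PC1–10 + study`, computed by Frisch–Waugh–Lovell
  residualization (numerically identical to the full regression; verified
  against statsmodels OLS to 1e-10 in the tests).
* **Scoring**: `PRS = Σ β_k x_k` over the weight SNPs available in the target
  genotypes; unavailable SNPs are dropped without reweighting and the
  coverage fraction is reported. Standardization is a z-score over the case
  set; the likelihood-ratio comparator uses `log-zscore`.

## Comparator likelihood-ratio scores

The case-case ER−/ER+ contrast is `β_ER− − β_ER+` (both log-odds against the
same controls). The likelihood-ratio parameterization is the standard
population-calibrated per-allele form: with risk-allele frequency p, q = 1−p
and per-allele OR, the mean multiplicative risk is μ = (p·OR + q)² and
LR_g = OR^g/μ, so Σ_g HWE(g)·LR_g = 1 identically (tested to 1e-10 across
OR ∈ [0.5, 3], p ∈ [0.05, 0.95]). The score is the product of LRs, computed
as an exponentiated sum of logs; absent SNPs contribute factor 1. The source
publications for this construction do not print the formula; the per-allele
form implemented here is documented as an interpretation, and the same
machinery scores an overall-risk PRS from any published OR/frequency table.

## Survival validation

* **Cox models** go through lifelines (Efron tie handling — the original
  analysis does not state its method, and simulated event times are
  continuous so the choice is immaterial there). Exposures are standardized,
  so effects read as HR per SD; joint models (two PRSs) and ER-stratified
  fits use the same path. Nested covariate sets: ancestry (PC1–10);
  +age+BMI; +stage; +treatments; +measured ROR-P; +ER.
* **KM tertiles** are rank-based on the analyzed cases (sizes differ by ≤1),
  with the 2-df log-rank test.
* **Meta-analysis**: study SEs recovered from Wald CIs as
  (ln U − ln L)/3.92; between-study variance τ² by REML (bounded scalar
  minimization of the restricted negative log-likelihood, tolerance 1e-10,
  explicit boundary check at 0); summary = inverse-variance weighted mean
  with weights 1/(SE²+τ²); Cochran's Q with fixed-effect weights and
  I² = max(0, (Q−df)/Q)·100, floored at 0. The implementation reproduces
  R metafor's REML τ², summary and CI to ~1e-6 on a heterogeneous fixture
  (frozen in the tests); note metafor reports a different I² definition
  (τ²-based), so only Q is compared there.
* **Grønnesby–Borgan**: samples are split into 10 equal-size strata of the
  fitted linear predictor; the statistic is the Rao score test for adding
  the 9 group indicators, using a hand-written Efron partial-likelihood
  gradient/Hessian evaluated at (β̂, 0) (lifelines exposes no score test).
  Event-free groups merge into the adjacent lower-risk group with a warning,
  reducing the df. Under a correctly specified model the p-values are
  uniform (KS-checked over 500 replicates in the acceptance tests).
* **Bootstrap calibration**: predicted survival at the horizon (Breslow
  baseline) versus per-stratum Kaplan–Meier, in 10 predicted-risk strata.
  The bias correction subtracts the bootstrap optimism: mean over resamples
  of the calibration error of the refitted model on its bootstrap sample
  minus its error on the original sample. The published analysis names only
  "bias-corrected"; this optimism scheme is the package's interpretation.
  `n_boot=0` returns the apparent curve with a warning.

## The synthetic cohort generator

The generator emulates the study conditions; it is first-class, tested code.

* **Genotypes**: independent SNPs, HWE, MAF ~ U(0.05, 0.5), 226 candidates
  by default, published GWAS p-values drawn as 10^−U(8,30) (genome-wide
  significant, unrelated to the simulated expression effects — matching how
  susceptibility SNPs relate to a downstream tumor phenotype). Optional LD
  partners are allele copies refreshed with probability 1 − √r² (target
  r² 0.5 by default) and always carry the larger published p, so clumping
  retains the source. Missingness is i.i.d. (default 2%).
* **Tumor state**: intrinsic subtype from a multinomial logit whose linear
  predictor moves along an aggressiveness axis (+Basal, +LumB, +Her2, −LumA,
  −Normal) driven by a standardized causal-SNP score (10 subtype-causal SNPs
  by default); proliferation = subtype mean + a second causal-SNP score (10
  prolif-causal SNPs) + N(0,1) noise. The latent ROR-P applies the published
  coefficient pattern to the true subtype indicator and proliferation, so
  the expression-derived score is a noisy measurement of it. The joint
  SNP→subtype→proliferation distribution is not specified by any published
  analysis; this multinomial-logit + additive-proliferation structure is one
  admissible choice and is flagged as such.
* **Heritability calibration**: a single strength multiplier scales both
  genetic scores; because the conditional mean and variance of the latent
  score given genotype are available in closed form from the logit
  probabilities, the multiplier solving
  Var(E[latent|G]) / Var(latent) = h² is found by Brent root-finding. The
  default h² = 0.17 sits mid-range of the reported 13–21% heritability of
  ROR-P. Sample R² at n = 10⁴ recovers the target within ±0.03.
* **Receptor status and grade**: ER+ probability conditional on subtype
  (LumA 0.95, LumB 0.85, Normal 0.70, Her2 0.35, Basal 0.10), shifted on the
  logit scale so the marginal matches the configured ER+ fraction (default
  0.75); HER2+ mostly in the Her2-enriched subtype; grade from a cumulative
  logit increasing in proliferation. The intrinsic-like surrogate from
  markers is LumA = ER+/HER2−/grade 1–2; LumB = ER+ and (HER2+ or grade 3);
  HER2-enriched = ER−/HER2+; Basal = ER−/HER2−.
* **Expression**: true-subtype centroid + N(0, 1) gene noise; proliferation
  genes shifted by the sample's proliferation value; per-study location
  shifts N(0, 0.3) exercising the study indicator; optional probe expansion
  (1..k probes per gene, probe noise 0.3). At these defaults the recomputed
  subtype call agrees with truth for >95% of samples and measured ROR-P
  correlates with the latent score at r ≈ 0.97.
* **Outcomes**: exponential event times with hazard
  λ₀·exp(ln(HR_SD)·z(latent)), administrative censoring at 12 years,
  λ₀ = 0.03/yr — roughly 30% cumulative events, representative of long
  follow-up with a recurrence-inclusive endpoint and chosen at design time,
  by a power analysis of the validation Cox model, so that a true HR of 1.3
  per SD of latent ROR-P is detectable through the built PRS with ~90%
  power at n = 5000. Covariates: PCs are standard Gaussians (plumbing, with
  an optional confounding effect on the latent score, default off — real
  ancestry structure is not simulated); age, BMI Gaussian; stage from a
  cumulative logit mildly increasing in latent ROR-P; treatment flags
  depending on stage and receptor status. These dependencies let the nested
  covariate models show the expected attenuation pattern.
* **Case-case summary statistics** for the comparator score are emitted from
  the same architecture: the ER−/ER+ contrast is proportional to each SNP's
  subtype weight plus estimation noise, so SNPs that push toward aggressive
  subtypes raise relative ER-negative risk.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: realistic LD beyond pairwise partners, population
stratification (PCs carry no ancestry geometry), batch effects beyond
additive study shifts, somatic copy number, non-proportional hazards,
informative censoring, and measurement platforms' probe-level artifacts
beyond additive noise.

## Problem sizes

Defaults mirror the study scale: development cohorts of 2500 tumors
(published development set: 2363) with 226 candidate SNPs, validation
cohorts of 5000 and 2500. The test suite uses smaller cohorts (300–2000)
for unit properties and full-scale runs (n = 10⁴ heritability check,
100-replicate Cox coverage and end-to-end power at n = 5000, 500-replicate
goodness-of-fit calibration) in the acceptance layer.

## Known limitations

* The CV r² on synthetic cohorts (~0.13–0.15) exceeds the published 0.049
  because the generator concentrates all heritability in the candidate set
  and simulates no LD with untyped causal variants; the number is a
  consistency check of the machinery, not a reproduction of the cohort
  value, which requires controlled-access data.
* The REML meta-analysis assumes symmetric Wald CIs on the log scale when
  recovering SEs from printed intervals.
* Perfect separation in feature associations raises an error (penalized
  fits are out of scope), as do competing risks and time-varying effects.
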