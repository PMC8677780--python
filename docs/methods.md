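# Methods

This note documents the statistical model, the synthetic-study generator,
the numerical choices, and what the validation suite does and does not
establish.

## Analysis model

### Score construction

Clumping + thresholding over a harmonised discovery panel:

1. **Hard calls.** Imputed genotype probability triples (p0, p1, p2) are
   converted to 0/1/2 when max(p) ≥ 0.8, otherwise treated as missing. The
   0.8 certainty bar is the conventional cutoff for post-imputation hard
   calls. QC runs after hard-calling, so the missingness filter sees both
   assay missingness and low-certainty imputations (the log records both).
2. **SNP QC.** Exclusions are strict inequalities: MAF < 0.05 or
   missingness > 0.05; boundary values are retained.
3. **Per-SNP N filter.** Discovery rows with n_eff < 0.8 × max(n_eff) are
   dropped (a SNP analysed in a GWAS subsample has a weight on a different
   effective scale).
4. **Harmonisation.** Matching is on rs-id. Swapped alleles flip the weight
   sign; strand-flipped pairs are complemented and re-matched; palindromic
   (A/T, C/G) SNPs are dropped unconditionally — no frequency-based rescue,
   trading a few informative SNPs for determinism. Mismatches are dropped
   and counted.
5. **Clumping.** Greedy in ascending discovery p (ties by chromosome then
   position, which makes the procedure invariant to input order). A SNP is
   absorbed by the most-correlated existing index within 250 kb with
   r² ≥ 0.1, estimated from pairwise-complete target-cohort dosages. The
   defaults are the conventional C+T tool defaults and are overridable.
6. **Scoring.** Threshold inclusion is p ≤ t (inclusive). Missing dosages
   are imputed as 2 × effect-allele frequency of the cohort's non-missing
   genotypes, matching standard scoring tools. The 1,001-point grid is the
   arithmetic sequence 0.0001 + 0.001k (k = 0..999) plus 1.0 — the only
   construction consistent with the stated range, increment and count.

### Per-cohort models

Continuous predictors (PGS, ICV) and the volume outcome are standardized
within cohort (mean 0, SD 1, denominator n−1), so the PGS coefficient reads
as SD-volume per SD-score and is invariant to score rescaling. Age enters
centered, with a centered-age quadratic (numerics only; leaves the PGS
terms unchanged). Sex and any other single-valued covariate is auto-omitted.
Multi-site cohorts get site indicator covariates (mega-analysis within the
cohort). All p-values are two-sided Wald/normal, so per-cohort estimates are
exactly the inputs the inverse-variance meta-analysis assumes; the smallest
cohorts are large enough (n > 140) that the absent t-correction is
immaterial.

Twin cohorts: linear mixed models and GEE are replaced by family-clustered
sandwich covariance (groups = family). For a fixed-effects estimand these
have the same large-sample target; the divergence is efficiency, not
consistency, and outputs are flagged `cluster_robust`. For the per-SNP GWAS
stage, where sandwich covariance per SNP would be costly and the upstream
tooling has no twin support, one member per family is kept instead: the
PTSD case when the family has exactly one, otherwise a seeded uniform pick
(among cases if several). PTSD risk models are logistic with age and sex
only; ICV is deliberately not a covariate there. Complete separation is
flagged and the estimate withheld rather than reported at a boundary.

### Meta-analysis and threshold selection

DerSimonian–Laird moment estimation (closed form, exactly testable):

    w_i  = 1/se_i²,  b_FE = Σw_i b_i / Σw_i,
    Q    = Σw_i (b_i − b_FE)²,
    τ²   = max(0, (Q − (k−1)) / (Σw − Σw²/Σw)),
    w*_i = 1/(se_i² + τ²),  b = Σw*_i b_i / Σw*_i,  se = (Σw*_i)^(−1/2),

with I² = max(0, (Q−(k−1))/Q) and two-sided normal p. The reference R
implementation defaults to REML; DL was chosen for its closed form, and the
two differ only in the τ² estimate. With k = 5 cohorts τ² is noisy; see
Known limitations.

The grid scan pools every threshold and selects the minimum-p threshold
(ties → smaller threshold). Comparisons use |z| so thresholds remain ordered
when p underflows double precision. Local peaks are thresholds at least as
significant as both neighbours; a plateau contributes its smallest
threshold. Follow-up interaction tests run at the top five peaks with a
Bonferroni family of five (0.01); the grid-wide family is 0.05/1001
≈ 5×10⁻⁵. 95% CIs use 1.96 exactly.

### GxE GWAS

Per cohort the model is volume ~ SNP + E + SNP×E + Stage-1 covariates, with
the full Stage-1 covariate set retained (including ICV and site dummies —
the conservative reading of "covariates as in the PGS models"). The scan
residualises the SNP and SNP×E columns against the shared covariate block
(Frisch–Waugh), which reproduces the full per-SNP OLS exactly (asserted
against statsmodels in the tests) while scanning thousands of SNPs in one
pass. Missing dosages are mean-imputed per cohort (2 × EAF, the same rule
as scoring); monomorphic SNPs drop that cohort for that SNP. Meta-exclusion
rules: MAF < 5% in any contributing cohort, or absent from more than two
cohorts. λ = median(χ²₁)/0.4549364 (the 1-df χ² median carried at full
precision; reported values rounded to 2–3 decimals). Independent top hits
come from greedy distance pruning (best p first, 250 kb window) — a
deterministic, self-contained replacement for interactive web-based
independent-SNP selection. Candidate SNPs get Benjamini–Hochberg FDR within
each region's candidate set, q ≤ 0.05. Confounder-sensitivity refits add
G×{age, sex, PCk} and E×{age, sex, PCk} products; terms that make the
design rank-deficient are dropped and reported.

## Synthetic-study generator

The generator is the package's study design, not a tuning surface.

- **Cohorts.** Five cohorts fixed at n = 377 (five-site, mega-analysed),
  143, 169, 6570 (10 PCs, 2.4% PTSD prevalence — control-heavy population
  cohort), 321 (all-male monozygotic-twin pairs); 7,580 subjects total.
  Prevalences, sex ratios and age distributions follow the target design's
  descriptive table.
- **Genotypes.** Latent-Gaussian blocks: per block of 20 SNPs the two
  haplotype latents share exchangeable correlation 0.7 and are thresholded
  at each SNP's allele frequency (drawn U(0.05, 0.5)), giving Hardy–Weinberg
  genotypes with within-block LD and independence across blocks. Blocks are
  2 Mb apart (SNPs 10 kb apart in-block), so clumping windows never span
  blocks. This is deliberately simpler than coalescent simulation — enough
  LD structure for clumping and scoring, trivially parameterised.
- **Imputation noise.** The true genotype class receives probability 1 − d
  with d ~ Exp(0.05) capped at 0.7, the remainder split randomly between
  the other classes; ~2% of genotypes fall below the 0.8 hard-call bar.
  A further 1% are missing completely at random.
- **Discovery GWAS.** Marginal per-SNP effects are the LD-leaked projection
  of the causal weights, computed from an internal reference draw of 4,000
  genotypes (deterministic under the seed), scaled so the true score
  explains 5% of discovery-sample volume variance, plus Wald noise at
  se = 1/(sd(g)√N) with N = 33,536. Ten percent of SNPs are marked as
  analysed on 50–80% of the maximum N to exercise the per-SNP N filter.
- **Phenotypes.** Standardized volume = √h² · S · (1 + δ·PTSD) + 0.3·ICV
  − 0.15·sex − 0.015·(age−50) − 0.0002·(age−50)² + 0.05·(PC1+PC2) + site
  effects + residual scaled to unit total variance. Defaults h² = 0.008
  (control slope ≈ 0.09 SD/SD) and δ = −1 (zero slope in cases) — the
  headline attenuation. PTSD is assigned by a logistic liability on the
  standardized true amygdala score with log-OR ln(1.15), the intercept
  solved for each cohort's prevalence. Childhood trauma is independent
  Bernoulli by default (a coupling knob exists). Twin pairs share genotypes
  (MZ) and have residual correlation 0.5 — the standard additive-genetics
  heuristic, config-overridable. Volumes are emitted in mm³ at realistic
  per-structure locations/scales, left/right constructed symmetrically
  around the bilateral mean. An optional spike SNP adds a case-only
  per-allele volume effect for GWAS power studies.
- **Phenotype-level path.** For calibration and recovery studies of the
  modelling stages, true scores are drawn directly (N(0,1), twin-shared)
  and attached as `pgs_<structure>` columns, skipping the genotype layer.

What the generator does **not** emulate: population structure/admixture
(the design restricts to one ancestry; PCs are pure noise covariates),
realistic recombination maps, imputation-quality gradients along the
genome, PTSD–trauma collinearity (off by default), and genuine between-
cohort effect heterogeneity beyond what prevalence differences induce.
Passing tests therefore show the machinery is correct and calibrated under
the design's assumptions, not that real-data confounding is handled.

## Problem sizes used in validation

Tests and the acceptance script run the full design at a 2,000-SNP panel
(100 causal SNPs), the scale at which the per-SNP GWAS stage is specified;
score-pipeline unit tests use 10–400 SNP panels. Calibration uses 1,000
null replicates (n = 1,000) for the interaction type-I error and a
3×1,000-subject null GWAS for λ; recovery uses 200 phenotype-level
replicates of the full 7,580-subject design and 50 genotype-level
replicates (3×2,000 subjects) for the spike study.

## Known limitations

- **DL p-values with few homogeneous cohorts are conservative.** Feeding
  exact N(0,1) estimates into the DL machinery yields genomic λ ≈ 0.78
  (k=3) to 0.81 (k=5): τ² estimation noise inflates the pooled SE exactly
  when estimates disagree by chance. Per-cohort scan p-values are
  calibrated (λ ≈ 1), and fixed-effects pooling would be too. The null-GWAS
  λ∈[0.9, 1.1] check therefore fails under the prescribed random-effects
  pooling — a property of the estimator, not an implementation defect.
- **Recovery power sits at the design's information limit.** With 670
  cases among 7,580 subjects, the pooled PGS×PTSD interaction SE has a
  fixed-effects floor near 0.054 (DL ≈ 0.060), so a planted −0.089
  interaction is negative in ~93% of replicates, and the pooled PTSD
  odds ratio lands in [1.05, 1.25] around a true 1.15 in ~85–89%. The
  corresponding acceptance checks assert 95%/90% and are expected to fail
  by those margins; they are kept as stated rather than widened.
- The fitted (noisy-weight) PGS attenuates all score-level effects by its
  correlation with the true score (~0.7–0.75 at the default discovery
  power), so end-to-end pipeline estimates are smaller than the planted
  score-level values — as they would be with real discovery GWAS weights.
- Best-threshold selection maximises significance and therefore inherits
  winner's-curse optimism; downstream stages reuse the selected threshold,
  matching the target procedure, and no correction is applied beyond the
  grid-wide Bonferroni annotation.
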