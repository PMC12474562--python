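# Methods

This note documents the models, estimators, and design choices behind
`salrun`, the defaults that matter, and what the synthetic-data generator
does and does not emulate.

## Run-timing descriptors

Daily counts are pooled across years and across the small/large size
classes (their seasonal patterns are parallel, so pooling only adds power).
The percentile descriptor is the **smallest day of year at which the
cumulative count fraction reaches q**, with no interpolation: counts are
integers per day and the descriptors are integer days. *early* is q = 0.05,
*late* q = 0.95, the yearly median q = 0.5 within each year.

Standard errors for *early*/*late* are a nonparametric bootstrap over years
(default 1,000 resamples, seeded): years are the natural exchangeable unit,
and the estimator is otherwise a deterministic function of the pooled
counts. With a single contributing year the SE is reported as NaN. Years
with zero total count are dropped per population with a logged warning.

Trends are fitted by OLS of `median_doy ~ Year * Site` with Type II
sums-of-squares ANOVA for the Year × Site interaction (the default of the
usual R ANOVA implementation for this design). Per-population slopes and
p-values come from linear contrasts of the full model
(slope_p = β_year + β_{year:pop}); these slopes are identical to independent
per-population fits, but their standard errors pool the residual variance.
The latitude correlation is Pearson's r between slopes and site latitude.

Modality is classified algorithmically (the trait is visual in field
practice): the mean daily count curve is smoothed with a Gaussian kernel
(bandwidth 7 days) and local maxima with prominence ≥ 20% of the global
maximum count as peaks; two or more peaks → "multiple". Both thresholds are
arguments.

## Genotypes, QC, diversity

Dosages are 0/1/2 alternate-allele counts with NaN for missing; the raw
matrix keeps missingness, and mean imputation happens only inside
PCA/RDA/LFMM. The MAF filter is inclusive (MAF ≥ cutoff), matching the
common PLINK semantics. LD pruning is greedy within windows of 50 SNPs
sliding by 5: while any retained pair in the window has r² above 0.5, the
lower-MAF member is removed (ties → larger position). The victim rule is
stated explicitly because tool internals differ; the contract is the
post-condition (no retained within-window pair above the threshold), which
is tested exhaustively.

FST is the Weir & Cockerham (1984) variance-component estimator θ computed
per SNP from population sample sizes, allele frequencies, and observed
heterozygote proportions; the multi-SNP average is the ratio of sums
Σa / Σ(a+b+c). SNPs monomorphic across all populations are excluded from
the average. Nucleotide diversity is the small-sample-corrected expected
heterozygosity 2p̂(1−p̂)·n/(n−1) with n the non-missing diploid count.

## Structure

PCA standardizes SNP columns (zero-variance SNPs dropped) and takes a
truncated SVD; scores are U·S and explained variance the singular-value
share of the total. Each axis is oriented so its first nonzero loading is
positive (a reproducibility convention only). Three PCs are used for
structure conditioning downstream; the number is an argument.

Ancestry estimation is a masked nonnegative factorization of the individual
allele-frequency matrix F = dosage/2 ≈ Q·G with Q rows on the probability
simplex and G in [0,1]: alternating masked least squares with simplex
projection for Q and clipping for G, stopping when the training objective
stops decreasing (the iterate before any projection-induced increase is
kept, so the objective path is non-increasing by construction). Model
choice uses the binomial cross-entropy of held-out entries (default 5%)
predicted by Q·G. Because the absolute cross-entropy sits on a large
irreducible binomial-noise floor, the elbow rule operates on the **decline**:
the chosen K is the first at which the improvement to K+1 falls below 2% of
the total decline over the K range.

## Association

Phenotypes are population-level: every fish carries its population's
*early*/*late* percentile day or the binary modality label. All association
is therefore at the population scale — individual-level significance
overstates the effective sample size, which is why both methods are
calibrated (permutation for pRDA, genomic-inflation rescaling for LFMM)
rather than read off parametric references.

**pRDA.** Genotypes (centered, scaled by default) and the trait are
residualized on the conditioning block (intercept + structure PCs); the
fitted matrix of the residual regression has exactly one constrained axis
for a single trait, and per-SNP scores are the axis loadings (proportional
to per-SNP trait covariance when unconditioned). Candidates are the top
ceil(f·p) by |score| (f = 0.01), ties broken toward the lower marker index
— this count rule reproduces 1,413 candidates from 141,263 markers. The
permutation test permutes the residualized trait and uses
p = (1 + #{perm ≥ obs})/(1 + nperm), bounded below by 1/(nperm+1).

**LFMM.** The ridge latent factor model
min ||Y − W − x bᵀ||² + λ||b||², W of rank K, has a closed-form solution:
with P the projection onto the trait direction and
D = (I − P) + √(λ/(λ + xᵀx))·P, the optimal latent term is
W = D⁻¹·SVD_K(D·Y) and b the ridge regression of Y − W on x. We use this
exact solution rather than alternating updates: the alternation has
multiple fixed points (initializing effects at zero lets the factors absorb
trait-aligned genetic variation; initializing at the marginal effects
leaves structure in them), while the closed form is the optimum the
alternation is meant to find. Defaults: K = 3, λ = 1e−5. z-scores are
b/SE; z² is divided by the genomic inflation factor median(z²)/0.4549
(the χ²₁ median) before the normal reference; q-values are
Benjamini–Hochberg; candidates are q < 0.05. K = 0 reduces to ordinary
per-SNP regression (and is tested against it).

Gene-level support intersects the genes hit by pRDA candidates with those
hit by LFMM candidates; gene sets are deduplicated per gene.

## Annotation

Coordinates are 1-based inclusive internally; BED input is converted on
read. A SNP annotates to every gene within 50 kb (inclusive at exactly
50,000 bp; "within" is read inclusively), distance 0 inside the gene.
Strand is carried but ignored for distance — the window is symmetric.
The interval-tree implementation is contractually identical to a brute-force
distance scan, and is tested against one.

## Genomic offset

Sites are populations — an intentionally small-n regime (11 sites at study
scale). Climate enters as 19 bioclim-style variables standardized by the
present-day mean/sd; future tables are projected onto the present-day PCA
axes. The trait → offset gate correlates pRDA axis-1 loadings with
climate-RDA axis-1 loadings over shared loci (Pearson when both vectors
pass Shapiro–Wilk at 0.05, Spearman otherwise) at the Bonferroni threshold
0.05/3 ≈ 0.0167 for the three traits.

Predictors are decorrelated before the forest: while any pair has |r| >
0.7, the lower-importance member is dropped, importance coming from a
preliminary forest on all variables (variables with no importance at all
count as zero).

Each locus gets a random forest of 500 regression trees on per-population
allele frequencies (bootstrap rows, mtry = ⌈p/3⌉, minimum leaf 2). The
per-locus cross-validated R² is the out-of-bag 1 − MSE/Var; loci with
R² ≤ 0 are dropped. Per-predictor weight within a locus is **out-of-bag
permutation importance** — train-set permutation importance would credit
noise predictors that deep trees memorize, and with mtry = ⌈p/3⌉ forced
noise splits would otherwise dilute attribution. Split impurity reductions,
located at each split's threshold, provide the *shape* of the turnover
function along each predictor's gradient; masses are weighted by locus R²
and predictor importance share, and normalized so the total rise across
predictors is 1 (each turnover function's total rise is its predictor's
importance share). Density standardization of split positions is not
applied by default. Evaluation outside the training range clamps to the
function endpoints and logs a warning (turnover is undefined in novel
climates).

The genomic offset per site is the Euclidean distance between
turnover-transformed present and future climate; it is zero when future
equals present, symmetric, and a metric in the transformed space. The
environmental offset is the Euclidean distance between present and future
positions in climate PC1–2. The multi-run protocol fits three
independently seeded forests; if their top-ranked predictor agrees, the
first run's offsets are reported, otherwise ten runs are fitted and the
modal top predictor and mean offsets reported.

The Wilcoxon rank-sum comparison of R² distributions uses exact tie-aware
enumeration when both samples have n ≤ 10 and the tie-corrected normal
approximation otherwise.

## Synthetic data

The generator reproduces the statistical structure the pipeline assumes,
not the biology of any river:

- **Genotypes**: a two-level Balding–Nichols F-model. Ancestral frequencies
  ~ U(0.05, 0.95); regional frequencies are Beta draws with variance
  F_between·p(1−p) around the ancestral value; population frequencies Beta
  draws with F_within around the regional value; genotypes Binomial(2, p).
  Defaults: 11 populations in regions of 4/5/2 (mirroring the
  Maritimes/Newfoundland/Labrador design), 27 fish per population (297),
  5,000 SNPs. F_between = 0.08 and F_within = 0.02 were chosen as realistic
  for regional salmon structure and put single-digit percentages of
  variance on the leading PCs, as observed in such data.
- **Trait axis**: each population's run-timing identity is a standardized
  latitude gradient plus a seeded river-specific deviation (sd 0.6 in
  latitude-z units). Real rivers deviate from the pure latitudinal cline
  (local thermal regimes), and this deviation is what leaves recoverable
  signal after structure correction — with a pure latitude cline the trait
  would be collinear with regional structure and conditioning would remove
  essentially all of it.
- **Planted loci**: 50 loci per trait receive a deterministic logit-scale
  cline of slope ±1 (the `effect_size`) against the standardized
  closed-form expected phenotype of their trait (the 5%/95% quantiles of
  the count model, or the binary modality label), so planted loci are
  associated with exactly the quantity the pipeline later measures from the
  realized counts (realized and expected phenotypes correlate > 0.99).
  Frequencies leaving (0,1) after the cline are clamped to [0.01, 0.99]
  with a warning. Because the three trait phenotypes are mutually
  correlated (as in real data), loci planted for one trait are genuinely
  associated with the others; recovery tests therefore count a discovery as
  a false positive only if it carries no planted cline at all, while power
  is scored against the tested trait's own locus set.
- **Climate**: temperature-like variables (BIO1/5/6/7/10/11) decrease with
  the latitude+river axis plus noise (colder in the north); three
  variables are built as near-copies of a partner (|r| > 0.7) to exercise
  decorrelation; the rest are noise. The future table applies a warming
  shift amplified toward the north (zero at the southernmost site) — cold
  northern sites move up *through* the observed climate range, which is
  what makes offsets respond to displacement rather than saturating at the
  range edge.
- **Counts**: Poisson draws around one Gaussian seasonal peak (sd 12 days)
  or a 0.55/0.45 mixture 50 days apart for bimodal populations (the
  lowest-latitude region is bimodal, as in the Maritimes), mean run date
  170 + 12·axis, per-year jitter sd 3 days, optional planted linear
  advance in days/year, over 28 years.
- **LD**: none, except an optional block-copy of neighboring SNPs for
  pruning tests. No coalescent realism, no realistic LD decay, no
  missingness by default, no genotyping error. Passing recovery tests on
  these data shows the estimators behave as designed under the assumed
  structure; it does not validate performance under real LD, ascertainment,
  or sampling noise.

All generators are pure functions of the seeded config; identical seeds
give identical outputs.

## Numerical choices and degenerate inputs

- Percentile descriptors error on zero total count; trend fitting requires
  ≥ 2 populations × ≥ 3 years and raises on rank-deficient designs.
- PCA requires a non-constant matrix; monomorphic SNPs give NaN r² and are
  excluded from FST averages; nucleotide diversity needs n ≥ 2.
- The permutation p-value can never be 0; with nperm = 1 it is 0.5 or 1.
- Gradient forests require ≥ 5 sites and error below that; monomorphic
  loci across sites are assigned R² = −inf and never retained.
- Problem sizes in tests and in the acceptance script (hundreds of SNPs for
  module tests, the full 297 × 5,000 default for recovery studies, 200–300
  trees where the full 500 adds only runtime) were chosen to keep the whole
  suite fast on a single core while leaving every statistical conclusion
  unchanged at the default study scale.

## Known limitations

- Population-level phenotypes mean all association is at the population
  scale; with 11 populations the effective sample size is small and
  residual drift beyond K latent factors produces genuine false positives
  at nominal thresholds — the GIF calibration controls the bulk, not the
  tail.
- Turnover functions are undefined outside the training climate range and
  are clamped there; offsets for strongly novel climates are lower bounds.
- The masked-NMF ancestry model is a generic factorization, not a
  population-genetic likelihood; its K selection is a heuristic elbow.
- The count model has no trap-efficiency correction and no within-year
  environmental covariates (flow, temperature).
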