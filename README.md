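# salrun

Population-level run-timing genomics for Atlantic salmon (*Salmo salar*).

Adult Atlantic salmon return from the sea to their natal rivers on schedules
that differ among populations and are shifting under climate change. `salrun`
implements, as a tested and reusable pipeline, the population-level analysis
of that migration phenology and its genetic basis: run-timing descriptors
from daily fishway/trap counts, structure-aware genome-wide association of
those descriptors with SNP genotypes, gene-window annotation of candidate
loci, and trait-specific **genomic offset** — the predicted allele-frequency
displacement needed to track projected climate — via gradient-forest
turnover functions. It is intended for salmonid conservation-genomics
practitioners and for anyone who wants a transparent, scriptable version of
this class of analysis with a synthetic-data generator that makes every
stage runnable (and testable) at desk scale.

## What it computes

**Run-timing descriptors.** From daily counts pooled over years and size
classes, *early* and *late* run timing are the days of year at which the
cumulative count fraction reaches 0.05 and 0.95; the yearly median (50%) day
feeds a `median_doy ~ Year × Site` regression whose interaction term tests
whether multi-year timing trends differ among rivers. *Modality*
(single vs. multiple seasonal peaks) is classified from the smoothed mean
daily count curve by peak prominence.

**Association.** Each fish carries its population's trait value. Partial
redundancy analysis (pRDA) residualizes genotypes **Y** (n × p, centered and
scaled, mean-imputed) and the trait x on the first three structure PCs, then
scores each SNP by its loading on the single constrained axis of the fitted
matrix; candidates are the top 1% of |scores| (ceil(0.01·p); 141,263 markers
→ 1,413 candidates). Overall significance comes from residual permutation
(p = (1 + #{perm ≥ obs})/(1 + nperm)). The ridge latent factor mixed model
(LFMM) solves

    min_{W rank K, b} ||Y − W − x bᵀ||² + λ||b||²

by its exact closed form, calibrates z² by the genomic inflation factor
(median z²/0.4549), and selects q < 0.05 after Benjamini–Hochberg.

**Genomic offset.** Populations are sites. A random forest (500 regression
trees, mtry = ⌈p/3⌉) models each candidate locus's allele frequency as a
function of bioclim-style climate predictors (decorrelated at |r| > 0.7);
loci with out-of-bag R² > 0 are retained, and split-point impurity
reductions — weighted by OOB permutation importance and per-locus R² —
accumulate into monotone per-predictor turnover functions F_v. The genomic
offset of a site is the Euclidean distance ‖F(climate_future) −
F(climate_present)‖ across predictors; the environmental offset is the same
distance in raw climate PC1–2 space. Offsets are computed only for traits
whose pRDA axis-1 loadings correlate with the climate-RDA loadings at the
Bonferroni level p < 0.05/3 ≈ 0.0167.

**Diversity context.** Weir–Cockerham FST (per SNP and ratio-of-sums
average), observed heterozygosity, and per-SNP nucleotide diversity.

## Worked example

```python
import numpy as np
from salrun import sim, runtiming, structure, association

cfg = sim.SimConfig(seed=7)          # 11 pops / 3 regions, 297 fish, 5000 SNPs
g, truth = sim.simulate_genotypes(cfg)
counts = sim.simulate_counts(cfg, truth.modality_labels)

s = runtiming.summarize_population(counts, "POP01", n_boot=200, seed=7)
print(s.early_doy, s.late_doy, s.modality)

pheno = sim.population_phenotypes(cfg, counts, truth)
y = sim.individual_phenotypes(g, pheno, "late")
pcs = structure.run_pca(g, n_pcs=3)
res = association.partial_rda(g, y, condition=pcs.scores)
lf = association.lfmm_ridge(g, y, K=3)
```

This prints, for the southernmost (bimodal) population and the late-run
trait:

```
POP01: early DOY 114 +/- 0.74, late DOY 196 +/- 0.77, modality multiple (28 years)
PC variance fractions: [0.064 0.042 0.008]
pRDA: 50 candidates (perm p = 0.001), 3 of 50 planted late-run loci recovered
LFMM: 66 candidates at q < 0.05 (GIF 3.08), 44 of 50 planted loci recovered
```

Population POP01 starts its run on day 114 and finishes 95% of it by day
196, with two seasonal peaks; the first three PCs carry ~11% of genotypic
variance (the three regional clusters). The pRDA is significant overall
(smallest attainable permutation p at 999 permutations), and the LFMM
recovers 44 of the 50 loci carrying a planted late-run cline. The
structure-conditioned pRDA recovers few planted loci here — the trait cline
is partly collinear with regional structure, so conditioning removes much of
the signal, which is exactly the behavior the structure-corrected /
uncorrected contrast in the offset stage quantifies.

The same stages are available from a shell:

```
salrun simulate --config config.yaml --out data/ --seed 1
salrun runtiming --counts data/counts.tsv --out out/ --bootstrap 1000 --seed 1
salrun qc --vcf data/genotypes.vcf --popmap data/popmap.tsv --maf 0.01 --prune 50,5,0.5 --out out/
salrun structure --vcf ... --k-range 1..11 --npcs 3 --seed 1 --out out/
salrun gwa --vcf ... --trait late --condition npcs=3 --nperm 999 --out out/
salrun annotate --candidates out/candidates_late.bed --genes data/genes.bed --window 50000 --out out/
salrun offset --freqs out/freqs.tsv --climate data/climate.tsv --trees 500 --out out/
salrun all --out out/ --seed 1
```

## Layout

- `src/salrun/sim.py` — synthetic genotypes (two-level Balding–Nichols
  F-model with planted climate clines), climate tables, daily count series
- `src/salrun/runtiming.py` — percentile descriptors, trends, modality
- `src/salrun/genotypes.py` — VCF/dosage I/O, MAF filter, LD pruning,
  FST/diversity
- `src/salrun/structure.py` — PCA, componentwise loadings, masked-NMF
  ancestry with cross-entropy K selection
- `src/salrun/association.py` — pRDA, permutation test, ridge LFMM, BH-FDR
- `src/salrun/annotation.py` — GFF3/BED readers, windowed closest-gene search
- `src/salrun/offset.py` — climate PCA, GEA, correlation gate, gradient
  forest, offsets
- `src/salrun/pipeline.py`, `src/salrun/cli.py` — orchestration and CLI

See `docs/methods.md` for the model assumptions, parameter defaults, and
known limitations.
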