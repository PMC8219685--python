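# rgwas — outlier-robust linear mixed model GWAS

Mixed-model association studies of quantitative traits are the
standard defence against population stratification and polygenic
relatedness, but their REML variance components and F tests are
fragile: a handful of grossly aberrant phenotype records (assay
failures, unit mix-ups) inflate the error variance and can erase real
associations genome-wide.  `rgwas` robustifies the scan for exactly
this failure mode.  It is written for statistical geneticists and
breeders analysing structured panels (diversity collections, inbred
line panels) whose traits are multimodal across genotype classes.

## The method

For the linear mixed model

&nbsp;&nbsp;&nbsp;&nbsp;**y** = **X a** + **Z b** + **ε**,&nbsp;&nbsp;
**b** ~ N(0, σ²_g **K**),&nbsp; **ε** ~ N(0, σ²_ε **I**)

with the allele-frequency-standardised kinship **K**, `rgwas` inserts
a repair step before the scan:

1. pick the top trait-associated SNP by a robust one-way ANOVA whose
   group moments are minimum β-divergence estimates (the fixed point
   of the β-weighted mean and variance);
2. partition the trait by that SNP's dosage groups 0/1/2;
3. score every observation with the β-weight
   W_β(y) = exp(−β (y − μ̂_l)² / (2 σ̂²_l)) and flag those whose weight
   falls at or below the group's empirical weight quantile *and* below
   an absolute ceiling;
4. replace flagged values with the group's robust mean μ̂_{l,β}
   (everything else stays bit-identical);
5. run the EMMA-style LMM scan (REML by spectral decomposition, GLS
   F tests) on the repaired trait.

At β = 0 every estimator reduces exactly to its classical ML
counterpart, so the robust machinery nests the standard analysis.
Because outliers are *replaced within genotype groups* rather than
removed (7σ rule) or globally rank-normalised (INT), the sample size
and the group signal both survive — the source of the method's power
advantage under contamination.  See `docs/methods.md` for the full
model, parameter table, simulator and evaluation details.

## Worked example

```bash
python examples/01_robustify_phenotype.py
```

```
grouping SNP selected by robust ANOVA: column 14 (causal columns: [9, 14, 36, 92])
injected outliers: 25; flagged: 25; recovered: 25
variance  clean 1.000  contaminated 4.403  repaired 0.965
```

A 500-individual, 3-subpopulation dataset is simulated with 5% of
trait values replaced by extreme outliers (2–5× the trait maximum).
The robust ANOVA picks a genuinely causal SNP to define the groups,
the β-weight rule recovers all 25 injected outliers with no false
flags, and replacing them by group robust means returns the trait
variance from 4.40 to 0.97 — essentially the clean value of 1.0, so
downstream variance components are estimated as if the contamination
never happened.

The other examples cover the association scan and its comparators
(`02`), a small replicated power/FDR experiment (`03` — the plain
LMM's power falls from 52.5% to 17.5% as contamination rises from 0 to
5%, while the robustified scan only drifts from 50% to 45%), and a
file-based preprocessing pipeline with kNN imputation and LD pruning
(`04`).

A thin CLI wraps the same functions:

```bash
rgwas simulate --n 1000 --snps 2000 --h2-main 0.2 --contaminate 0.05 --seed 7 --out-prefix sim_
rgwas robustify --genotypes sim_genotypes.csv --phenotype sim_phenotype.tsv --out repaired.tsv --report outliers.tsv
rgwas run --method rgwas --genotypes sim_genotypes.csv --phenotype sim_phenotype.tsv --fast --out results.tsv
rgwas evaluate --h2 0.2 --rates 0 0.05 --reps 100 --out grid.tsv
```

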