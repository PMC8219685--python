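# Methods

`rgwas` implements an outlier-robust variant of mixed-model genome-wide
association analysis for quantitative traits, together with the
structured-population simulator and the power/false-discovery
evaluation used to characterise it.

## The problem

The linear mixed model (LMM) is the standard answer to the two
confounders of GWAS in structured panels — population stratification
and polygenic relatedness:

    y = X a + Z b + e,    b ~ N(0, sigma_g^2 K),   e ~ N(0, sigma_e^2 I)

with K the genomic relationship matrix

    k_jt = (1/T) sum_i (x_ij - 2 f_i)(x_it - 2 f_i) / (2 f_i (1 - f_i)).

Both variance components are estimated by REML, and every SNP is tested
by the generalised-least-squares F statistic on its dosage coefficient
(1 and n − q degrees of freedom).  REML and the F test are
likelihood-based and therefore fragile: a handful of grossly aberrant
phenotype records (assay failures, transcription errors, unit mix-ups)
inflate sigma_e^2, deflate every noncentrality, and can erase real
associations genome-wide.

## The robustification

A quantitative trait viewed across a strongly associated SNP is
*multimodal* — one mode per dosage group 0/1/2 — so global unimodal
outlier rules (trimming at k·SD, global rank transforms) either miss
group-level outliers or distort clean group structure.  The repair
implemented here is local to genotype groups:

1. **Group selection.** The top-ranking SNP is found by a robust
   one-way ANOVA: per SNP and per dosage group, location and scale are
   estimated by the minimum beta-divergence (density-power) method,
   and the statistic

       F_beta = [sum_l n_l (mu_l − mu_bar)^2 / (g − 1)] /
                [sum_l n_l sigma2_l / (N − g)]

   is maximised over SNPs (ties to the lowest column index).  Because
   the beta = 0 scale estimate is the ML variance SS_l/n_l, the n_l
   weighting makes F_0 *exactly* the classical one-way ANOVA F — the
   reduction property that anchors the robust statistic.
2. **Per-group estimation.**  Within each group the estimators solve
   the fixed point of the weighted mean and weighted variance with
   weights

       W_beta(y) = exp(−beta (y − mu)^2 / (2 sigma^2)),

   the variance update carrying a (beta + 1) factor so that beta = 0
   reduces to the Gaussian MLEs.  Outlying points get exponentially
   small weight and therefore do not perturb the fit.
3. **Detection.**  A point is declared an outlier iff its weight is
   ≤ tau_l, the `outlier_quantile` empirical quantile of its group's
   weights, *and* below an absolute ceiling (default 0.2 ≈ a 4-sigma
   deviation at beta = 0.2).  The quantile caps how much of a group
   can ever be modified; the ceiling makes clean groups yield
   (essentially) zero outliers, where a pure quantile rule would
   always flag a fixed fraction.
4. **Modification.**  Flagged values are replaced by their group's
   robust mean; everything else is returned bit-identical.  The
   repaired trait then goes through the ordinary LMM scan.

Replacing (rather than deleting) outliers preserves the sample size —
the reason the method outperforms k-sigma removal — and because the
replacement is the *group* mean rather than a global centre, the
genotype–phenotype signal at the grouping SNP survives, unlike under a
global inverse-normal transform.

### Tuning parameters

| parameter | default | meaning |
|---|---|---|
| `beta` | 0.2 | divergence tuning; 0 = classical ML, larger = more aggressive downweighting |
| `outlier_quantile` | 0.1 | per-group weight quantile for tau_l; bounds the modifiable fraction |
| `weight_ceiling` | 0.2 | absolute weight ceiling; keeps clean groups untouched |
| `tol`, `max_iter` | 1e-8, 100 | fixed-point convergence control |
| `min_group_size` | 3 | groups smaller than this are skipped |

`beta = 0.2` follows the standard recommendation for this weight
family; selecting beta by cross-validation is out of scope and the
parameter is exposed instead.  The `outlier_quantile` default of 0.1
is an upper bound on the contamination fractions the method targets
(up to 5%): with the AND-rule above, the quantile must sit *above* the
contaminated fraction or the threshold lands inside the outlier mass
and caps recall at the quantile itself; 0.1 leaves headroom at 5%
contamination while the ceiling still protects clean data.

### Numerical notes

* Fixed-point iteration is initialised at robust starting values
  (median and squared scaled MAD in the scalar path; per-group order
  statistics — median and IQR/1.349 squared — read off a single sort
  in the all-SNPs vectorised path used by the robust ANOVA).  Both
  paths converge to the same fixed point (asserted in tests); the
  robust start avoids the contaminated basin that a mean/variance
  start can fall into under heavy outliers.
* Degenerate groups (all values identical) raise; groups whose IQR is
  zero fall back to the classical variance for initialisation.
* Columns whose three group fits have all moved less than `tol` drop
  out of the vectorised iteration (pure performance; results
  unchanged).

## REML and the association scan

The restricted likelihood is profiled on delta = sigma_e^2/sigma_g^2
using one eigendecomposition of Z K Z′ per dataset:

    -2 LL_R(delta) = (n−q)(log 2π σ̂²_R + 1) + log|H| + log|X'H⁻¹X| − log|X'X|,

with H = Z K Z′ + delta I and σ̂²_R = R/(n−q) from the rotated weighted
regression.  This is algebraically identical to the classic
formulation on the n−q eigenvalues of the doubly-projected kinship
(asserted against that independent form in the tests) but needs no
per-phenotype eigendecomposition.  delta is maximised on a 100-point
log grid over [1e-5, 1e5] with Brent refinement in the best bracket;
a boundary hit is flagged.  sigma_g^2 = R/(n−q) (REML) or R/n (ML
variant).

Two scan modes: `exact` re-estimates delta under each SNP's
alternative model (vectorised grid over SNPs + per-SNP Brent);
`fast` reuses the null-model delta for every SNP (the EMMAX-style
approximation).  On clean simulated data the two agree within 0.5 on
−log10 p for ≥95% of SNPs and give identical power in the replication
grids, so the grids and the acceptance script use `fast`.

Kinship uses SNPs whose counted-allele frequency lies in (0.01, 0.5];
monomorphic SNPs never contribute but are still tested (p = 1 with a
flag for truly monomorphic columns).  Missing dosages are mean-imputed
inside the kinship cross-products only.

## The simulator

The generator emulates a stratified diversity panel:

* **Genotypes.**  n individuals split near-equally into `n_pops`
  subpopulations.  Per individual an AR(1) latent Gaussian path over
  the m SNPs (correlation rho^|j−k|, rho = 0.5) is thresholded at the
  population's (s1, s2), chosen so Hardy–Weinberg dosage probabilities
  match the population's target allele frequency (defaults 0.15 /
  0.30 / 0.45 — moderately differentiated subpopulations).  The AR(1)
  construction is O(m) per individual.
* **Phenotype.**  Four causal SNPs (drawn among MAF > 0.1) with
  standard-normal raw effects, a polygenic background over all
  remaining SNPs, and Gaussian noise.  The three component vectors are
  centred, Gram–Schmidt-orthogonalised (polygenic against main, error
  against both) and rescaled so the realized variance shares equal the
  design values *exactly* (20/40/40 or 30/40/30).  The realized
  component vectors are stored, and the variance-partition diagnostic
  uses them, so the decomposition sums to 100% by construction.
* **Contamination.**  round(rate·n) positions are replaced by draws
  satisfying 2 max(y) < y* < 5 max(y).  Within that constraint the
  default draw is uniform on (2 max, 2.5 max): the reference
  variance-partition results imply a realized outlier second moment of
  about 4·max², i.e. outliers near the lower admissible edge, whereas
  a full-band uniform draw would inflate total variance by ~8x at 5%
  contamination — far harsher than the behaviour the method is
  characterised against.  The band is configurable.

What the simulator does *not* emulate: realistic LD maps beyond the
short-range AR decay, genotyping error, minor-allele count sampling
noise shared across populations, relatedness/family structure within
populations (individuals are exchangeable draws), or missing data
(tests inject missingness explicitly where needed).  Passing tests
therefore demonstrate the statistical mechanics of the method, not
its behaviour on any particular real panel.

## Evaluation

Power = 100·P_T/P_C and FDR = 100·P_F/(P_T+P_F) (0 when nothing is
detected), averaged over replicates; a SNP is declared at p < 1e-5
with no multiplicity correction.  Declarations are scored with a
±3-column LD window: under rho = 0.5 the immediate neighbours of a
strong causal SNP carry dosage r² ≈ 0.1 and are regularly significant,
so an exact-column rule would book the same tagged signal as a false
discovery (and pushes mixed-model FDR to ~10% where the true
false-signal rate is near zero).  Beyond lag 3 the latent correlation
is ≤ 0.125 and dosage r² < 0.01, effectively no LD; window = 0
restores exact matching.

Per replicate one clean dataset is simulated per heritability; the
same clean phenotype is contaminated at every requested rate, so rates
differ only in their injected outliers.  Replicate streams are spawned
deterministically from (master seed, heritability, replicate); the
grids default to 100 replications, with kinship and its
eigendecomposition shared across all scans of a replicate.

The default grid scale is the study design (n = 1000, m = 2000); the
test suite runs its shared grid at n = 500, m = 1000 so the whole
suite stays fast, and `scripts/acceptance.py` runs the full scale.

### Known limitation: mixed-model power under this generating design

With polygenic effects placed on every one of ~2n SNPs, the fitted
covariance sigma_g²K + sigma_e²I carries genuine polygenic variance
along *every* SNP direction (the effective SNP count is further
reduced ~3x by the AR(0.5) correlation).  Any correctly computed GLS
then pays a noncentrality shrinkage on the tested SNP itself — we
measure x'V⁻¹x ≈ 0.36·x'x/sigma_e² at this n/m ratio (0.45 even with
the true variance components, 0.49 with the tested SNP left out of K).
Clean-data mixed-model power is therefore structurally lower here than
the shrinkage-free noncentrality n·s_k/sigma_e² would suggest, while
per-SNP regression (which absorbs nothing) is unaffected.  The effect
shrinks as m/n grows, as real panels (tens of thousands of SNPs per
thousand lines) do; leave-one-chromosome-out kinship would remove the
proximal part but is deliberately not applied, to keep the kinship
definition exactly as stated above.

## Baselines

* **7-sigma rule**: remove observations outside mean ± 7 SD of the
  full (possibly contaminated) vector, single pass, naive moments —
  the rule as conventionally applied.  At 5% contamination the
  inflated SD usually swallows the outliers and the rule barely fires.
* **Inverse-normal transform**: rank-based mapping onto N(0, 1)
  quantiles with the Blom offset 3/8 (configurable), average ranks for
  ties; order- and n-preserving.

Both feed the same LMM scan.  After 7-sigma removal the kinship matrix
is row/column-subset from the full-data matrix (per-SNP frequencies
from the full sample) rather than recomputed.

## Design choices that were genuinely open

* Convergence constants (tol 1e-8, 100 iterations), the delta grid
  (100 log-spaced points with Brent refinement), and the p-quantile
  implementation (`numpy.quantile`, linear interpolation).
* The robust ANOVA within-group weighting (n_l, dictated by the
  beta = 0 reduction; see above).
* One repair pass: the top SNP is selected once, not re-selected after
  modification (repair is idempotent under the default configuration).
* kNN genotype imputation distance: mean squared dosage difference
  over pairwise-complete SNPs, 1/d weighting, rounded to legal codes;
  zero-distance neighbours (duplicates) dominate.  Meaningful only
  when the panel contains relatives/near-duplicates.
* LD pruning: greedy left-to-right, 200-variant windows advanced by
  50, drop the later of any pair with r² > 0.9; used for the kinship
  SNP set only.
* FDR of an empty detection set is 0.
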