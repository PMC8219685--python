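"""Repair phenotypic outliers group-wise with the beta-weight rule.

Simulates a small structured dataset, injects 5% extreme outliers,
and shows how the minimum beta-divergence step finds and replaces
them without touching clean observations.
"""

import numpy as np

from rgwas import SimDesign, robustify_phenotype, simulate_dataset

ds = simulate_dataset(SimDesign(n=500, m_snps=200, contamination_rate=0.05),
                      seed=42)
y_obs = ds.phenotype_observed.values
y_clean = ds.phenotype_clean.values

y_mod, report = robustify_phenotype(y_obs, ds.genotypes.dosages)

truth = np.flatnonzero(ds.contamination_mask)
hit = np.isin(truth, report.outlier_indices).sum()
print(f"grouping SNP selected by robust ANOVA: column {report.selected_snp} "
      f"(causal columns: {ds.causal_indices.tolist()})")
print(f"injected outliers: {truth.size}; flagged: {report.n_outliers}; "
      f"recovered: {hit}")
print(f"variance  clean {y_clean.var():.3f}  contaminated {y_obs.var():.3f}  "
      f"repaired {y_mod.var():.3f}")
# The repaired variance returns to the clean level because each outlier
# is replaced by the robust mean of its genotype group; clean values
# are untouched (bit-identical).
untouched = np.setdiff1d(np.arange(y_obs.size), report.outlier_indices)
assert (y_mod[untouched] == y_obs[untouched]).all()
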