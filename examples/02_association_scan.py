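"""Mixed-model association scan, with and without robustification.

Builds one contaminated dataset, computes the kinship matrix, and
compares three scans at the 1e-5 cutoff: plain linear regression,
the LMM, and the LMM after beta-divergence phenotype repair.
"""

import numpy as np

from rgwas import (SimDesign, compute_kinship, lmm_association_scan,
                   lrm_association_scan, robustify_phenotype,
                   simulate_dataset)
from rgwas.io import export_qq_manhattan

ds = simulate_dataset(SimDesign(n=600, m_snps=500, h2_main=0.3,
                                contamination_rate=0.05), seed=7)
y = ds.phenotype_observed.values
K = compute_kinship(ds.genotypes)
print(f"kinship from {K.n_snps_used} SNPs; causal columns "
      f"{ds.causal_indices.tolist()}")

y_mod, rep = robustify_phenotype(y, ds.genotypes.dosages)
scans = {
    "lrm": lrm_association_scan(y, ds.genotypes),
    "lmm": lmm_association_scan(y, ds.genotypes, K, mode="fast"),
    "rgwas": lmm_association_scan(y_mod, ds.genotypes, K, mode="fast"),
}
for name, res in scans.items():
    det = np.flatnonzero(res["pvalue"].to_numpy() < 1e-5)
    true_hits = [j for j in det if np.abs(ds.causal_indices - j).min() <= 3]
    print(f"{name:>6}: {det.size:3d} detections below 1e-5, "
          f"{len(true_hits)} tagging a causal SNP")
# Expected pattern: LRM fires on many structure-confounded SNPs (high
# FDR); the plain LMM misses causal SNPs because the outliers inflate
# its error variance; the robustified scan recovers them.

info = export_qq_manhattan(scans["rgwas"], "scratch_example", cutoff=1e-5)
print(f"genomic inflation lambda (robustified scan): {info['lambda']:.2f}")
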