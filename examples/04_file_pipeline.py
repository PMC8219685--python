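"""File-based pipeline: write, preprocess, impute, prune, scan.

Mirrors a real diversity-panel workflow on synthetic files: genotype
CSV + SNP map on disk, phenotype TSV, call-rate/MAF filtering, kNN
imputation of missing calls, LD pruning for the kinship SNP set, and
a robustified scan.
"""

import os
import tempfile

import numpy as np

from rgwas import (SimDesign, compute_kinship, lmm_association_scan,
                   robustify_phenotype, simulate_dataset, align)
from rgwas.io import (filter_variants, knn_impute, ld_prune, read_genotypes,
                      read_phenotype, write_genotypes, write_phenotype)

ds = simulate_dataset(SimDesign(n=300, m_snps=250, h2_main=0.3,
                                contamination_rate=0.03), seed=5)
# knock out 1% of calls to exercise imputation
D = ds.genotypes.dosages
rng = np.random.default_rng(0)
D[rng.random(D.shape) < 0.01] = np.nan

with tempfile.TemporaryDirectory() as tmp:
    gpath = os.path.join(tmp, "genotypes.csv")
    mpath = os.path.join(tmp, "snp_map.tsv")
    ppath = os.path.join(tmp, "phenotype.tsv")
    write_genotypes(ds.genotypes, gpath, map_path=mpath)
    write_phenotype(ds.phenotype_observed, ppath)

    g = read_genotypes(gpath, map_path=mpath)
    p = read_phenotype(ppath)
    print(f"loaded {g.n_individuals} individuals x {g.n_snps} SNPs, "
          f"{np.isnan(g.dosages).sum()} missing calls")

    g = filter_variants(g, min_call_rate=0.7, min_maf=0.05)
    g = knn_impute(g, k=5)
    g, p = align(g, p)
    pruned = ld_prune(g, r2_max=0.9, window=50, step=25)
    print(f"{g.n_snps} SNPs after filters; kinship uses {pruned.n_snps} "
          f"LD-pruned SNPs")

    K = compute_kinship(pruned)
    y_mod, rep = robustify_phenotype(p, g)
    res = lmm_association_scan(y_mod, g, K, mode="fast")
    top = res.nsmallest(3, "pvalue")[["snp_id", "pos", "F", "pvalue"]]
    print(f"{rep.n_outliers} phenotype outliers repaired; top hits:")
    print(top.to_string(index=False))
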