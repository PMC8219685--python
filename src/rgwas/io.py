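"""Readers, writers and real-data preprocessing.

Formats
-------
Genotype CSV: individuals x SNPs, first column the individual id,
header row the SNP ids, cells 0/1/2 or ``NA``.  An optional sidecar
map TSV carries columns ``snp_id``, ``chr``, ``pos`` (1-based).
PLINK ``.raw`` dialect: whitespace table with the usual six leading
columns (FID IID PAT MAT SEX PHENOTYPE) followed by per-SNP dosage
columns.  Phenotype TSV: two columns, id and value.

Preprocessing mirrors what a diversity-panel analysis needs before the
scan: call-rate/MAF filtering, weighted k-nearest-neighbour imputation
of missing dosages, and sliding-window LD pruning for the kinship SNP
set.  On read, dosages are re-oriented so the counted allele is the
minor one (column mean <= 1).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .datatypes import GenotypeMatrix, PhenotypeVector

__all__ = [
    "read_genotypes",
    "write_genotypes",
    "read_phenotype",
    "write_phenotype",
    "filter_variants",
    "knn_impute",
    "ld_prune",
    "export_qq_manhattan",
    "genomic_inflation",
]

_PLINK_META = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


def _orient_minor(D: np.ndarray) -> np.ndarray:
    """Recode columns so the counted allele is the minor one."""
    with np.errstate(invalid="ignore"):
        flip = np.nanmean(D, axis=0) > 1.0
    D[:, flip] = 2.0 - D[:, flip]
    return D


def read_genotypes(path, format: str = "csv", map_path=None) -> GenotypeMatrix:
    """Load a dosage table; enforces minor-allele orientation.

    ``format="csv"``: individuals x SNPs with id index column.
    ``format="plink_raw"``: PLINK ``--recode A`` text output; SNP ids
    keep their allele suffix stripped (``rs1_A`` -> ``rs1``).
    A malformed row raises with the offending line number.
    """
    if format == "csv":
        try:
            df = pd.read_csv(path, index_col=0, na_values=["NA"])
        except pd.errors.ParserError as err:
            raise ValueError(f"malformed genotype CSV {path}: {err}") from err
        snp_ids = df.columns.to_numpy(dtype=str)
        ind_ids = df.index.to_numpy(dtype=str)
        D = df.to_numpy(dtype=float)
    elif format == "plink_raw":
        df = pd.read_csv(path, sep=r"\s+", na_values=["NA"])
        missing_meta = [c for c in _PLINK_META if c not in df.columns]
        if missing_meta:
            raise ValueError(f"not a PLINK .raw table; missing {missing_meta}")
        snp_cols = [c for c in df.columns if c not in _PLINK_META]
        snp_ids = np.array([c.rsplit("_", 1)[0] for c in snp_cols])
        ind_ids = df["IID"].to_numpy(dtype=str)
        D = df[snp_cols].to_numpy(dtype=float)
    else:
        raise ValueError("format must be 'csv' or 'plink_raw'")
    bad = ~(np.isnan(D) | np.isin(D, (0.0, 1.0, 2.0)))
    if bad.any():
        row = int(np.argwhere(bad)[0, 0])
        raise ValueError(f"non-dosage value in {path} at data row {row + 1}")
    D = _orient_minor(D)

    m = len(snp_ids)
    chrom = np.ones(m, dtype=int)
    pos = np.arange(1, m + 1)
    if map_path is not None:
        mp = pd.read_csv(map_path, sep="\t", dtype={"snp_id": str})
        mp = mp.set_index("snp_id").reindex(snp_ids)
        if mp["chr"].isna().any():
            missing = snp_ids[mp["chr"].isna().to_numpy()][:3]
            raise ValueError(f"map file lacks entries for SNPs {list(missing)}")
        chrom = mp["chr"].to_numpy(dtype=int)
        pos = mp["pos"].to_numpy(dtype=int)
    return GenotypeMatrix(D, snp_ids, chrom, pos, ind_ids)


def write_genotypes(g: GenotypeMatrix, path, map_path=None) -> None:
    """Write the CSV dialect (and optionally the sidecar map TSV)."""
    df = pd.DataFrame(g.dosages, index=pd.Index(g.individual_ids, name="id"),
                      columns=g.snp_ids)
    # keep integer look for legal calls, NA for missing
    df = df.map(lambda v: "NA" if np.isnan(v) else str(int(v)))
    df.to_csv(path)
    if map_path is not None:
        pd.DataFrame({"snp_id": g.snp_ids, "chr": g.chrom, "pos": g.pos}
                     ).to_csv(map_path, sep="\t", index=False)


def read_phenotype(path) -> PhenotypeVector:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    if df.shape[1] < 2:
        raise ValueError("phenotype TSV needs id and value columns")
    return PhenotypeVector(df.iloc[:, 0].to_numpy(dtype=str),
                           df.iloc[:, 1].to_numpy(dtype=float))


def write_phenotype(p: PhenotypeVector, path) -> None:
    pd.DataFrame({"id": p.individual_ids, "value": p.values}
                 ).to_csv(path, sep="\t", index=False, na_rep="NA")


def filter_variants(g: GenotypeMatrix, min_call_rate: float = 0.7,
                    min_maf: float = 0.05) -> GenotypeMatrix:
    """Keep SNPs with call rate > ``min_call_rate`` and MAF > ``min_maf``.

    Order is preserved; raises if nothing survives.
    """
    for name, v in (("min_call_rate", min_call_rate), ("min_maf", min_maf)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must be in [0, 1]")
    keep = (g.call_rate() > min_call_rate) & (g.maf() > min_maf)
    if not keep.any():
        raise ValueError("all SNPs removed by the filters")
    return g.take_snps(np.flatnonzero(keep))


def knn_impute(g: GenotypeMatrix, k: int = 5) -> GenotypeMatrix:
    """Weighted k-nearest-neighbour imputation of missing dosages.

    Distance between two individuals is the mean squared dosage
    difference over their shared non-missing SNPs; each missing call is
    filled with the 1/d-weighted average of the k nearest individuals'
    observed dosages at that SNP, rounded to the nearest legal code.
    A zero-distance neighbour (duplicate individual) dominates.
    Observed dosages are never altered.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    D = g.dosages
    miss = np.isnan(D)
    if not miss.any():
        return g
    all_missing = miss.all(axis=1)
    if all_missing.any():
        bad = g.individual_ids[all_missing]
        raise ValueError(f"individuals with no genotype calls: {list(bad)}")
    X = np.nan_to_num(D, nan=0.0)
    O = (~miss).astype(float)
    # squared distances restricted to pairwise-complete SNPs
    sq = X * X
    cross = X @ X.T
    s_i = sq @ O.T
    overlap = O @ O.T
    with np.errstate(invalid="ignore", divide="ignore"):
        d2 = (s_i + s_i.T - 2.0 * cross) / overlap
    np.fill_diagonal(d2, np.inf)
    d2[overlap == 0] = np.inf

    n = D.shape[0]
    filled = D.copy()
    rows, cols = np.nonzero(miss)
    order = np.argsort(d2, axis=1)
    for i in np.unique(rows):
        want = cols[rows == i]
        neigh_order = order[i]
        for j in want:
            usable = neigh_order[~miss[neigh_order, j] &
                                 np.isfinite(d2[i, neigh_order])]
            nb = usable[:k]
            if nb.size == 0:
                raise ValueError(
                    f"cannot impute individual {g.individual_ids[i]!r}: "
                    f"no neighbour observed at SNP {g.snp_ids[j]!r}")
            d = d2[i, nb]
            w = np.where(d <= 0, np.inf, 1.0 / np.sqrt(np.maximum(d, 1e-300)))
            if np.isinf(w).any():  # duplicates: average the exact matches
                val = D[nb[np.isinf(w)], j].mean()
            else:
                val = float(w @ D[nb, j] / w.sum())
            filled[i, j] = np.clip(np.round(val), 0, 2)
    out = GenotypeMatrix(filled, g.snp_ids, g.chrom, g.pos, g.individual_ids)
    return out


def ld_prune(g: GenotypeMatrix, r2_max: float = 0.9, window: int = 200,
             step: int = 50) -> GenotypeMatrix:
    """Greedy left-to-right LD pruning on squared dosage correlation.

    Within each sliding window of ``window`` SNPs (advanced by
    ``step``), the later SNP of any pair with r^2 > ``r2_max`` is
    dropped.  Deterministic given input order; intended for the kinship
    SNP set (the tested set stays complete).
    """
    if not 0 < r2_max <= 1:
        raise ValueError("r2_max must be in (0, 1]")
    if window < 2:
        raise ValueError("window must be >= 2")
    D = np.nan_to_num(g.dosages, nan=np.nan)
    m = g.n_snps
    keep = np.ones(m, dtype=bool)
    col_mean = np.nanmean(D, axis=0)
    Xc = np.where(np.isnan(D), 0.0, D - col_mean)
    norms = np.sqrt((Xc * Xc).sum(axis=0))
    for start in range(0, m, step):
        idx = np.flatnonzero(keep[start:start + window]) + start
        if idx.size < 2:
            continue
        B = Xc[:, idx]
        nrm = np.where(norms[idx] > 0, norms[idx], 1.0)
        R = (B.T @ B) / np.outer(nrm, nrm)
        r2 = R * R
        iu, ju = np.triu_indices(idx.size, k=1)
        hits = r2[iu, ju] > r2_max
        keep[idx[ju[hits]]] = False
        if start + window >= m:
            break
    return g.take_snps(np.flatnonzero(keep))


def genomic_inflation(pvalues) -> float:
    """Inflation factor lambda: median observed 1-df chi-square over
    its null median (0.4549...)."""
    from scipy import stats

    p = np.asarray(pvalues, dtype=float)
    p = p[np.isfinite(p)]
    chi2 = stats.chi2.isf(np.clip(p, 1e-300, 1.0), df=1)
    return float(np.median(chi2) / stats.chi2.isf(0.5, df=1))


def export_qq_manhattan(results: pd.DataFrame, out_prefix,
                        cutoff: float | None = None) -> dict:
    """Write Manhattan and QQ tables for a results frame.

    ``<prefix>_manhattan.tsv``: chr, pos, cumulative genome coordinate,
    -log10 p (and a ``significant`` flag when ``cutoff`` is given).
    ``<prefix>_qq.tsv``: expected vs observed -log10 p under uniform
    order statistics.  Returns the file paths and the genomic inflation
    factor lambda.  Zero/NaN p-values are clamped with a warning.
    """
    if len(results) == 0:
        raise ValueError("results frame is empty")
    res = results.copy()
    p = res["pvalue"].to_numpy(dtype=float)
    bad = ~np.isfinite(p) | (p <= 0)
    if bad.any():
        warnings.warn(f"{bad.sum()} zero/NaN p-values clamped", stacklevel=2)
        p = np.where(bad, 1e-300, p)

    # cumulative genome coordinate by chromosome
    chroms = res["chr"].to_numpy()
    pos = res["pos"].to_numpy(dtype=float)
    cum = np.zeros_like(pos)
    offset = 0.0
    for ch in pd.unique(chroms):
        sel = chroms == ch
        cum[sel] = pos[sel] + offset
        offset = cum[sel].max()
    man = pd.DataFrame({"snp_id": res["snp_id"], "chr": chroms,
                        "pos": res["pos"], "cum_pos": cum.astype(int),
                        "neglog10p": -np.log10(p)})
    if cutoff is not None:
        man["significant"] = p < cutoff
    man_path = f"{out_prefix}_manhattan.tsv"
    man.to_csv(man_path, sep="\t", index=False)

    n = p.size
    expected = -np.log10((np.arange(1, n + 1) - 0.5) / n)
    observed = -np.log10(np.sort(p))  # descending, matching expected
    qq = pd.DataFrame({"expected": expected, "observed": observed})
    qq_path = f"{out_prefix}_qq.tsv"
    qq.to_csv(qq_path, sep="\t", index=False)

    lam = genomic_inflation(p)
    return {"manhattan": man_path, "qq": qq_path, "lambda": lam,
            "n_significant": int((p < cutoff).sum()) if cutoff else None}
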