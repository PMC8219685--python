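"""Linear mixed model association testing with a genomic kinship matrix.

Model: y = X a + Z b + e, with polygenic random effect
b ~ N(0, sigma_g^2 K) over genotype lines and e ~ N(0, sigma_e^2 I).
Writing delta = sigma_e^2 / sigma_g^2, the phenotypic covariance is
V = sigma_g^2 (Z K Z' + delta I).  A single eigendecomposition of
Z K Z' makes the (restricted) likelihood a cheap one-dimensional
function of delta, which is maximised on a log grid with Brent
refinement.  Each SNP enters the fixed-effect design next to the
intercept (and optional covariates) and is tested with the GLS F
statistic on 1 and n - q degrees of freedom.

Two scan modes are provided: ``exact`` re-estimates delta under each
SNP's alternative model; ``fast`` estimates delta once under the null
(covariates-only) model and reuses it for every SNP, the usual
approximation for large scans.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .datatypes import GenotypeMatrix, PhenotypeVector, align

__all__ = [
    "KinshipMatrix",
    "LMMFit",
    "compute_kinship",
    "reml_fit",
    "lmm_association_scan",
    "lrm_association_scan",
]

_DELTA_BOUNDS = (1e-5, 1e5)
_N_GRID = 100
_MIN_P = 5e-324  # smallest subnormal double; perfect-fit guard


@dataclass
class KinshipMatrix:
    """Genomic relationship matrix over genotype lines."""

    values: np.ndarray
    individual_ids: np.ndarray | None = None
    n_snps_used: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("kinship must be a square matrix")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        ids = (self.individual_ids if self.individual_ids is not None
               else np.arange(self.n))
        return pd.DataFrame(self.values, index=ids, columns=ids)


def compute_kinship(X, maf_bounds: tuple[float, float] = (0.01, 0.5)
                    ) -> KinshipMatrix:
    """Allele-frequency-standardised genomic relationship matrix.

    k_jt = (1/T) sum_i (x_ij - 2 f_i)(x_it - 2 f_i) / (2 f_i (1 - f_i))

    averaged over the T SNPs whose counted-allele frequency f_i lies in
    ``(maf_bounds[0], maf_bounds[1]]``; monomorphic SNPs never
    contribute.  Missing dosages are mean-imputed (x = 2 f_i), i.e. they
    contribute zero to the cross-products.
    """
    ids = None
    if isinstance(X, GenotypeMatrix):
        ids = X.individual_ids
        D = X.dosages
    else:
        D = np.asarray(X, dtype=float)
    f = np.nanmean(D, axis=0) / 2.0
    lo, hi = maf_bounds
    keep = (f > lo) & (f <= hi)
    if not keep.any():
        raise ValueError("no polymorphic SNP available for kinship")
    Dk = D[:, keep]
    fk = f[keep]
    Zs = (Dk - 2.0 * fk) / np.sqrt(2.0 * fk * (1.0 - fk))
    Zs = np.nan_to_num(Zs, nan=0.0)
    T = int(keep.sum())
    K = (Zs @ Zs.T) / T
    return KinshipMatrix(K, ids, T)


@dataclass
class LMMFit:
    """Variance components and fixed effects at the REML/ML optimum."""

    delta: float
    sigma_g2: float
    sigma_e2: float
    a_hat: np.ndarray
    loglik: float
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    method: str = "reml"
    boundary: bool = False
    n: int = 0
    q: int = 0

    @property
    def heritability(self) -> float:
        """sigma_g^2 / (sigma_g^2 + sigma_e^2) = 1 / (1 + delta)."""
        return 1.0 / (1.0 + self.delta)


def _eigendecompose(A: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    A = 0.5 * (A + A.T)
    xi, U = np.linalg.eigh(A)
    if xi[0] < -1e-8 * max(abs(xi[-1]), 1.0):
        warnings.warn("random-effect covariance not PSD; "
                      "clamping negative eigenvalues to zero", stacklevel=3)
    return np.maximum(xi, 0.0), U


def _gls_pieces(yt, Xt, xi, delta):
    """Weighted-regression quantities at a given delta (rotated basis)."""
    w = 1.0 / (xi + delta)
    Xw = Xt * w[:, None]
    XtWX = Xt.T @ Xw
    XtWy = Xw.T @ yt
    a = np.linalg.solve(XtWX, XtWy)
    r = yt - Xt @ a
    R = float(w @ (r * r))
    sign, logdet_xwx = np.linalg.slogdet(XtWX)
    return a, R, logdet_xwx, w


def _restricted_loglik(delta, yt, Xt, xi, logdet_xx):
    n, q = Xt.shape
    _, R, logdet_xwx, _ = _gls_pieces(yt, Xt, xi, delta)
    sigma2 = R / (n - q)
    logdet_h = float(np.log(xi + delta).sum())
    return -0.5 * ((n - q) * (np.log(2.0 * np.pi * sigma2) + 1.0)
                   + logdet_h + logdet_xwx - logdet_xx)


def _full_loglik(delta, yt, Xt, xi):
    n = Xt.shape[0]
    _, R, _, _ = _gls_pieces(yt, Xt, xi, delta)
    sigma2 = R / n
    logdet_h = float(np.log(xi + delta).sum())
    return -0.5 * (n * (np.log(2.0 * np.pi * sigma2) + 1.0) + logdet_h)


def _optimise_delta(loglik, bounds=_DELTA_BOUNDS, n_grid=_N_GRID):
    grid = np.logspace(np.log10(bounds[0]), np.log10(bounds[1]), n_grid)
    vals = np.array([loglik(d) for d in grid])
    k = int(np.argmax(vals))
    boundary = k in (0, n_grid - 1)
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, n_grid - 1)]
    if lo < hi:
        res = optimize.minimize_scalar(
            lambda t: -loglik(10.0 ** t),
            bounds=(np.log10(lo), np.log10(hi)), method="bounded",
            options={"xatol": 1e-8})
        delta = float(10.0 ** res.x)
        if loglik(delta) < vals[k]:
            delta = float(grid[k])
    else:
        delta = float(grid[k])
    return delta, boundary


def reml_fit(y, Xfix=None, K: KinshipMatrix | np.ndarray | None = None,
             genotype_index=None, method: str = "reml",
             eigen: tuple[np.ndarray, np.ndarray] | None = None) -> LMMFit:
    """Estimate variance components by spectral-decomposition REML.

    Parameters
    ----------
    y
        Phenotype vector (array or :class:`PhenotypeVector`).
    Xfix
        Fixed-effect design (n x q), full column rank.  Defaults to an
        intercept.
    K
        Kinship over genotype lines.
    genotype_index
        Optional length-n integer map of observations onto rows of K
        (the incidence matrix Z); identity when omitted.
    method
        "reml" (sigma^2 = R/(n-q)) or "ml" (sigma^2 = R/n).
    eigen
        Pre-computed ``(eigenvalues, eigenvectors)`` of Z K Z', to share
        one decomposition across phenotypes on the same genotypes.
    """
    yv = y.values if isinstance(y, PhenotypeVector) else np.asarray(y, float)
    n = yv.size
    X = (np.ones((n, 1)) if Xfix is None
         else np.atleast_2d(np.asarray(Xfix, dtype=float)))
    if X.shape[0] != n:
        raise ValueError("Xfix rows must match phenotype length")
    q = X.shape[1]
    if np.linalg.matrix_rank(X) < q:
        raise ValueError("Xfix is rank deficient")
    if eigen is None:
        Kv = K.values if isinstance(K, KinshipMatrix) else np.asarray(K, float)
        A = Kv if genotype_index is None else Kv[np.ix_(genotype_index,
                                                        genotype_index)]
        if A.shape != (n, n):
            raise ValueError("Z K Z' must be n x n")
        xi, U = _eigendecompose(A)
    else:
        xi, U = eigen
    yt = U.T @ yv
    Xt = U.T @ X
    sign, logdet_xx = np.linalg.slogdet(X.T @ X)

    if method == "reml":
        def ll(d):
            return _restricted_loglik(d, yt, Xt, xi, logdet_xx)
    elif method == "ml":
        def ll(d):
            return _full_loglik(d, yt, Xt, xi)
    else:
        raise ValueError("method must be 'reml' or 'ml'")

    delta, boundary = _optimise_delta(ll)
    a, R, _, _ = _gls_pieces(yt, Xt, xi, delta)
    dof = n - q if method == "reml" else n
    sigma_g2 = R / dof
    sigma_e2 = delta * sigma_g2
    return LMMFit(delta=delta, sigma_g2=sigma_g2, sigma_e2=sigma_e2,
                  a_hat=a, loglik=ll(delta), eigenvalues=xi, eigenvectors=U,
                  method=method, boundary=boundary, n=n, q=q)


# ----------------------------------------------------------------------
# Association scans
# ----------------------------------------------------------------------

def _as_aligned(y, X):
    if isinstance(y, PhenotypeVector) and isinstance(X, GenotypeMatrix):
        X, y = align(X, y)
        return y.values, X.dosages, X
    yv = y.values if isinstance(y, PhenotypeVector) else np.asarray(y, float)
    if isinstance(X, GenotypeMatrix):
        return yv, X.dosages, X
    return yv, np.asarray(X, dtype=float), None


def _result_frame(gmat, m, F, pval, beta_hat, df2, method):
    if gmat is not None:
        out = gmat.snp_frame()[["snp_id", "chr", "pos", "maf"]].copy()
    else:
        out = pd.DataFrame({"snp_id": np.arange(m), "chr": 1,
                            "pos": np.arange(1, m + 1), "maf": np.nan})
    out["beta_hat"] = beta_hat
    out["F"] = F
    out["df1"] = 1
    out["df2"] = df2
    out["pvalue"] = pval
    out.attrs["method"] = method
    return out


def _fwl_scan(yw, X0w, Gw, df2):
    """Per-SNP slope F-tests after projecting out X0w (all weighted)."""
    Q, _ = np.linalg.qr(X0w)
    ry = yw - Q @ (Q.T @ yw)
    RG = Gw - Q @ (Q.T @ Gw)
    gg = np.einsum("ij,ij->j", RG, RG)
    gy = ry @ RG
    yy = float(ry @ ry)
    mono = gg <= 1e-12 * max(yy, 1.0)
    gg_safe = np.where(mono, 1.0, gg)
    slope = gy / gg_safe
    rss = np.maximum(yy - slope * gy, 0.0)
    rss = np.maximum(rss, 1e-300)
    sigma2 = rss / df2
    F = slope * slope * gg_safe / sigma2
    pval = stats.f.sf(F, 1, df2)
    pval = np.maximum(pval, _MIN_P)
    F[mono] = 0.0
    pval[mono] = 1.0
    slope[mono] = 0.0
    return F, pval, slope, mono


def lrm_association_scan(y, X, covariates=None) -> pd.DataFrame:
    """Per-SNP ordinary least squares scan (intercept + covariates + SNP).

    The baseline linear regression model: no kinship correction, F-test
    (the square of the slope t-test) on 1 and n - q denominator degrees
    of freedom.  Monomorphic SNPs get p = 1.
    """
    yv, G, gmat = _as_aligned(y, X)
    n = yv.size
    X0 = np.ones((n, 1))
    if covariates is not None:
        X0 = np.column_stack([X0, np.asarray(covariates, dtype=float)])
    q = X0.shape[1] + 1
    F, pval, slope, _ = _fwl_scan(yv, X0, np.nan_to_num(G, nan=0.0), n - q)
    return _result_frame(gmat, G.shape[1], F, pval, slope, n - q, "lrm")


def lmm_association_scan(y, X, K: KinshipMatrix | np.ndarray,
                         covariates=None, mode: str = "exact",
                         genotype_index=None,
                         eigen=None, null_fit: LMMFit | None = None
                         ) -> pd.DataFrame:
    """Mixed-model association scan over every SNP.

    ``mode="exact"`` re-estimates the variance ratio delta under each
    SNP's alternative model (grid search plus Brent refinement on the
    per-SNP restricted likelihood); ``mode="fast"`` reuses the null
    model's delta for every SNP.  Returns a results table with columns
    snp_id, chr, pos, maf, beta_hat, F, df1, df2, pvalue.
    """
    if mode not in ("exact", "fast"):
        raise ValueError("mode must be 'exact' or 'fast'")
    yv, G, gmat = _as_aligned(y, X)
    n = yv.size
    m = G.shape[1]
    G = np.nan_to_num(G, nan=0.0)
    X0 = np.ones((n, 1))
    if covariates is not None:
        X0 = np.column_stack([X0, np.asarray(covariates, dtype=float)])
        if np.linalg.matrix_rank(X0) < X0.shape[1]:
            raise ValueError("covariates are collinear with the intercept")
    q = X0.shape[1] + 1

    if eigen is None:
        Kv = K.values if isinstance(K, KinshipMatrix) else np.asarray(K, float)
        A = Kv if genotype_index is None else Kv[np.ix_(genotype_index,
                                                        genotype_index)]
        xi, U = _eigendecompose(A)
    else:
        xi, U = eigen
    if null_fit is None:
        null_fit = reml_fit(yv, X0, eigen=(xi, U))
    yt = U.T @ yv
    X0t = U.T @ X0
    Gt = U.T @ G

    if mode == "fast":
        deltas = np.full(m, null_fit.delta)
    else:
        deltas = _per_snp_delta(yt, X0t, Gt, xi)

    F = np.empty(m)
    pval = np.empty(m)
    slope = np.empty(m)
    # group SNPs by (nearly) common delta to keep the fast path vectorised
    uniq, inverse = np.unique(np.round(np.log10(deltas), 6),
                              return_inverse=True)
    for u in range(uniq.size):
        cols = np.flatnonzero(inverse == u)
        d = float(deltas[cols[0]])
        sqw = 1.0 / np.sqrt(xi + d)
        Fj, pj, sj, _ = _fwl_scan(yt * sqw, X0t * sqw[:, None],
                                  Gt[:, cols] * sqw[:, None], n - q)
        F[cols], pval[cols], slope[cols] = Fj, pj, sj
    res = _result_frame(gmat, m, F, pval, slope, n - q,
                        f"lmm-{mode}")
    res.attrs["null_delta"] = float(null_fit.delta)
    return res


class FastScanContext:
    """Reusable pieces for repeated fast-mode scans on fixed genotypes.

    Holds the eigendecomposition of the random-effect covariance and
    the rotated genotype/design matrices, so scanning many phenotypes
    on the same genotype matrix (replication studies, robustified vs
    raw traits) costs one weighted regression sweep per phenotype.
    """

    def __init__(self, G, K, covariates=None):
        Kv = K.values if isinstance(K, KinshipMatrix) else np.asarray(K, float)
        G = np.nan_to_num(np.asarray(G, dtype=float), nan=0.0)
        n, self.m = G.shape
        self.n = n
        self.xi, self.U = _eigendecompose(Kv)
        X0 = np.ones((n, 1))
        if covariates is not None:
            X0 = np.column_stack([X0, np.asarray(covariates, dtype=float)])
        self.q = X0.shape[1] + 1
        self.X0 = X0
        self.X0t = self.U.T @ X0
        self.Gt = self.U.T @ G
        _, self.logdet_xx = np.linalg.slogdet(X0.T @ X0)

    def scan(self, y):
        """Fast-mode p-values for one phenotype; returns a dict of arrays."""
        yv = y.values if isinstance(y, PhenotypeVector) else np.asarray(y, float)
        yt = self.U.T @ yv

        def ll(d):
            return _restricted_loglik(d, yt, self.X0t, self.xi,
                                      self.logdet_xx)

        delta, boundary = _optimise_delta(ll)
        sqw = 1.0 / np.sqrt(self.xi + delta)
        df2 = self.n - self.q
        F, pval, slope, mono = _fwl_scan(yt * sqw, self.X0t * sqw[:, None],
                                         self.Gt * sqw[:, None], df2)
        return {"F": F, "pvalue": pval, "beta_hat": slope, "delta": delta,
                "df2": df2, "boundary": boundary, "monomorphic": mono}


def _per_snp_delta(yt, X0t, Gt, xi, n_grid=_N_GRID):
    """Profile-REML delta per SNP: vectorised grid + Brent refinement.

    For each delta the per-SNP restricted log-likelihood differs from
    the null-design one only through the SNP column; with the covariate
    block projected out, ln|X'H^-1 X| = ln|X0'H^-1 X0| + ln(g'H^-1 g -
    proj), and the residual sum follows from the
    Frisch-Waugh-Lovell step, so all SNPs share one pass per grid point.
    The delta-independent ln|X'X| term is dropped (it does not move the
    argmax).
    """
    n, q0 = X0t.shape
    m = Gt.shape[1]
    q = q0 + 1
    grid = np.logspace(np.log10(_DELTA_BOUNDS[0]), np.log10(_DELTA_BOUNDS[1]),
                       n_grid)

    def ll_all(d):
        sqw = 1.0 / np.sqrt(xi + d)
        X0w = X0t * sqw[:, None]
        yw = yt * sqw
        Q, Rq = np.linalg.qr(X0w)
        logdet0 = 2.0 * float(np.log(np.abs(np.diag(Rq))).sum())
        ry = yw - Q @ (Q.T @ yw)
        Gw = Gt * sqw[:, None]
        RG = Gw - Q @ (Q.T @ Gw)
        gg = np.einsum("ij,ij->j", RG, RG)
        gg = np.maximum(gg, 1e-300)
        gy = ry @ RG
        rss = np.maximum(float(ry @ ry) - gy * gy / gg, 1e-300)
        logdet_h = float(np.log(xi + d).sum())
        return -0.5 * ((n - q) * (np.log(2.0 * np.pi * rss / (n - q)) + 1.0)
                       + logdet_h + logdet0 + np.log(gg))

    vals = np.empty((n_grid, m))
    for i, d in enumerate(grid):
        vals[i] = ll_all(d)
    best = np.argmax(vals, axis=0)

    deltas = np.empty(m)
    log_grid = np.log10(grid)
    for j in range(m):
        k = int(best[j])
        lo = log_grid[max(k - 1, 0)]
        hi = log_grid[min(k + 1, n_grid - 1)]
        if lo >= hi:
            deltas[j] = grid[k]
            continue
        gj = Gt[:, j:j + 1]

        def negll(t, gj=gj, j=j):
            return -float(ll_all_single(10.0 ** t, gj))

        def ll_all_single(d, gcol):
            sqw = 1.0 / np.sqrt(xi + d)
            X0w = X0t * sqw[:, None]
            yw = yt * sqw
            Q, Rq = np.linalg.qr(X0w)
            logdet0 = 2.0 * float(np.log(np.abs(np.diag(Rq))).sum())
            ry = yw - Q @ (Q.T @ yw)
            gw = gcol[:, 0] * sqw
            rg = gw - Q @ (Q.T @ gw)
            gg = max(float(rg @ rg), 1e-300)
            gy = float(ry @ rg)
            rss = max(float(ry @ ry) - gy * gy / gg, 1e-300)
            logdet_h = float(np.log(xi + d).sum())
            return -0.5 * ((n - q) * (np.log(2 * np.pi * rss / (n - q)) + 1.0)
                           + logdet_h + logdet0 + np.log(gg))

        res = optimize.minimize_scalar(negll, bounds=(lo, hi),
                                       method="bounded",
                                       options={"xatol": 1e-6})
        cand = float(10.0 ** res.x)
        if ll_all_single(cand, gj) >= vals[k, j]:
            deltas[j] = cand
        else:
            deltas[j] = grid[k]
    return deltas
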