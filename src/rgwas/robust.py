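"""Minimum beta-divergence estimation and phenotype outlier modification.

The robustification pipeline implemented here addresses a practical
failure mode of mixed-model GWAS: a handful of wildly aberrant phenotype
measurements inflate the error variance component and wash out real
associations.  Because a quantitative trait measured across the genotype
classes of a SNP is *multimodal* (one mode per dosage group), global
unimodal outlier rules misbehave; instead the trait is partitioned by
the genotype groups of the most strongly associated SNP and outliers are
judged, and repaired, within each group.

Per group, location and scale are estimated by the minimum
beta-divergence (density-power divergence) method: a fixed-point
iteration of the weighted mean and weighted variance, where each
observation carries the weight

    W_beta(y) = exp(-beta * (y - mu)^2 / (2 sigma^2))  in (0, 1].

Observations far from the bulk get exponentially small weight, so the
estimators ignore them; at beta = 0 every weight is 1 and the estimators
reduce exactly to the Gaussian maximum-likelihood mean and variance.
The same weight doubles as the outlier score: points whose weight falls
at or below a group-specific threshold are replaced by the group's
robust mean, after which the trait can be analysed by a standard LMM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .datatypes import GenotypeMatrix, PhenotypeVector, align

__all__ = [
    "BetaConfig",
    "BetaFit",
    "BetaGroupEstimates",
    "OutlierReport",
    "beta_weight",
    "fit_beta_estimators",
    "fit_group_estimators",
    "detect_outliers",
    "robust_anova_scores",
    "robust_anova_select_snp",
    "robustify_phenotype",
]

_GROUP_LABELS = (0, 1, 2)


class DegenerateScaleError(ValueError):
    """All values identical: no scale to estimate."""


@dataclass(frozen=True)
class BetaConfig:
    """Tuning parameters of the robustification.

    Parameters
    ----------
    beta
        Robustness tuning parameter of the divergence; 0 gives the
        classical ML estimators, larger values downweight deviant
        observations more aggressively.  Default 0.2.
    outlier_quantile
        Probability p of the empirical weight quantile used as the
        per-group threshold tau_l.  It caps the fraction of a group
        that can ever be flagged; the default 0.1 is an upper bound on
        the contamination fractions the method targets (up to 5%).
    weight_ceiling
        Absolute ceiling: a point is only flagged if its weight is also
        below this value.  With beta = 0.2 a weight of 0.2 corresponds
        to a ~4-sigma deviation, so clean Gaussian groups yield
        (essentially) zero outliers even though the quantile rule alone
        would always flag a fixed fraction.
    max_iter, tol
        Fixed-point iteration control: stop when
        max(|d mu|, |d sigma^2|) < tol or after max_iter sweeps.
    min_group_size
        Genotype groups smaller than this are skipped (never flagged,
        excluded from the robust ANOVA).
    """

    beta: float = 0.2
    outlier_quantile: float = 0.1
    weight_ceiling: float = 0.2
    max_iter: int = 100
    tol: float = 1e-8
    min_group_size: int = 3

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if not 0 < self.outlier_quantile < 1:
            raise ValueError("outlier_quantile must be in (0, 1)")
        if not 0 < self.weight_ceiling <= 1:
            raise ValueError("weight_ceiling must be in (0, 1]")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")


def beta_weight(y, mu, sigma2, beta):
    """Beta-weight W_beta(y) = exp(-(beta / (2 sigma^2)) (y - mu)^2).

    Vectorises over ``y``.  Always in (0, 1]; equals 1 at y = mu and for
    beta = 0.
    """
    sigma2 = np.asarray(sigma2, dtype=float)
    if np.any(sigma2 <= 0):
        raise ValueError("sigma2 must be positive")
    y = np.asarray(y, dtype=float)
    dev = y - mu
    return np.exp(-(beta / (2.0 * sigma2)) * dev * dev)


class BetaFit(NamedTuple):
    """Result of a single-group minimum beta-divergence fit."""

    mu: float
    sigma2: float
    weights: np.ndarray
    converged: bool
    n_iter: int


def fit_beta_estimators(values, config: BetaConfig = BetaConfig()) -> BetaFit:
    """Minimum beta-divergence location/scale of one sample.

    Fixed-point iteration of the weighted mean and the weighted variance
    (the latter carries a (beta + 1) factor so that beta = 0 recovers
    the ML variance), initialised at the sample median and the squared
    scaled MAD.  With beta = 0 the closed-form ML estimators are
    returned directly.
    """
    y = np.asarray(values, dtype=float).ravel()
    if y.size < 2:
        raise ValueError("need at least two observations")
    if np.ptp(y) == 0:
        raise DegenerateScaleError("all values identical; scale is degenerate")
    if config.beta == 0:
        mu = float(np.mean(y))
        s2 = float(np.var(y))
        return BetaFit(mu, s2, np.ones_like(y), True, 0)

    mu = float(np.median(y))
    mad = float(np.median(np.abs(y - mu)))
    s2 = (1.4826 * mad) ** 2
    if s2 == 0:  # >50% ties: fall back on the classical variance
        s2 = float(np.var(y))
    beta = config.beta
    converged = False
    n_iter = 0
    for n_iter in range(1, config.max_iter + 1):
        dev2 = (y - mu) ** 2
        w = np.exp(-(beta / (2.0 * s2)) * dev2)
        sw = w.sum()
        mu_new = float(w @ y / sw)
        s2_new = float((1.0 + beta) * (w @ dev2) / sw)
        delta = max(abs(mu_new - mu), abs(s2_new - s2))
        mu, s2 = mu_new, s2_new
        if delta < config.tol:
            converged = True
            break
    weights = np.exp(-(beta / (2.0 * s2)) * (y - mu) ** 2)
    return BetaFit(mu, s2, weights, converged, n_iter)


@dataclass
class BetaGroupEstimates:
    """Per-genotype-group robust location/scale for one SNP's partition.

    ``weights`` covers every observation (1.0 in skipped groups); the
    remaining arrays are indexed by position in ``group_labels``.
    """

    group_labels: np.ndarray
    mu: np.ndarray
    sigma2: np.ndarray
    weights: np.ndarray
    converged: np.ndarray
    n_iter: np.ndarray
    skipped_labels: np.ndarray = field(default_factory=lambda: np.array([], int))
    beta: float = 0.2


def fit_group_estimators(values, groups, config: BetaConfig = BetaConfig()
                         ) -> BetaGroupEstimates:
    """Fit the beta-divergence estimators within each genotype group.

    Groups smaller than ``config.min_group_size`` are skipped with a
    warning and their observations keep weight 1.
    """
    y = np.asarray(values, dtype=float).ravel()
    g = np.asarray(groups).ravel()
    if g.shape != y.shape:
        raise ValueError("groups must align with values")
    labels, mus, s2s, convs, iters, skipped = [], [], [], [], [], []
    weights = np.ones_like(y)
    for lab in np.unique(g[~np.isnan(g.astype(float))]):
        idx = np.flatnonzero(g == lab)
        if idx.size < config.min_group_size:
            warnings.warn(
                f"genotype group {lab!r} has {idx.size} observations "
                f"(< {config.min_group_size}); skipped", stacklevel=2)
            skipped.append(lab)
            continue
        fit = fit_beta_estimators(y[idx], config)
        labels.append(lab)
        mus.append(fit.mu)
        s2s.append(fit.sigma2)
        convs.append(fit.converged)
        iters.append(fit.n_iter)
        weights[idx] = fit.weights
    return BetaGroupEstimates(
        np.asarray(labels), np.asarray(mus, float), np.asarray(s2s, float),
        weights, np.asarray(convs, bool), np.asarray(iters, int),
        np.asarray(skipped), config.beta)


@dataclass
class OutlierReport:
    """Which observations were flagged, and what replaced them."""

    outlier_indices: np.ndarray
    thresholds: dict
    replaced_values: np.ndarray
    replacement_values: np.ndarray
    weights: np.ndarray
    groups: np.ndarray
    estimates: BetaGroupEstimates | None = None
    selected_snp: int | None = None

    @property
    def n_outliers(self) -> int:
        return int(self.outlier_indices.size)

    def to_frame(self, individual_ids=None):
        import pandas as pd

        idx = self.outlier_indices
        ids = (np.asarray(individual_ids)[idx] if individual_ids is not None
               else idx)
        return pd.DataFrame({
            "individual_id": ids,
            "group": self.groups[idx],
            "original_value": self.replaced_values,
            "weight": self.weights[idx],
            "threshold": [self.thresholds[g] for g in self.groups[idx]],
            "replacement": self.replacement_values,
        })


def detect_outliers(values, groups, config: BetaConfig = BetaConfig()
                    ) -> OutlierReport:
    """Flag per-group outliers by the beta-weight rule.

    Within group l the threshold tau_l is the ``outlier_quantile``-th
    empirical quantile of the group's weights; an observation is an
    outlier iff its weight is <= tau_l *and* below the absolute
    ``weight_ceiling``.  The quantile caps how much of a group can be
    modified; the ceiling keeps clean groups untouched.
    """
    y = np.asarray(values, dtype=float).ravel()
    g = np.asarray(groups).ravel()
    est = fit_group_estimators(y, g, config)
    flagged = np.zeros(y.size, dtype=bool)
    thresholds: dict = {}
    replacement = np.full(y.size, np.nan)
    for k, lab in enumerate(est.group_labels):
        idx = np.flatnonzero(g == lab)
        w = est.weights[idx]
        tau = float(np.quantile(w, config.outlier_quantile))
        thresholds[lab] = tau
        out = (w <= tau) & (w < config.weight_ceiling)
        flagged[idx[out]] = True
        replacement[idx] = est.mu[k]
    out_idx = np.flatnonzero(flagged)
    return OutlierReport(
        outlier_indices=out_idx,
        thresholds=thresholds,
        replaced_values=y[out_idx].copy(),
        replacement_values=replacement[out_idx],
        weights=est.weights,
        groups=g,
        estimates=est,
    )


# ----------------------------------------------------------------------
# Vectorised group moments across all SNPs (drives the robust ANOVA)
# ----------------------------------------------------------------------

def _order_stat(C, counts, q, ys, n):
    """Value of the ceil(q*c)-th order statistic per column.

    ``C`` is the per-column cumulative count of group members with rows
    sorted by phenotype value, ``ys`` the sorted phenotype.
    """
    k = np.maximum(1, np.ceil(q * counts).astype(int))
    idx = (C < k[None, :]).sum(axis=0)
    return ys[np.minimum(idx, n - 1)]


def _group_moments_all_snps(y, dosages, config: BetaConfig):
    """Robust (mu, sigma2) for every (genotype group, SNP) pair at once.

    Returns arrays of shape (3, m): ``mu``, ``sigma2``, ``counts`` and a
    ``valid`` mask (group present with >= min_group_size members and a
    non-degenerate scale).  The iteration is the same fixed point as
    :func:`fit_beta_estimators`, initialised from per-group order
    statistics (median and IQR-based scale) read off a single sort of
    the phenotype.
    """
    y = np.asarray(y, dtype=float).ravel()
    D = np.asarray(dosages)
    n, m = D.shape
    var_y = float(np.var(y))
    tiny = max(var_y, 1.0) * 1e-12

    Df = D.astype(float, copy=False)
    Dint = np.where(np.isnan(Df), -1.0, Df).astype(np.int8)
    Dgather = np.maximum(Dint, 0)  # safe index for gathers; masked out of sums
    masks = [(Dint == lab) for lab in _GROUP_LABELS]
    counts = np.stack([mk.sum(axis=0) for mk in masks]).astype(np.int64)
    valid = counts >= config.min_group_size

    # classical (beta = 0) moments via masked sums; also the fallback init
    Y = y[:, None]
    mu = np.zeros((3, m))
    s2 = np.zeros((3, m))
    for k, mk in enumerate(masks):
        c = np.maximum(counts[k], 1)
        sw_y = y @ mk
        mu[k] = sw_y / c
        s2[k] = (y * y) @ mk / c - mu[k] ** 2
    if config.beta == 0:
        valid &= s2 > tiny
        return mu, np.maximum(s2, tiny), counts, valid, np.zeros(m, int), True

    # robust init: per-group median and IQR read from one global sort
    order = np.argsort(y, kind="stable")
    ys = y[order]
    Ds = Dint[order]
    mu0 = np.empty((3, m))
    s20 = np.empty((3, m))
    for k, lab in enumerate(_GROUP_LABELS):
        C = np.cumsum(Ds == lab, axis=0)
        med = _order_stat(C, counts[k], 0.50, ys, n)
        q1 = _order_stat(C, counts[k], 0.25, ys, n)
        q3 = _order_stat(C, counts[k], 0.75, ys, n)
        mu0[k] = med
        s20[k] = ((q3 - q1) / 1.349) ** 2
    use_fallback = s20 <= tiny
    s20[use_fallback] = s2[use_fallback]
    mu_c, s2_c = mu, s2  # keep the classical moments as the fallback
    mu, s2 = mu0, s20
    valid &= s2 > tiny
    s2 = np.maximum(s2, tiny)

    # invalid groups report the (clamped) classical moments
    for k in range(3):
        mu[k] = np.where(valid[k], mu[k], mu_c[k])
        s2[k] = np.where(valid[k], s2[k], np.maximum(s2_c[k], tiny))

    beta = config.beta
    half = -0.5 * beta
    n_iter_col = np.zeros(m, dtype=int)
    converged = True

    # iterate with per-column freezing: a SNP whose three group fits have
    # all moved by < tol drops out of the computation
    active = np.flatnonzero(valid.any(axis=0))
    Da = Dgather[:, active]
    Ma = [mk[:, active].astype(float) for mk in masks]
    it = 0
    while active.size and it < config.max_iter:
        it += 1
        cols_a = np.arange(active.size)
        mu_a = mu[:, active]
        s2_a = s2[:, active]
        valid_a = valid[:, active]
        mu_mat = mu_a[Da, cols_a]
        s2_mat = s2_a[Da, cols_a]
        dev = Y - mu_mat
        dev2 = dev * dev
        A = np.exp(half * dev2 / s2_mat)
        B = A * dev2
        dcol = np.zeros(active.size)
        for k, mk in enumerate(Ma):
            W = A * mk
            sw = W.sum(axis=0)
            sw = np.where(sw > 0, sw, 1.0)
            mu_new = (y @ W) / sw
            s2_new = (1.0 + beta) * (B * mk).sum(axis=0) / sw
            s2_new = np.maximum(s2_new, tiny)
            ok = valid_a[k]
            dcol = np.maximum(dcol, np.where(
                ok, np.maximum(np.abs(mu_new - mu_a[k]),
                               np.abs(s2_new - s2_a[k])), 0.0))
            mu[k, active] = np.where(ok, mu_new, mu[k, active])
            s2[k, active] = np.where(ok, s2_new, s2[k, active])
        n_iter_col[active] = it
        done = dcol < config.tol
        if done.any():
            still = ~done
            active = active[still]
            Da = Da[:, still]
            Ma = [mk[:, still] for mk in Ma]
    if active.size:
        converged = False
    return mu, s2, counts, valid, n_iter_col, converged


def robust_anova_scores(y, dosages, config: BetaConfig = BetaConfig()
                        ) -> np.ndarray:
    """Robust one-way ANOVA F-like statistic per SNP.

    F_beta = [sum_l n_l (mu_l - mu_bar)^2 / (g - 1)]
             / [sum_l n_l sigma2_l / (N - g)]

    with (mu_l, sigma2_l) the per-group minimum beta-divergence
    estimates, mu_bar their n_l-weighted mean, g the number of eligible
    groups and N their total size.  Since the beta = 0 scale estimate
    is the ML variance SS_l / n_l, weighting it by n_l recovers the
    within-group sum of squares and the statistic reduces *exactly* to
    the classical one-way ANOVA F.  SNPs with fewer than two
    eligible groups get NaN.
    """
    y = np.asarray(y, dtype=float).ravel()
    D = np.asarray(dosages)
    if D.ndim != 2 or D.shape[0] != y.size:
        raise ValueError("dosages must be (n, m) aligned with y")
    mu, s2, counts, valid, _, _ = _group_moments_all_snps(y, D, config)
    nl = np.where(valid, counts, 0).astype(float)
    g = valid.sum(axis=0)
    N = nl.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        grand = (nl * mu).sum(axis=0) / N
        ssb = (nl * (mu - grand) ** 2).sum(axis=0)
        msb = ssb / (g - 1)
        msw = (nl * np.where(valid, s2, 0.0)).sum(axis=0) / (N - g)
        F = msb / msw
    F[(g < 2) | (N - g <= 0)] = np.nan
    return F


def robust_anova_select_snp(y, X, config: BetaConfig = BetaConfig()) -> int:
    """Index of the SNP maximising the robust ANOVA statistic.

    Ties break to the lowest column index.  Raises if no SNP has at
    least two genotype groups of ``min_group_size`` observations.
    """
    if isinstance(y, PhenotypeVector):
        y = y.values
    if isinstance(X, GenotypeMatrix):
        X = X.dosages
    F = robust_anova_scores(y, X, config)
    if not np.isfinite(F).any():
        raise ValueError(
            "no SNP has >= 2 genotype groups of the minimum size; "
            "relax min_group_size or check the data")
    return int(np.nanargmax(F))


def robustify_phenotype(y, X, config: BetaConfig = BetaConfig()
                        ) -> tuple:
    """Modify phenotypic outliers group-wise and return the repair report.

    Selects the top SNP by robust ANOVA, partitions the phenotype by
    that SNP's genotype groups, flags outliers per group by the
    beta-weight rule and replaces them with the group's robust mean.
    Non-outlying values are returned bit-identical.
    """
    pheno_in = None
    if isinstance(y, PhenotypeVector) and isinstance(X, GenotypeMatrix):
        X, y = align(X, y)
        pheno_in = y
        yv = y.values
        D = X.dosages
    else:
        yv = np.asarray(y, dtype=float).ravel()
        D = X.dosages if isinstance(X, GenotypeMatrix) else np.asarray(X)
    snp = robust_anova_select_snp(yv, D, config)
    report = detect_outliers(yv, D[:, snp], config)
    report.selected_snp = snp
    y_mod = yv.copy()
    y_mod[report.outlier_indices] = report.replacement_values
    if pheno_in is not None:
        return pheno_in.with_values(y_mod), report
    return y_mod, report
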