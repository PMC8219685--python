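"""Kinship, REML variance components and association scans."""

import numpy as np
import pytest
from scipy import stats

from rgwas.datatypes import GenotypeMatrix
from rgwas.io import genomic_inflation
from rgwas.lmm import (
    FastScanContext,
    KinshipMatrix,
    compute_kinship,
    lmm_association_scan,
    lrm_association_scan,
    reml_fit,
    _restricted_loglik,
)
from rgwas.simulate import SimDesign, simulate_dataset


def _toy_gmat(D):
    D = np.asarray(D, dtype=float)
    n, m = D.shape
    return GenotypeMatrix(D, [f"s{j}" for j in range(m)], np.ones(m, int),
                          np.arange(1, m + 1), [f"i{i}" for i in range(n)])


class TestKinship:
    def test_hand_example_homozygous_minor(self):
        # one SNP, f = 0.5; dosages (2, 2): k = (2-1)(2-1)/(2*0.5*0.5) = 2
        K = compute_kinship(np.array([[2.0], [2.0], [0.0], [0.0]]))
        assert K.values[0, 1] == pytest.approx(2.0)

    def test_hand_example_heterozygous(self):
        # dosages (1, 1) at f = 0.5 are exactly the population mean: k = 0
        K = compute_kinship(np.array([[1.0], [1.0], [0.0], [2.0]]))
        assert K.values[0, 1] == pytest.approx(0.0)

    def test_column_order_invariance(self, rng):
        D = rng.integers(0, 3, size=(40, 25)).astype(float)
        perm = rng.permutation(25)
        K1 = compute_kinship(D)
        K2 = compute_kinship(D[:, perm])
        np.testing.assert_allclose(K1.values, K2.values, atol=1e-12)
        assert K1.n_snps_used == K2.n_snps_used

    def test_monomorphic_excluded_and_all_monomorphic_errors(self):
        D = np.column_stack([np.full(10, 2.0), np.tile([0.0, 2.0], 5)])
        K = compute_kinship(D)
        assert K.n_snps_used == 1
        with pytest.raises(ValueError):
            compute_kinship(np.full((10, 3), 1.0 + 1.0))  # all dosage 2

    def test_symmetric_finite(self, small_dataset):
        K = compute_kinship(small_dataset.genotypes)
        np.testing.assert_allclose(K.values, K.values.T)
        assert np.isfinite(K.values).all()


class TestRemlFit:
    def test_k_zero_degenerates_to_ols(self, rng):
        n = 80
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = X @ [1.0, 2.0] + rng.normal(size=n)
        fit = reml_fit(y, X, np.zeros((n, n)))
        beta_ols, res, *_ = np.linalg.lstsq(X, y, rcond=None)
        np.testing.assert_allclose(fit.a_hat, beta_ols, atol=1e-8)
        assert fit.sigma_e2 == pytest.approx(res[0] / (n - 2), rel=1e-6)

    def test_reml_profile_matches_projected_eigenvalue_form(self, rng):
        """Dual route: the rotated-GLS restricted likelihood must equal the
        classic formulation on the nonzero eigenvalues of S (ZKZ') S."""
        n, q = 60, 2
        G = rng.integers(0, 3, size=(n, 100)).astype(float)
        K = compute_kinship(G).values
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = rng.normal(size=n) + G[:, 0]
        xi, U = np.linalg.eigh(0.5 * (K + K.T))
        xi = np.maximum(xi, 0)
        yt, Xt = U.T @ y, U.T @ X
        _, logdet_xx = np.linalg.slogdet(X.T @ X)
        # oracle: EMMA-style eigenvalues of K projected onto an explicit
        # orthonormal basis of the complement of col(X)
        Qx, _ = np.linalg.qr(X, mode="complete")
        B = Qx[:, q:]  # n x (n - q)
        lam_s, W = np.linalg.eigh(B.T @ (0.5 * (K + K.T)) @ B)
        lam_s = np.maximum(lam_s, 0)
        eta2 = ((B @ W).T @ y) ** 2
        for delta in (1e-3, 0.1, 1.0, 10.0, 1e3):
            ref = 0.5 * ((n - q) * np.log((n - q) / (2 * np.pi)) - (n - q)
                         - (n - q) * np.log((eta2 / (lam_s + delta)).sum())
                         - np.log(lam_s + delta).sum())
            got = _restricted_loglik(delta, yt, Xt, np.maximum(xi, 0),
                                     logdet_xx)
            assert got == pytest.approx(ref, abs=1e-6)

    def test_optimum_beats_grid(self, small_dataset):
        K = compute_kinship(small_dataset.genotypes)
        y = small_dataset.phenotype_clean.values
        fit = reml_fit(y, None, K)
        X = np.ones((y.size, 1))
        xi, U = fit.eigenvalues, fit.eigenvectors
        yt, Xt = U.T @ y, U.T @ X
        _, logdet_xx = np.linalg.slogdet(X.T @ X)
        for d in np.logspace(-5, 5, 100):
            assert fit.loglik >= _restricted_loglik(
                d, yt, Xt, xi, logdet_xx) - 1e-8

    def test_delta_recovery_on_known_components(self, rng):
        """Generating delta = sigma_e2/sigma_g2 is recovered on average."""
        n = 250
        G = rng.integers(0, 3, size=(n, 400)).astype(float)
        K = compute_kinship(G).values
        L = np.linalg.cholesky(K + 1e-6 * np.eye(n))
        true_delta = 1.0  # sigma_g2 = sigma_e2 = 1
        rel_err = []
        for _ in range(30):
            u = L @ rng.normal(size=n)
            y = 2.0 + u + rng.normal(size=n)
            fit = reml_fit(y, None, K)
            rel_err.append(fit.delta / true_delta)
        assert abs(np.median(rel_err) - 1.0) < 0.25

    def test_rank_deficient_design_rejected(self, rng):
        n = 30
        X = np.ones((n, 2))
        with pytest.raises(ValueError):
            reml_fit(rng.normal(size=n), X, np.eye(n))


class TestScans:
    def test_null_pvalues_uniform_with_k_zero(self, rng):
        n, m = 500, 2000
        D = rng.integers(0, 3, size=(n, m)).astype(float)
        y = rng.normal(size=n)
        res = lmm_association_scan(y, D, np.zeros((n, n)), mode="fast")
        ks = stats.kstest(res["pvalue"], "uniform")
        assert ks.pvalue > 0.01

    def test_k_zero_matches_lrm(self, rng):
        n, m = 120, 60
        D = rng.integers(0, 3, size=(n, m)).astype(float)
        y = rng.normal(size=n) + 0.5 * D[:, 10]
        a = lmm_association_scan(y, D, np.zeros((n, n)), mode="fast")
        b = lrm_association_scan(y, D)
        np.testing.assert_allclose(a["pvalue"], b["pvalue"], atol=1e-6)
        np.testing.assert_allclose(a["F"], b["F"], rtol=1e-6)

    def test_perfect_fit_guard(self):
        n = 50
        D = np.tile([0.0, 1.0, 2.0], 17)[:n].reshape(-1, 1)
        y = 3.0 * D[:, 0]  # exactly linear, no noise
        res = lrm_association_scan(y, D)
        assert res["pvalue"].iloc[0] <= 1e-290

    def test_monomorphic_snp_flagged_p1(self, rng):
        n = 60
        D = np.column_stack([np.full(n, 1.0),
                             rng.integers(0, 3, n).astype(float)])
        res = lrm_association_scan(rng.normal(size=n), D)
        assert res["pvalue"].iloc[0] == 1.0
        assert res["F"].iloc[0] == 0.0

    def test_shift_scale_invariance(self, small_dataset):
        K = compute_kinship(small_dataset.genotypes)
        y = small_dataset.phenotype_clean.values
        a = lmm_association_scan(y, small_dataset.genotypes, K, mode="fast")
        b = lmm_association_scan(3.0 + 2.5 * y, small_dataset.genotypes, K,
                                 mode="fast")
        np.testing.assert_allclose(
            -np.log10(a["pvalue"]), -np.log10(b["pvalue"]), atol=1e-6)

    def test_fast_and_exact_modes_agree(self, small_dataset):
        K = compute_kinship(small_dataset.genotypes)
        y = small_dataset.phenotype_clean.values
        fast = lmm_association_scan(y, small_dataset.genotypes, K, mode="fast")
        exact = lmm_association_scan(y, small_dataset.genotypes, K,
                                     mode="exact")
        dlp = np.abs(np.log10(fast["pvalue"]) - np.log10(exact["pvalue"]))
        assert (dlp < 0.5).mean() >= 0.95

    def test_context_scan_matches_function(self, small_dataset):
        K = compute_kinship(small_dataset.genotypes)
        y = small_dataset.phenotype_observed.values
        ctx = FastScanContext(small_dataset.genotypes.dosages, K.values)
        res = lmm_association_scan(y, small_dataset.genotypes, K, mode="fast")
        np.testing.assert_allclose(ctx.scan(y)["pvalue"], res["pvalue"],
                                   rtol=1e-8)

    def test_lmm_calibrated_lrm_inflated_under_structure(self):
        """On a structured null (no causal SNPs) the kinship correction
        keeps lambda near 1 while plain regression inflates."""
        ds = simulate_dataset(SimDesign(n=500, m_snps=600, h2_main=0.0),
                              seed=42)
        K = compute_kinship(ds.genotypes)
        y = ds.phenotype_clean.values
        lam_lmm = genomic_inflation(
            lmm_association_scan(y, ds.genotypes, K, mode="fast")["pvalue"])
        lam_lrm = genomic_inflation(
            lrm_association_scan(y, ds.genotypes)["pvalue"])
        assert 0.85 < lam_lmm < 1.15
        assert lam_lrm > lam_lmm + 0.1
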