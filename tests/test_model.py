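"""Mixed-model equations: variance components, assembly, solvers (against a
dense generalized-ridge oracle), Wald tests and Bonferroni control."""

import numpy as np
import pandas as pd
import pytest

from blupgwas.model import (
    AssociationResult,
    CollinearityError,
    DegeneratePhenotypeError,
    MMESystem,
    bonferroni,
    build_mme,
    estimate_variances,
    rank_hits,
    solve_mme,
    wald_test,
)
from tests.conftest import make_variants


def ridge_oracle(X, Z, y, lam):
    """Independent generalized-ridge solve: augmented least squares
    [[X, Z], [0, sqrt(lam) I]] against [y; 0]."""
    n, p = X.shape
    q = Z.shape[1]
    A = np.vstack(
        [np.hstack([X, Z]),
         np.hstack([np.zeros((q, p)), np.sqrt(lam) * np.eye(q)])]
    )
    b = np.concatenate([y, np.zeros(q)])
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    return sol[:p], sol[p:]


def random_instance(rng, n=None, q=None):
    n = n or int(rng.integers(10, 200))
    q = q or int(rng.integers(1, 500))
    X = np.column_stack(
        [np.ones(n), rng.uniform(20, 80, n), rng.integers(0, 2, n)]
    )
    Z = rng.integers(0, 3, size=(n, q)).astype(float)
    y = rng.integers(0, 2, n).astype(float)
    if y.min() == y.max():
        y[0] = 1 - y[0]
    return X, Z, y


class TestEstimateVariances:
    def test_balanced_binary_example(self):
        spec = estimate_variances(np.array([0.0, 0, 1, 1]))
        assert spec.sigma_y2 == pytest.approx(1 / 3)
        assert spec.sigma_g2 == pytest.approx(0.1)
        assert spec.sigma_e2 == pytest.approx(0.7 / 3)
        assert spec.lam == pytest.approx(7 / 3)

    def test_lambda_is_share_ratio_regardless_of_y(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            y = rng.integers(0, 2, 50).astype(float)
            if y.min() == y.max():
                continue
            assert estimate_variances(y).lam == pytest.approx(7 / 3, abs=1e-12)

    def test_study_sized_response_variance(self):
        y = np.array([1.0] * 235 + [0.0] * 306)
        spec = estimate_variances(y)
        assert spec.sigma_y2 == pytest.approx(np.var(y, ddof=1), abs=1e-15)

    def test_scaled_mode_divides_by_variance_mass(self):
        y = np.array([0.0, 0, 1, 1])
        freqs = np.array([0.1, 0.5])
        spec = estimate_variances(y, variance_mode="scaled", allele_freqs=freqs)
        mass = 2 * np.sum(freqs * (1 - freqs))
        assert spec.sigma_g2 == pytest.approx(0.3 * (1 / 3) / mass)
        assert spec.sigma_e2 == pytest.approx(0.7 / 3)
        assert spec.lam == pytest.approx(spec.sigma_e2 / spec.sigma_g2)

    def test_constant_y_rejected(self):
        with pytest.raises(DegeneratePhenotypeError):
            estimate_variances(np.ones(10))


class TestBuildMme:
    def test_single_sample_single_snp_entries(self):
        spec = estimate_variances(np.array([0.0, 0, 1, 1]))
        z = 2.0
        system = build_mme(
            np.ones((1, 1)), np.array([[z]]), np.array([1.0]), spec
        )
        C = system.coefficient_matrix()
        assert C == pytest.approx(
            np.array([[1.0, z], [z, z * z + spec.lam]])
        )

    def test_zero_snp_column_diagonal_is_lambda(self):
        spec = estimate_variances(np.array([0.0, 1, 1]))
        system = build_mme(
            np.ones((3, 1)), np.zeros((3, 1)), np.array([0.0, 1, 1]), spec
        )
        assert system.coefficient_matrix()[1, 1] == pytest.approx(spec.lam)

    def test_coefficient_matrix_matches_dense_assembly(self):
        rng = np.random.default_rng(2)
        X, Z, y = random_instance(rng, n=30, q=8)
        spec = estimate_variances(y)
        system = build_mme(X, Z, y, spec)
        A = np.hstack([X, Z])
        expected = A.T @ A
        expected[3:, 3:] += spec.lam * np.eye(8)
        assert np.allclose(system.coefficient_matrix(), expected)
        assert np.allclose(
            system.rhs(), np.concatenate([X.T @ y, Z.T @ y])
        )

    def test_matvec_agrees_with_dense(self):
        rng = np.random.default_rng(3)
        X, Z, y = random_instance(rng, n=25, q=12)
        system = build_mme(X, Z, y, estimate_variances(y))
        v = rng.standard_normal(3 + 12)
        assert np.allclose(system.matvec(v), system.coefficient_matrix() @ v)

    def test_collinear_fixed_effects_rejected(self):
        X = np.column_stack([np.ones(5), np.ones(5)])
        with pytest.raises(CollinearityError, match="column 1"):
            build_mme(
                X, np.zeros((5, 1)), np.array([0.0, 1, 0, 1, 0]),
                estimate_variances(np.array([0.0, 1, 0, 1, 0])),
            )


class TestSolveMme:
    def test_zero_rhs_gives_zero_solution(self):
        system = MMESystem(
            np.ones((4, 1)), np.eye(4), np.zeros(4), lam=7 / 3
        )
        for method in ("direct", "pcg"):
            fit = solve_mme(system, method=method)
            assert np.all(fit.beta_hat == 0) and np.all(fit.g_hat == 0)

    def test_frozen_small_instance(self):
        # 4 samples, intercept + 2 SNPs, lam=7/3: dense-inversion oracle
        # gives beta = 1/26, g = (6/26, 6/26)
        X = np.ones((4, 1))
        Z = np.array([[0.0, 1], [1, 0], [2, 1], [1, 2]])
        y = np.array([0.0, 0, 1, 1])
        fit = solve_mme(MMESystem(X, Z, y, lam=7 / 3), method="direct")
        assert fit.beta_hat == pytest.approx([1 / 26], abs=1e-12)
        assert fit.g_hat == pytest.approx([6 / 26, 6 / 26], abs=1e-12)

    def test_infinite_shrinkage_limit_recovers_ols(self):
        rng = np.random.default_rng(4)
        X, Z, y = random_instance(rng, n=50, q=20)
        fit = solve_mme(MMESystem(X, Z, y, lam=1e12), method="direct")
        ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert np.max(np.abs(fit.g_hat)) <= 1e-6 * y.std()
        assert fit.beta_hat == pytest.approx(ols, abs=1e-6)

    def test_direct_matches_ridge_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            X, Z, y = random_instance(rng)
            spec = estimate_variances(y)
            fit = solve_mme(build_mme(X, Z, y, spec), method="direct")
            beta_o, g_o = ridge_oracle(X, Z, y, spec.lam)
            sol = np.concatenate([fit.beta_hat, fit.g_hat])
            oracle = np.concatenate([beta_o, g_o])
            assert np.linalg.norm(sol - oracle) <= 1e-8 * np.linalg.norm(oracle)

    def test_pcg_agrees_with_direct(self):
        rng = np.random.default_rng(6)
        for _ in range(5):
            X, Z, y = random_instance(rng, n=80, q=60)
            system = build_mme(X, Z, y, estimate_variances(y))
            fd = solve_mme(system, method="direct")
            fp = solve_mme(system, method="pcg", tol=1e-10)
            assert fp.rel_residual <= 1e-8
            assert np.allclose(fp.g_hat, fd.g_hat, atol=1e-6)
            assert np.allclose(fp.beta_hat, fd.beta_hat, atol=1e-6)

    def test_shrinkage_monotone_in_lambda(self):
        rng = np.random.default_rng(7)
        X, Z, y = random_instance(rng, n=60, q=30)
        norms = [
            np.linalg.norm(
                solve_mme(MMESystem(X, Z, y, lam), method="direct").g_hat
            )
            for lam in (0.1, 1.0, 10.0, 100.0)
        ]
        assert all(a >= b for a, b in zip(norms, norms[1:]))

    def test_column_permutation_equivariance(self):
        rng = np.random.default_rng(8)
        X, Z, y = random_instance(rng, n=40, q=15)
        spec = estimate_variances(y)
        perm = rng.permutation(15)
        f1 = solve_mme(build_mme(X, Z, y, spec), method="direct")
        f2 = solve_mme(build_mme(X, Z[:, perm], y, spec), method="direct")
        assert np.allclose(f2.g_hat, f1.g_hat[perm], atol=1e-10)
        assert np.allclose(f2.beta_hat, f1.beta_hat, atol=1e-10)


class TestWaldAndBonferroni:
    def wald_result(self, g_hat, sigma_g2=1.0, alpha=0.05):
        m = len(g_hat)
        spec = estimate_variances(np.array([0.0, 0, 1, 1]))
        spec = type(spec)(
            sigma_y2=1.0, sigma_g2=sigma_g2, sigma_e2=1.0,
            genetic_share=0.5, residual_share=0.5,
        )
        from blupgwas.model import ModelFit

        fit = ModelFit(np.zeros(1), np.asarray(g_hat, float), "direct", 1, 0.0)
        return wald_test(fit, spec, make_variants(m), alpha=alpha)

    def test_zero_effect_gives_p_one(self):
        res = self.wald_result([0.0])
        assert res.table["W"].iloc[0] == 0.0
        assert res.table["p"].iloc[0] == 1.0

    def test_quantile_identity(self):
        res = self.wald_result([1.959964])
        assert res.table["p"].iloc[0] == pytest.approx(0.05, abs=1e-6)

    def test_normal_cdf_oracle_values(self):
        res = self.wald_result([0.5, -2.0, 3.0])
        assert res.table["p"].to_numpy() == pytest.approx(
            [0.6171, 0.0455, 0.0027], abs=1e-4
        )

    def test_p_never_exactly_zero(self):
        res = self.wald_result([60.0])
        assert res.table["p"].iloc[0] > 0.0

    def test_sigma_scales_statistic(self):
        res = self.wald_result([1.0], sigma_g2=4.0)
        assert res.table["W"].iloc[0] == pytest.approx(0.5)

    def test_bonferroni_threshold_and_flags(self):
        res = self.wald_result([0.0, 5.0], alpha=0.05)
        assert res.threshold == pytest.approx(0.025)
        res2 = bonferroni(res, alpha=0.01)
        assert res2.threshold == pytest.approx(0.005)
        assert list(res2.table["significant"]) == [False, True]

    def test_bonferroni_study_scale_m(self):
        res = self.wald_result([0.0])
        res = AssociationResult(
            table=res.table, m_tests=15_489_173, alpha=0.05,
            threshold=0.05 / 15_489_173,
        )
        out = bonferroni(res, alpha=0.05)
        assert out.threshold == pytest.approx(0.05 / 15_489_173, rel=1e-12)

    def test_all_p_one_nothing_significant(self):
        res = self.wald_result([0.0, 0.0, 0.0])
        assert not res.table["significant"].any()

    def test_invalid_alpha_rejected(self):
        res = self.wald_result([0.0])
        with pytest.raises(ValueError):
            bonferroni(res, alpha=1.5)


class TestRankHits:
    def test_sorted_by_p(self):
        res = TestWaldAndBonferroni().wald_result([0.1, 3.0, 1.5])
        ranked = rank_hits(res)
        assert list(ranked["snp_id"]) == ["v2", "v3", "v1"]

    def test_ties_broken_by_position(self):
        res = TestWaldAndBonferroni().wald_result([2.0, -2.0, 2.0])
        ranked = rank_hits(res)
        assert list(ranked["pos"]) == sorted(ranked["pos"])

    def test_matches_reference_sort(self):
        rng = np.random.default_rng(9)
        res = TestWaldAndBonferroni().wald_result(rng.standard_normal(50))
        ranked = rank_hits(res)
        expected = res.table.sort_values(
            ["p", "chrom", "pos"], kind="mergesort"
        )["snp_id"].tolist()
        assert list(ranked["snp_id"]) == expected
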