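import numpy as np
import pytest
import scipy.sparse as sp

from sparseped.he import (
    assemble_he_system,
    fit_he,
    he_estimates,
    he_sampling_variance,
    ols_fixed_effects,
)
from sparseped.kinship import CovarianceSet

from .oracles import he_pair_sums


def random_cov_set(n, d, rng, density=0.1):
    mats = []
    for _ in range(d):
        B = sp.random(n, n, density=density,
                      random_state=int(rng.integers(1e6)))
        M = (B @ B.T).toarray()
        scale = np.sqrt(np.outer(np.diag(M) + 1, np.diag(M) + 1))
        mats.append(sp.csr_matrix((M + np.eye(n)) / scale))
    return CovarianceSet(matrices=mats, labels=[f"m{k}" for k in range(d)])


class TestOls:
    def test_intercept_only_gives_mean(self, rng):
        y = rng.standard_normal(30)
        beta, r = ols_fixed_effects(y, np.ones((30, 1)))
        assert beta[0] == pytest.approx(y.mean())
        assert r.sum() == pytest.approx(0.0, abs=1e-10)

    def test_exact_linear_zero_residuals(self, rng):
        C = np.column_stack([np.ones(20), rng.standard_normal(20)])
        y = C @ np.array([2.0, -1.5])
        _, r = ols_fixed_effects(y, C)
        assert np.abs(r).max() < 1e-10

    def test_matches_normal_equations(self, rng):
        C = np.column_stack([np.ones(50), rng.standard_normal((50, 2))])
        y = rng.standard_normal(50)
        beta, _ = ols_fixed_effects(y, C)
        ref = np.linalg.solve(C.T @ C, C.T @ y)
        assert np.abs(beta - ref).max() < 1e-10

    def test_collinear_named(self, rng):
        C = np.ones((10, 2))
        with pytest.raises(np.linalg.LinAlgError, match=r"\[1\]"):
            ols_fixed_effects(rng.standard_normal(10), C)


class TestAssembly:
    def test_identity_degenerate(self):
        M = CovarianceSet([sp.identity(5, format="csr")], ["id"])
        sys_ = assemble_he_system(np.ones(5), M)
        assert sys_.q[0] == 0.0
        assert sys_.S[0, 0] == 0.0

    def test_single_pair_closed_form(self):
        a, n = 0.3, 4
        M = sp.lil_matrix((n, n))
        M.setdiag(1.0)
        M[0, 2] = M[2, 0] = a
        cov = CovarianceSet([M.tocsr()], ["m"])
        r = np.array([1.0, 2.0, -1.5, 0.5])
        sys_ = assemble_he_system(r, cov)
        assert sys_.q[0] == pytest.approx(2 * a * r[0] * r[2])
        assert sys_.S[0, 0] == pytest.approx(2 * a ** 2)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_pair_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n, d = 60, 2
        cov = random_cov_set(n, d, rng)
        r = rng.standard_normal(n)
        sys_ = assemble_he_system(r, cov)
        q_b, S_b = he_pair_sums(r, cov.matrices)
        assert np.abs(sys_.q - q_b).max() < 1e-10
        assert np.abs(sys_.S - S_b).max() < 1e-10

    def test_permutation_equivariance(self, rng):
        n = 40
        cov = random_cov_set(n, 2, rng)
        r = rng.standard_normal(n)
        sys1 = assemble_he_system(r, cov)
        p = rng.permutation(n)
        mats_p = [M.tocsr()[p][:, p] for M in cov.matrices]
        sys2 = assemble_he_system(r[p],
                                  CovarianceSet(mats_p, cov.labels))
        assert np.abs(sys1.q - sys2.q).max() < 1e-9
        assert np.abs(sys1.S - sys2.S).max() < 1e-9

    def test_scaling_property(self, rng):
        n = 30
        cov = random_cov_set(n, 1, rng)
        r = rng.standard_normal(n)
        s1 = assemble_he_system(r, cov)
        s2 = assemble_he_system(3.0 * r, cov)
        assert np.abs(s2.q - 9.0 * s1.q).max() < 1e-9
        assert np.abs(s2.S - s1.S).max() < 1e-12


class TestExclusion:
    def test_excluding_zero_pair_is_noop(self, rng):
        n = 30
        cov = random_cov_set(n, 1, rng, density=0.05)
        M = cov.matrices[0].toarray()
        zero_pairs = [(i, j) for i in range(n) for j in range(i + 1, n)
                      if M[i, j] == 0]
        r = rng.standard_normal(n)
        s0 = assemble_he_system(r, cov)
        s1 = assemble_he_system(r, cov, excluded=zero_pairs[:5])
        assert np.abs(s0.q - s1.q).max() < 1e-12
        assert np.abs(s0.S - s1.S).max() < 1e-12

    def test_exclusion_removes_contribution(self):
        a, n = 0.4, 4
        M = sp.lil_matrix((n, n))
        M.setdiag(1.0)
        M[0, 1] = M[1, 0] = a
        M[2, 3] = M[3, 2] = a
        cov = CovarianceSet([M.tocsr()], ["m"])
        r = np.array([1.0, 1.0, 2.0, 2.0])
        s = assemble_he_system(r, cov, excluded=[(0, 1)])
        # only the (2,3) pair remains
        assert s.q[0] == pytest.approx(2 * a * 4.0)
        assert s.S[0, 0] == pytest.approx(2 * a ** 2)
        assert s.excluded_pairs == 1

    def test_unknown_individual_rejected(self, rng):
        cov = random_cov_set(10, 1, rng)
        with pytest.raises(IndexError):
            assemble_he_system(np.ones(10), cov, excluded=[(0, 99)])


class TestEstimates:
    def test_single_matrix_closed_form(self, rng):
        n = 30
        cov = random_cov_set(n, 1, rng)
        r = rng.standard_normal(n)
        sys_ = assemble_he_system(r, cov)
        fit = he_estimates(sys_)
        M = cov.matrices[0]
        expected = (r @ (M @ r) - M.diagonal() @ r ** 2) / sys_.S[0, 0]
        assert fit.sigma2[0] == pytest.approx(expected)

    def test_matches_pair_regression(self, rng):
        n, d = 60, 3
        cov = random_cov_set(n, d, rng)
        r = rng.standard_normal(n)
        sys_ = assemble_he_system(r, cov)
        fit = he_estimates(sys_)
        rows, Y = [], []
        for i in range(n):
            for j in range(n):
                if i != j:
                    rows.append([cov.matrices[k][i, j] for k in range(d)])
                    Y.append(r[i] * r[j])
        ref, *_ = np.linalg.lstsq(np.asarray(rows), np.asarray(Y),
                                  rcond=None)
        assert np.abs(fit.sigma2 - ref).max() < 1e-8

    def test_singular_system_reports_condition(self, rng):
        n = 20
        cov = random_cov_set(n, 1, rng)
        M = cov.matrices[0]
        dup = CovarianceSet([M, (2.0 * M).tocsr()], ["a", "b"])
        sys_ = assemble_he_system(rng.standard_normal(n), dup)
        with pytest.raises(np.linalg.LinAlgError, match="cond"):
            he_estimates(sys_)

    def test_negative_estimates_warn_unclipped(self):
        M = sp.lil_matrix((4, 4))
        M.setdiag(1.0)
        M[0, 1] = M[1, 0] = 0.5
        cov = CovarianceSet([M.tocsr()], ["m"])
        r = np.array([1.0, -1.0, 0.1, 0.1])  # negative pair product
        sys_ = assemble_he_system(r, cov)
        with pytest.warns(UserWarning, match="negative"):
            fit = he_estimates(sys_)
        assert fit.sigma2[0] < 0


class TestSamplingVariance:
    def setup_fit(self, rng, n=40, d=2):
        cov = random_cov_set(n, d, rng)
        y = rng.standard_normal(n)
        C = np.ones((n, 1))
        beta, r = ols_fixed_effects(y, C)
        sys_ = assemble_he_system(r, cov)
        with pytest.warns(UserWarning):
            fit = he_estimates(sys_, beta)
        return cov, sys_, fit

    def test_exact_matches_dense_traces(self, rng):
        cov, sys_, fit = self.setup_fit(rng)
        covm = he_sampling_variance(sys_, cov, fit, mode="exact")
        d, n = sys_.d, len(sys_.resid)
        Sig = sum(s * M.toarray() for s, M in zip(fit.sigma2, cov.matrices))
        Sig += fit.sigma2_e * np.eye(n)
        til = [M.toarray() - np.diag(M.diagonal()) for M in cov.matrices]
        var_q = np.array(
            [[2 * np.trace(Sig @ til[k] @ Sig @ til[l]) for l in range(d)]
             for k in range(d)]
        )
        Sinv = np.linalg.inv(sys_.S)
        assert np.abs(covm - Sinv @ var_q @ Sinv).max() < 1e-8

    def test_diagonal_sigma_closed_form(self, rng):
        n = 25
        cov = random_cov_set(n, 1, rng)
        r = rng.standard_normal(n)
        sys_ = assemble_he_system(r, cov)
        fit = he_estimates(sys_)
        fit.sigma2 = np.array([0.0])  # makes Sigma_hat diagonal
        fit.sigma2_e = 0.8
        covm = he_sampling_variance(sys_, cov, fit, mode="exact")
        A = cov.matrices[0].toarray()
        til = A - np.diag(np.diag(A))
        closed = 2 * 0.8 ** 2 * (til ** 2).sum()
        assert covm[0, 0] * sys_.S[0, 0] ** 2 == pytest.approx(closed)

    def test_mc_converges_to_exact(self, rng):
        cov, sys_, fit = self.setup_fit(rng)
        ce = he_sampling_variance(sys_, cov, fit, mode="exact")
        cm = he_sampling_variance(sys_, cov, fit, mode="mc",
                                  n_probes=50_000, seed=1)
        assert np.abs(cm - ce).max() / np.abs(ce).max() < 0.01

    def test_probe_count_validated(self, rng):
        cov, sys_, fit = self.setup_fit(rng)
        with pytest.raises(ValueError):
            he_sampling_variance(sys_, cov, fit, mode="mc", n_probes=0)


def test_fit_he_end_to_end(rng):
    n = 80
    cov = random_cov_set(n, 1, rng, density=0.2)
    A = cov.matrices[0].toarray()
    L = np.linalg.cholesky(0.5 * A + 0.5 * np.eye(n))
    C = np.column_stack([np.ones(n), rng.standard_normal(n)])
    y = C @ np.array([1.0, 0.3]) + L @ rng.standard_normal(n)
    fit = fit_he(y, C, cov, se_mode="exact")
    assert fit.se is not None and fit.se[0] > 0
    assert fit.n == n
    assert abs(fit.sigma2[0] - 0.5) < 4 * fit.se[0]
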