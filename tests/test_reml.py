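import numpy as np
import pytest
import scipy.optimize
import scipy.sparse as sp

from sparseped.kinship import CovarianceSet
from sparseped.reml import (
    LmmModel,
    aireml_se,
    beta_mle,
    exact_trace,
    factorize_sigma,
    fit_reml,
    mc_trace,
    reml_gradient,
    restricted_loglik,
)

from .oracles import ai_matrix_dense, gls_beta_dense, restricted_loglik_dense


def toy_model(n=60, d=2, seed=3, density=0.1):
    rng = np.random.default_rng(seed)
    mats = []
    for _ in range(d):
        B = sp.random(n, n, density=density,
                      random_state=int(rng.integers(1e6)))
        M = (B @ B.T).toarray()
        scale = np.sqrt(np.outer(np.diag(M) + 1, np.diag(M) + 1))
        mats.append(sp.csr_matrix((M + np.eye(n)) / scale))
    cov = CovarianceSet(matrices=mats, labels=[f"m{k}" for k in range(d)])
    C = np.column_stack([np.ones(n), rng.standard_normal((n, 2))])
    s2_true = np.linspace(0.3, 0.5, d)
    Sigma = sum(s * M.toarray() for s, M in zip(s2_true, mats))
    Sigma += 0.4 * np.eye(n)
    y = C @ rng.standard_normal(3) * 0.2 + np.linalg.cholesky(
        Sigma) @ rng.standard_normal(n)
    model = LmmModel(y=y, C=C, M=cov)
    return model, Sigma, s2_true


class TestFactorAndBeta:
    def test_beta_reduces_to_ols_when_identity(self):
        model, *_ = toy_model(d=1)
        chol = factorize_sigma(model, [0.0], 1.0)
        beta, _, _ = beta_mle(model, chol)
        ref = np.linalg.lstsq(model.C, model.y, rcond=None)[0]
        assert np.abs(beta - ref).max() < 1e-9

    def test_beta_matches_dense_gls(self):
        model, Sigma, s2 = toy_model(n=100)
        chol = factorize_sigma(model, s2, 0.4)
        beta, _, _ = beta_mle(model, chol)
        assert np.abs(beta - gls_beta_dense(model.y, model.C, Sigma)).max() \
            < 1e-9

    def test_intercept_only_scaled_identity(self):
        rng = np.random.default_rng(0)
        y = rng.standard_normal(50)
        model = LmmModel(y=y, C=np.ones((50, 1)),
                         M=CovarianceSet([], [], n_individuals=50))
        chol = factorize_sigma(model, [], 2.5)
        assert chol.logdet == pytest.approx(50 * np.log(2.5))
        beta, _, _ = beta_mle(model, chol)
        assert beta[0] == pytest.approx(y.mean())


class TestRestrictedLoglik:
    def test_matches_dense(self):
        model, Sigma, s2 = toy_model(n=100)
        chol = factorize_sigma(model, s2, 0.4)
        beta, _, CtSiC = beta_mle(model, chol)
        ll = restricted_loglik(model, chol, beta, CtSiC=CtSiC)
        ref = restricted_loglik_dense(model.y, model.C, Sigma, beta)
        assert ll == pytest.approx(ref, abs=1e-8)

    def test_null_model_closed_form(self):
        """d = 0, intercept only: l_R at sigma2 equals the one-sample
        normal restricted likelihood with divisor n - 1."""
        rng = np.random.default_rng(5)
        n = 40
        y = rng.standard_normal(n)
        model = LmmModel(y=y, C=np.ones((n, 1)),
                         M=CovarianceSet([], [], n_individuals=n))
        s2 = 1.3
        chol = factorize_sigma(model, [], s2)
        beta, _, CtSiC = beta_mle(model, chol)
        ll = restricted_loglik(model, chol, beta, CtSiC=CtSiC)
        rss = np.sum((y - y.mean()) ** 2)
        ref = (
            -0.5 * rss / s2
            - 0.5 * (n - 1) * np.log(2 * np.pi * s2)
            + 0.5 * np.log(n)
            - 0.5 * np.log(n / s2)
            + 0.5 * np.log(n)
        )
        # direct dense evaluation as the cross-check of the closed form
        dense = restricted_loglik_dense(y, np.ones((n, 1)),
                                        s2 * np.eye(n), beta)
        assert ll == pytest.approx(dense, abs=1e-8)

    def test_rank_deficient_C_rejected(self):
        rng = np.random.default_rng(1)
        with pytest.raises(np.linalg.LinAlgError):
            LmmModel(
                y=rng.standard_normal(10),
                C=np.ones((10, 2)),
                M=CovarianceSet([], [], n_individuals=10),
            )


class TestTraces:
    def test_identity_in_expectation(self):
        model, Sigma, s2 = toy_model(n=50, d=1)
        chol = factorize_sigma(model, s2, 0.4)
        # M = Sigma: every probe term is z'z, mean ~ n for any probe count
        est = mc_trace(chol, sp.csc_matrix(Sigma), probes=5, seed=0)
        assert est == pytest.approx(50, rel=0.4)

    def test_converges_to_exact(self):
        model, Sigma, s2 = toy_model(n=50, d=1)
        chol = factorize_sigma(model, s2, 0.4)
        M = model.M.matrices[0]
        exact = exact_trace(chol, M)
        assert exact == pytest.approx(
            np.trace(np.linalg.inv(Sigma) @ M.toarray()), abs=1e-8
        )
        est = mc_trace(chol, M, probes=100_000, seed=1)
        assert abs(est - exact) / exact < 0.005

    def test_seeded_determinism(self):
        model, _, s2 = toy_model(n=50, d=1)
        chol = factorize_sigma(model, s2, 0.4)
        M = model.M.matrices[0]
        a = mc_trace(chol, M, probes=50, seed=7)
        b = mc_trace(chol, M, probes=50, seed=7)
        assert a == b
        assert a != mc_trace(chol, M, probes=50, seed=8)


class TestGradient:
    def test_matches_finite_differences_exact_traces(self):
        model, Sigma, s2_true = toy_model(n=60)
        point = np.array([*s2_true, 0.4])

        def lr(s2v):
            ch = factorize_sigma(model, s2v[:-1], s2v[-1])
            b, _, Ct = beta_mle(model, ch)
            return restricted_loglik(model, ch, b, CtSiC=Ct)

        chol = factorize_sigma(model, point[:-1], point[-1])
        beta, X, CtSiC = beta_mle(model, chol)
        g = reml_gradient(model, chol, beta, exact_traces=True, X=X,
                          CtSiC=CtSiC)
        eps = 1e-6
        for k in range(len(point)):
            e = np.zeros_like(point)
            e[k] = eps
            fd = (lr(point + e) - lr(point - e)) / (2 * eps)
            assert g[k] == pytest.approx(fd, abs=1e-5)

    def test_mc_gradient_converges(self):
        model, _, s2_true = toy_model(n=60)
        chol = factorize_sigma(model, s2_true, 0.4)
        beta, X, CtSiC = beta_mle(model, chol)
        g_exact = reml_gradient(model, chol, beta, exact_traces=True,
                                X=X, CtSiC=CtSiC)
        rng = np.random.default_rng(2)
        Z = rng.standard_normal((model.n, 200_000))
        g_mc = reml_gradient(model, chol, beta, Z=Z, X=X, CtSiC=CtSiC)
        assert np.abs(g_mc - g_exact).max() < 0.05


class TestFit:
    def test_matches_dense_optimum(self):
        model, *_ = toy_model(n=80, d=1)
        fit = fit_reml(model, exact_traces=True, seed=0, ftol=1e-12,
                       gtol=1e-7)

        def neg(theta):
            s2v = np.exp(theta)
            ch = factorize_sigma(model, s2v[:-1], s2v[-1])
            b, _, Ct = beta_mle(model, ch)
            return -restricted_loglik(model, ch, b, CtSiC=Ct)

        ref = scipy.optimize.minimize(
            neg, np.log([0.3, 0.3]), method="Nelder-Mead",
            options={"xatol": 1e-12, "fatol": 1e-13, "maxiter": 10_000},
        )
        assert fit.restricted_ll == pytest.approx(-ref.fun, abs=1e-4)
        assert np.abs(
            np.append(fit.sigma2, fit.sigma2_e) - np.exp(ref.x)
        ).max() < 1e-3

    def test_null_model_recovers_reml_variance(self):
        rng = np.random.default_rng(8)
        n, c = 50, 2
        C = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = C @ np.array([1.0, 0.5]) + 1.7 * rng.standard_normal(n)
        model = LmmModel(y=y, C=C, M=CovarianceSet([], [], n_individuals=n))
        fit = fit_reml(model, exact_traces=True, ftol=1e-12, gtol=1e-8)
        resid = y - C @ np.linalg.lstsq(C, y, rcond=None)[0]
        reml_var = np.sum(resid ** 2) / (n - c)
        assert fit.sigma2_e == pytest.approx(reml_var, rel=1e-4)
        # closed-form standard error of the null-model variance
        expected_se = reml_var * np.sqrt(2.0 / (n - c))
        assert fit.se[-1] == pytest.approx(expected_se, rel=0.05)

    def test_ll_never_below_start(self):
        model, *_ = toy_model(n=60)
        fit = fit_reml(model, seed=3)
        assert fit.restricted_ll >= fit.ll_path[0] - 1e-9

    def test_scale_equivariance(self):
        model, *_ = toy_model(n=60, d=1)
        f1 = fit_reml(model, exact_traces=True, seed=0)
        m2 = LmmModel(y=2.0 * model.y, C=model.C, M=model.M)
        f2 = fit_reml(m2, exact_traces=True, seed=0)
        assert np.abs(4.0 * f1.sigma2 - f2.sigma2).max() < 1e-3
        assert f2.sigma2_e == pytest.approx(4.0 * f1.sigma2_e, rel=1e-3)
        ratio = f2.se / f1.se
        assert np.abs(ratio - 4.0).max() < 0.1

    def test_permutation_invariance(self):
        model, *_ = toy_model(n=50, d=1)
        rng = np.random.default_rng(9)
        p = rng.permutation(50)
        mats_p = [M.tocsr()[p][:, p] for M in model.M.matrices]
        m2 = LmmModel(y=model.y[p], C=model.C[p],
                      M=CovarianceSet(mats_p, model.M.labels))
        f1 = fit_reml(model, exact_traces=True, seed=0)
        f2 = fit_reml(m2, exact_traces=True, seed=0)
        assert np.abs(f1.sigma2 - f2.sigma2).max() < 1e-5
        assert f1.sigma2_e == pytest.approx(f2.sigma2_e, abs=1e-5)


class TestAiStandardErrors:
    def test_matches_dense_ai_matrix(self):
        model, Sigma, s2 = toy_model(n=60)
        chol = factorize_sigma(model, s2, 0.4)
        beta, _, _ = beta_mle(model, chol)
        _, AI = aireml_se(model, chol, beta, n_probes=100)
        mats = [M.toarray() for M in model.M.matrices] + [np.eye(model.n)]
        ref = ai_matrix_dense(model.y, model.C, Sigma, mats)
        assert np.abs(AI - ref).max() < 1e-8

    def test_probe_inflation_factor(self):
        model, Sigma, s2 = toy_model(n=60, d=1)
        chol = factorize_sigma(model, s2, 0.4)
        beta, _, _ = beta_mle(model, chol)
        se100, _ = aireml_se(model, chol, beta, n_probes=100)
        se10, _ = aireml_se(model, chol, beta, n_probes=10)
        assert np.allclose(se10 / se100, 1.1 / 1.01)
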