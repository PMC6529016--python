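"""Restricted maximum likelihood (REML) with stochastic trace gradients.

The model is y ~ N(C beta, Sigma), Sigma = sum_k sigma2_k M^k + sigma2_e I,
with sparse symmetric covariance structures M^k. The restricted
log-likelihood

    l_R = l + (c/2) log 2pi + (1/2) log|C'C| - (1/2) log|C' Sigma^-1 C|
    l   = -(1/2) r' Sigma^-1 r - (1/2) log|Sigma| - (n/2) log 2pi

is maximized over log-variances (an unconstrained parameterization that
keeps Sigma positive definite) with L-BFGS-B, profiling the GLS fixed
effects beta_hat = (C' Sigma^-1 C)^-1 C' Sigma^-1 y at every step.

Every solve against Sigma goes through one sparse Cholesky factorization
per iteration (the symbolic analysis is reused across iterations since the
pattern never changes). The only inexact ingredient is the trace term of
the gradient, tr(Sigma^-1 M^k): it is estimated as E[y' Sigma^-1 M^k
Sigma^-1 y'] over ~100 probe vectors y' ~ N(0, Sigma), drawn once per fit
through fixed standard normal seeds (common random numbers, so the
stochastic gradient field is smooth across iterations). The quadratic and
fixed-effect correction terms are exact. Standard errors come from the
average-information (AI) approximation to the information matrix, scaled
by (1 + 1/n_probes) to account for the Monte-Carlo trace noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.optimize
import scipy.sparse as sp

from .cholesky import IbdProductCholesky, SparseCholesky
from .kinship import CovarianceSet, IbdDecomposition

__all__ = [
    "LmmModel",
    "RemlFit",
    "factorize_sigma",
    "beta_mle",
    "restricted_loglik",
    "mc_trace",
    "exact_trace",
    "reml_gradient",
    "aireml_se",
    "fit_reml",
]

LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class LmmModel:
    """Data and covariance structures of the linear mixed model.

    When the model is additive-only (a single 'ibd' structure spanning the
    whole pedigree) and ``ibd_decomposition`` plus ``parent_matrix``
    (I - B, from :func:`sparseped.kinship.parent_link_matrix`) are
    supplied, Sigma is factorized through the near-fill-free product form
    Sigma = L K L^T instead of a direct sparse Cholesky; results are
    identical, only speed differs.
    """

    y: np.ndarray
    C: np.ndarray
    M: CovarianceSet
    ibd_decomposition: IbdDecomposition | None = None
    parent_matrix: "sp.spmatrix | None" = None

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float)
        self.C = np.asarray(self.C, dtype=float)
        if self.C.ndim == 1:
            self.C = self.C[:, None]
        if len(self.y) != self.C.shape[0] or len(self.y) != self.M.n:
            raise ValueError("y, C and covariance matrices must share n")
        if np.linalg.matrix_rank(self.C) < self.C.shape[1]:
            raise np.linalg.LinAlgError("covariate matrix is rank deficient")

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def c(self) -> int:
        return self.C.shape[1]

    @property
    def d(self) -> int:
        return self.M.d

    def sigma(self, sigma2, sigma2_e) -> sp.csc_matrix:
        """Sigma = sum_k sigma2_k M^k + sigma2_e I (csc, sorted)."""
        S = sp.identity(self.n, format="csc") * float(sigma2_e)
        for s2, Mk in zip(sigma2, self.M.matrices):
            S = S + float(s2) * Mk.tocsc()
        S = S.tocsc()
        S.sort_indices()
        return S

    @property
    def has_product_form(self) -> bool:
        return (
            self.d == 1
            and self.M.labels == ["ibd"]
            and self.ibd_decomposition is not None
            and self.parent_matrix is not None
            and self.parent_matrix.shape[0] == self.n
        )


def factorize_sigma(
    model: LmmModel, sigma2, sigma2_e, ordering: str = "auto",
    previous=None,
):
    """Factorization handle for Sigma (solve / logdet / sample / solve_Lt).

    Uses the additive product form when the model supports it, otherwise a
    direct sparse Cholesky; ``previous`` lets iterative callers reuse the
    symbolic analysis when the pattern is unchanged.
    """
    if model.has_product_form:
        if isinstance(previous, IbdProductCholesky):
            return previous.refactor_components(float(sigma2[0]),
                                                float(sigma2_e))
        return IbdProductCholesky(
            model.parent_matrix, model.ibd_decomposition.H,
            float(sigma2[0]), float(sigma2_e),
        )
    S = model.sigma(sigma2, sigma2_e)
    if (
        isinstance(previous, SparseCholesky)
        and previous.n == S.shape[0]
        and getattr(previous, "_pattern_nnz", None) == S.nnz
    ):
        return previous.refactor(S)
    f = SparseCholesky(S, ordering=ordering)
    f._pattern_nnz = S.nnz
    return f


def beta_mle(model: LmmModel, chol: SparseCholesky):
    """GLS fixed effects beta = (C'S^-1C)^-1 C'S^-1 y via c solves.

    Returns (beta_hat, X = Sigma^-1 C, CtSiC) so callers can reuse the
    solves.
    """
    X = chol.solve(model.C)
    CtSiC = model.C.T @ X
    rhs = X.T @ model.y
    try:
        beta = np.linalg.solve(CtSiC, rhs)
    except np.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError(
            f"C' Sigma^-1 C is singular: {e}"
        ) from e
    return beta, X, CtSiC


def restricted_loglik(model: LmmModel, chol: SparseCholesky, beta,
                      CtSiC=None) -> float:
    """Exact restricted log-likelihood (no Monte-Carlo content)."""
    r = model.y - model.C @ beta
    quad = float(r @ chol.solve(r))
    ll = -0.5 * quad - 0.5 * chol.logdet - 0.5 * model.n * LOG2PI
    if CtSiC is None:
        X = chol.solve(model.C)
        CtSiC = model.C.T @ X
    _, ld_ctc = np.linalg.slogdet(model.C.T @ model.C)
    _, ld_ctsic = np.linalg.slogdet(CtSiC)
    return ll + 0.5 * model.c * LOG2PI + 0.5 * ld_ctc - 0.5 * ld_ctsic


def mc_trace(chol: SparseCholesky, M, probes: int = 100,
             seed: int | None = 0, Z=None) -> float:
    """Monte-Carlo estimate of tr(Sigma^-1 M).

    With y' = L z ~ N(0, Sigma), E[y' Sigma^-1 M Sigma^-1 y'] =
    tr(Sigma^-1 M); each term reduces to w' M w with w = L^-T z (one
    triangular solve per probe). A fixed seed gives a bit-identical
    estimate across runs.
    """
    if Z is None:
        if probes < 1:
            raise ValueError("probes must be >= 1")
        rng = np.random.default_rng(seed)
        Z = rng.standard_normal((chol.n, probes))
    W = chol.solve_Lt(Z)
    MW = M @ W if sp.issparse(M) else np.asarray(M) @ W
    return float(np.mean(np.sum(W * MW, axis=0)))


def exact_trace(chol: SparseCholesky, M) -> float:
    """tr(Sigma^-1 M) by solving against every column of M (dense cost;
    intended for small n and for validating the Monte-Carlo path)."""
    Md = M.toarray() if sp.issparse(M) else np.asarray(M, dtype=float)
    return float(np.trace(chol.solve(Md)))


def _all_traces(model: LmmModel, chol: SparseCholesky, Z, exact: bool):
    """tr(Sigma^-1 M^k) for every structure plus the identity."""
    out = np.empty(model.d + 1)
    if exact:
        for k, Mk in enumerate(model.M):
            out[k] = exact_trace(chol, Mk)
        out[model.d] = exact_trace(chol, sp.identity(model.n, format="csr"))
        return out
    W = chol.solve_Lt(Z)
    for k, Mk in enumerate(model.M):
        out[k] = np.mean(np.sum(W * (Mk @ W), axis=0))
    out[model.d] = np.mean(np.sum(W * W, axis=0))
    return out


def reml_gradient(
    model: LmmModel,
    chol: SparseCholesky,
    beta,
    Z=None,
    probes: int = 100,
    seed: int | None = 0,
    exact_traces: bool = False,
    X=None,
    CtSiC=None,
):
    """Gradient of the restricted log-likelihood w.r.t. each variance
    component (the last entry is sigma2_e, with M = I):

        dl_R/dsigma2_k = (1/2)[ r'S^-1 M^k S^-1 r - tr(S^-1 M^k)
                                + tr((C'S^-1C)^-1 C'S^-1 M^k S^-1 C) ]

    The quadratic and correction terms are exact; the trace term is the
    Monte-Carlo estimate unless ``exact_traces``.
    """
    if Z is None and not exact_traces:
        rng = np.random.default_rng(seed)
        Z = rng.standard_normal((model.n, probes))
    r = model.y - model.C @ beta
    v = chol.solve(r)
    if X is None:
        X = chol.solve(model.C)
    if CtSiC is None:
        CtSiC = model.C.T @ X
    CtSiC_inv = np.linalg.inv(CtSiC)
    traces = _all_traces(model, chol, Z, exact_traces)
    grad = np.empty(model.d + 1)
    for k in range(model.d + 1):
        if k < model.d:
            Mk = model.M.matrices[k]
            quad = float(v @ (Mk @ v))
            corr = float(np.trace(CtSiC_inv @ (X.T @ (Mk @ X))))
        else:
            quad = float(v @ v)
            corr = float(np.trace(CtSiC_inv @ (X.T @ X)))
        grad[k] = 0.5 * (quad - traces[k] + corr)
    return grad


@dataclass
class RemlFit:
    """REML estimates with AI standard errors."""

    sigma2: np.ndarray  # d genetic components
    sigma2_e: float
    se: np.ndarray | None  # d+1 entries (components + noise)
    beta_hat: np.ndarray
    restricted_ll: float
    converged: bool
    labels: list
    n_iter: int = 0
    n_probes: int = 100
    message: str = ""
    ll_path: list = field(default_factory=list)
    ai_matrix: np.ndarray | None = None
    n: int = 0


def aireml_se(model: LmmModel, chol: SparseCholesky, beta,
              n_probes: int = 100):
    """Average-information standard errors at the fitted point.

    AI_kl = (1/2) y'P M^k P M^l P y with P = S^-1 - S^-1C(C'S^-1C)^-1C'S^-1
    approximates the information matrix; standard errors are the square
    roots of the diagonal of its inverse, multiplied by (1 + 1/n_probes)
    to account for the Monte-Carlo trace noise of the point estimates.
    Returns (se, AI).
    """
    _, X, CtSiC = beta_mle(model, chol)
    CtSiC_inv = np.linalg.inv(CtSiC)

    def P_apply(t):
        St = chol.solve(t)
        return St - X @ (CtSiC_inv @ (X.T @ t))

    # P y = Sigma^-1 (y - C beta_hat) when beta_hat is the GLS estimate
    r = model.y - model.C @ beta
    Py = chol.solve(r)
    mats = list(model.M.matrices) + [sp.identity(model.n, format="csr")]
    T = np.column_stack([Mk @ Py for Mk in mats])  # M^k P y
    PT = np.column_stack([P_apply(T[:, k]) for k in range(T.shape[1])])
    AI = 0.5 * (T.T @ PT)
    AI = 0.5 * (AI + AI.T)
    try:
        cov = np.linalg.inv(AI)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None)) * (
            1.0 + 1.0 / n_probes
        )
    except np.linalg.LinAlgError:
        warnings.warn("AI matrix is singular; standard errors set to NaN")
        se = np.full(len(mats), np.nan)
        cov = None
    return se, AI


def fit_reml(
    model: LmmModel,
    probes: int = 100,
    seed: int | None = 0,
    max_iter: int = 200,
    ftol: float = 1e-6,
    gtol: float = 1e-4,
    extra_starts: int = 0,
    exact_traces: bool = False,
    ordering: str = "auto",
    compute_se: bool = True,
) -> RemlFit:
    """Maximize the restricted log-likelihood over log-variances.

    ``extra_starts`` adds randomly perturbed restarts (the stochastic
    objective can have boundary local maxima in very sparse designs);
    the best final restricted likelihood wins. Components that land below
    e^-20 * var(y) are reported as exactly zero.
    """
    n, d = model.n, model.d
    if n <= model.c:
        raise ValueError("need more individuals than covariates")
    rng = np.random.default_rng(seed)
    Z = None if exact_traces else rng.standard_normal((n, probes))
    vary = float(np.var(model.y))
    resid_var = float(
        np.var(model.y - model.C @ np.linalg.lstsq(model.C, model.y,
                                                   rcond=None)[0])
    )
    theta0 = np.full(d + 1, np.log(max(resid_var, 1e-12) / (d + 1)))
    lo = np.log(max(vary, 1e-300)) - 20.0
    hi = np.log(max(vary, 1e-300)) + 5.0
    bounds = [(lo, hi)] * (d + 1)

    state = {"theta": None, "chol": None, "beta": None, "X": None,
             "CtSiC": None, "ll": None}
    ll_path = []

    def refresh(theta):
        if state["theta"] is not None and np.array_equal(theta, state["theta"]):
            return
        s2 = np.exp(theta)
        chol = factorize_sigma(
            model, s2[:d], s2[d], ordering=ordering, previous=state["chol"]
        )
        beta, X, CtSiC = beta_mle(model, chol)
        ll = restricted_loglik(model, chol, beta, CtSiC=CtSiC)
        state.update(theta=theta.copy(), chol=chol, beta=beta, X=X,
                     CtSiC=CtSiC, ll=ll)
        ll_path.append(ll)

    def objective(theta):
        refresh(theta)
        return -state["ll"]

    def gradient(theta):
        refresh(theta)
        g = reml_gradient(
            model, state["chol"], state["beta"], Z=Z,
            exact_traces=exact_traces, X=state["X"], CtSiC=state["CtSiC"],
        )
        return -g * np.exp(theta)  # chain rule to the log scale

    starts = [theta0]
    for _ in range(extra_starts):
        starts.append(theta0 + rng.uniform(-2.0, 2.0, size=d + 1))

    best = None
    for t0 in starts:
        state.update(theta=None, chol=None)
        res = scipy.optimize.minimize(
            objective,
            np.clip(t0, lo, hi),
            jac=gradient,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": max_iter, "ftol": ftol, "gtol": gtol},
        )
        if best is None or -res.fun > -best.fun:
            best = res
    res = best
    theta = res.x
    refresh(theta)
    s2 = np.exp(theta)
    floor = np.exp(-20.0) * vary
    s2 = np.where(s2 < floor, 0.0, s2)
    converged = bool(res.success)
    if not converged:
        warnings.warn(f"REML did not converge: {res.message}")
    se = None
    ai = None
    if compute_se:
        se, ai = aireml_se(model, state["chol"], state["beta"],
                           n_probes=(probes if not exact_traces else 10**9))
    return RemlFit(
        sigma2=s2[:d],
        sigma2_e=float(s2[d]),
        se=se,
        beta_hat=state["beta"],
        restricted_ll=float(state["ll"]),
        converged=converged,
        labels=list(model.M.labels),
        n_iter=int(res.nit),
        n_probes=probes,
        message=str(res.message),
        ll_path=ll_path,
        ai_matrix=ai,
        n=n,
    )
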