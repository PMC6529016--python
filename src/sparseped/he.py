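"""Haseman-Elston (HE) regression for variance components.

HE regression is a method-of-moments estimator: it regresses the products
of phenotype residual pairs (y_i - C_i b)(y_j - C_j b) over all pairs of
distinct individuals on the corresponding entries of the covariance
matrices M^1..M^d. The normal equations of that regression collapse to

    sigma2_hat = S^{-1} q,
    q_k  = sum_{i != j} M^k_ij r_i r_j,
    S_kl = sum_{i != j} M^k_ij M^l_ij,

which are sums over the off-diagonal sparse entries only, so the whole
estimator costs O(nnz) and scales to millions of individuals. The
printed-diagonal correction terms are computed with the matrices' actual
diagonals (1 + f under inbreeding), which reduces to the unit-diagonal
shortcut whenever no individual is inbred.

Specific pairs (e.g. spouses) can be excluded from the regression without
excluding the individuals, by zeroing their entries in every covariance
matrix. The residual variance is not itself a regression coefficient
(diagonal pairs never enter); it is reported as var(r) - sum_k sigma2_k,
clipped at zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .kinship import CovarianceSet

__all__ = [
    "HeSystem",
    "HeFit",
    "ols_fixed_effects",
    "assemble_he_system",
    "he_estimates",
    "he_sampling_variance",
    "fit_he",
]


def ols_fixed_effects(y, C):
    """Ordinary least squares for the fixed effects: b = (C'C)^-1 C'y.

    Returns (beta_hat, residuals). Raises on rank-deficient C, naming the
    collinear columns.
    """
    y = np.asarray(y, dtype=float)
    C = np.asarray(C, dtype=float)
    rank = np.linalg.matrix_rank(C)
    if rank < C.shape[1]:
        # identify a maximal independent prefix to name the offenders
        bad = []
        cols = np.empty((C.shape[0], 0))
        for j in range(C.shape[1]):
            trial = np.column_stack([cols, C[:, j]])
            if np.linalg.matrix_rank(trial) > cols.shape[1]:
                cols = trial
            else:
                bad.append(j)
        raise np.linalg.LinAlgError(
            f"covariate matrix is rank deficient (collinear columns {bad})"
        )
    beta, *_ = np.linalg.lstsq(C, y, rcond=None)
    return beta, y - C @ beta


@dataclass
class HeSystem:
    """Assembled HE normal equations."""

    q: np.ndarray  # d-vector
    S: np.ndarray  # d x d
    resid: np.ndarray
    labels: list
    excluded_pairs: int = 0

    @property
    def d(self) -> int:
        return len(self.q)


def _zero_pairs(M: sp.csr_matrix, pairs) -> sp.csr_matrix:
    """Copy of M with the off-diagonal entries of ``pairs`` set to zero
    (applied symmetrically)."""
    M = M.tocsr(copy=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", sp.SparseEfficiencyWarning)
        for i, j in pairs:
            if i == j:
                continue
            M[i, j] = 0.0
            M[j, i] = 0.0
    M.eliminate_zeros()
    return M


def assemble_he_system(resid, M: CovarianceSet, excluded=None) -> HeSystem:
    """Build q and S over the off-diagonal entries of the covariance set.

    ``excluded`` is an iterable of (i, j) index pairs treated as zero in
    every matrix (both orientations). Entries are summed with the matrices'
    actual diagonals subtracted, i.e. q_k = r'M^k r - sum_i M^k_ii r_i^2.
    """
    r = np.asarray(resid, dtype=float)
    n = len(r)
    mats = []
    n_excl = 0
    excluded = list(excluded or [])
    for i, j in excluded:
        if not (0 <= i < n and 0 <= j < n):
            raise IndexError(f"excluded pair ({i}, {j}) out of range for n={n}")
    if excluded:
        n_excl = len({frozenset((i, j)) for i, j in excluded if i != j})
    for Mk in M:
        mats.append(_zero_pairs(Mk, excluded) if excluded else Mk.tocsr())
    d = len(mats)
    q = np.empty(d)
    S = np.empty((d, d))
    diags = [Mk.diagonal() for Mk in mats]
    for k, Mk in enumerate(mats):
        q[k] = r @ (Mk @ r) - diags[k] @ (r * r)
        for l in range(k, d):
            S[k, l] = S[l, k] = (
                Mk.multiply(mats[l]).sum() - diags[k] @ diags[l]
            )
    return HeSystem(
        q=q, S=S, resid=r, labels=list(M.labels), excluded_pairs=n_excl
    )


@dataclass
class HeFit:
    """HE point estimates with standard errors."""

    sigma2: np.ndarray
    sigma2_e: float
    se: np.ndarray | None
    beta_hat: np.ndarray | None
    labels: list
    excluded_pairs: int = 0
    cov_sigma2: np.ndarray | None = None
    n: int = 0
    settings: dict = field(default_factory=dict)


def he_estimates(sys: HeSystem, beta_hat=None) -> HeFit:
    """Solve sigma2 = S^{-1} q; the residual variance is reported as
    var(resid) - sum(sigma2), clipped at zero.

    Negative point estimates are kept as-is (with a warning): the moment
    estimator is unbiased only when unclipped.
    """
    cond = np.linalg.cond(sys.S)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(
            f"HE system is singular or ill-conditioned (cond={cond:.3g}); "
            "matrices may be proportional or lack off-diagonal structure"
        )
    sigma2 = np.linalg.solve(sys.S, sys.q)
    if np.any(sigma2 < 0):
        warnings.warn(
            "negative HE variance-component estimate(s) reported unclipped"
        )
    sigma2_e = max(float(np.var(sys.resid)) - float(np.sum(sigma2)), 0.0)
    return HeFit(
        sigma2=sigma2,
        sigma2_e=sigma2_e,
        se=None,
        beta_hat=beta_hat,
        labels=sys.labels,
        excluded_pairs=sys.excluded_pairs,
        n=len(sys.resid),
    )


def _sigma_hat(M: CovarianceSet, sigma2, sigma2_e) -> sp.csr_matrix:
    n = M.n
    S = sp.identity(n, format="csr") * float(sigma2_e)
    for s2, Mk in zip(sigma2, M.matrices):
        S = S + float(s2) * Mk.tocsr()
    return S.tocsr()


def he_sampling_variance(
    sys: HeSystem,
    M: CovarianceSet,
    fit: HeFit,
    mode: str = "exact",
    n_probes: int = 100,
    seed: int | None = 0,
):
    """Sampling covariance of the HE estimates: S^-1 var(q) S^-1 with
    var(q)_kl = 2 tr(Sigma_hat Mt^k Sigma_hat Mt^l), Mt = M - diag(M).

    ``mode='exact'`` evaluates the trace through sparse matrix products and
    elementwise sums; ``mode='mc'`` approximates it with ~``n_probes``
    standard normal probe vectors y': E[y' Mt^k Sigma Mt^l y'].
    Updates ``fit.se`` and ``fit.cov_sigma2`` in place and returns the
    covariance matrix.
    """
    if mode not in {"exact", "mc"}:
        raise ValueError(f"mode must be 'exact' or 'mc', got {mode!r}")
    if mode == "mc" and n_probes < 1:
        raise ValueError("n_probes must be >= 1")
    d = sys.d
    Sigma = _sigma_hat(M, fit.sigma2, fit.sigma2_e)
    tilde = []
    for Mk in M:
        T = Mk.tocsr(copy=True)
        T.setdiag(0.0)
        T.eliminate_zeros()
        tilde.append(T)
    var_q = np.empty((d, d))
    if mode == "exact":
        prods = [(Sigma @ T).tocsr() for T in tilde]
        for k in range(d):
            for l in range(k, d):
                t = prods[k].multiply(prods[l].T).sum()
                var_q[k, l] = var_q[l, k] = 2.0 * t
    else:
        rng = np.random.default_rng(seed)
        Y = rng.standard_normal((M.n, n_probes))
        SY = Sigma @ Y
        V = [T @ SY for T in tilde]  # Mt^k Sigma y'
        W = [Sigma @ (T @ Y) for T in tilde]  # Sigma Mt^l y'
        # E[(Sigma y')' Mt^k Sigma (Mt^l y')] = tr(Sigma Mt^k Sigma Mt^l)
        for k in range(d):
            for l in range(k, d):
                est = 0.5 * (
                    np.mean(np.sum(V[k] * W[l], axis=0))
                    + np.mean(np.sum(V[l] * W[k], axis=0))
                )
                var_q[k, l] = var_q[l, k] = 2.0 * est
    Sinv = np.linalg.inv(sys.S)
    cov = Sinv @ var_q @ Sinv
    fit.cov_sigma2 = cov
    fit.se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    fit.settings.update({"se_mode": mode, "n_probes": n_probes})
    return cov


def fit_he(
    y,
    C,
    M: CovarianceSet,
    excluded=None,
    se_mode: str | None = "exact",
    n_probes: int = 100,
    seed: int | None = 0,
) -> HeFit:
    """Two-step HE regression: OLS fixed effects, then moment estimation."""
    beta, resid = ols_fixed_effects(y, C)
    sys = assemble_he_system(resid, M, excluded=excluded)
    fit = he_estimates(sys, beta_hat=beta)
    if se_mode is not None:
        he_sampling_variance(
            sys, M, fit, mode=se_mode, n_probes=n_probes, seed=seed
        )
    return fit
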