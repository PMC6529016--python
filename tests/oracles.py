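"""Independent dense/brute-force reference implementations used by the
tests. Everything here is deliberately O(n^2) or worse and shares no code
with the package's sparse routines."""

import numpy as np


def dense_ibd(father, mother):
    """Classical pairwise recursion for the numerator relationship matrix:
    a_ij = (a_{j,f_i} + a_{j,m_i}) / 2, a_ii = 1 + a_{f_i,m_i} / 2,
    over a topologically ordered pedigree."""
    n = len(father)
    a = np.zeros((n, n))
    for i in range(n):
        f, m = father[i], mother[i]
        for j in range(i):
            v = 0.0
            if f >= 0:
                v += 0.5 * a[j, f]
            if m >= 0:
                v += 0.5 * a[j, m]
            a[i, j] = a[j, i] = v
        a[i, i] = 1.0 + (0.5 * a[f, m] if (f >= 0 and m >= 0) else 0.0)
    return a


def dense_dominance(father, mother, A):
    """Direct evaluation of the dominance approximation on all pairs."""
    n = len(father)
    D = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            fi, mi = father[i], mother[i]
            fj, mj = father[j], mother[j]
            if min(fi, mi, fj, mj) < 0:
                continue
            D[i, j] = 0.25 * (A[fi, fj] * A[mi, mj] + A[fi, mj] * A[mi, fj])
    return D


def he_pair_sums(resid, mats):
    """Brute-force double loop over all ordered pairs of distinct
    individuals for the HE normal equations."""
    d = len(mats)
    n = len(resid)
    q = np.zeros(d)
    S = np.zeros((d, d))
    dense = [np.asarray(M.todense()) for M in mats]
    for k in range(d):
        for i in range(n):
            for j in range(n):
                if i != j:
                    q[k] += dense[k][i, j] * resid[i] * resid[j]
        for l in range(d):
            S[k, l] = sum(
                dense[k][i, j] * dense[l][i, j]
                for i in range(n)
                for j in range(n)
                if i != j
            )
    return q, S


def restricted_loglik_dense(y, C, Sigma, beta):
    """Direct dense evaluation of the restricted log-likelihood."""
    n, c = C.shape
    Si = np.linalg.inv(Sigma)
    r = y - C @ beta
    ll = (
        -0.5 * r @ Si @ r
        - 0.5 * np.linalg.slogdet(Sigma)[1]
        - 0.5 * n * np.log(2 * np.pi)
    )
    return (
        ll
        + 0.5 * c * np.log(2 * np.pi)
        + 0.5 * np.linalg.slogdet(C.T @ C)[1]
        - 0.5 * np.linalg.slogdet(C.T @ Si @ C)[1]
    )


def gls_beta_dense(y, C, Sigma):
    Si = np.linalg.inv(Sigma)
    return np.linalg.solve(C.T @ Si @ C, C.T @ Si @ y)


def ai_matrix_dense(y, C, Sigma, mats):
    """Average-information matrix: AI_kl = y'P M^k P M^l P y / 2 with
    P the projected inverse covariance; ``mats`` includes the identity."""
    Si = np.linalg.inv(Sigma)
    P = Si - Si @ C @ np.linalg.inv(C.T @ Si @ C) @ C.T @ Si
    d = len(mats)
    AI = np.zeros((d, d))
    Py = P @ y
    for k in range(d):
        for l in range(d):
            AI[k, l] = 0.5 * Py @ mats[k] @ P @ mats[l] @ Py
    return AI


def random_pedigree(n, rng, p_founder=0.25, p_single=0.15):
    """Random topologically ordered pedigree arrays (father, mother)."""
    father = np.full(n, -1, dtype=np.int64)
    mother = np.full(n, -1, dtype=np.int64)
    for i in range(2, n):
        u = rng.random()
        if u < p_founder:
            continue
        pa = rng.integers(0, i, size=2)
        if u < p_founder + p_single:
            father[i] = pa[0]
        else:
            father[i], mother[i] = pa[0], pa[1] if pa[1] != pa[0] else -1
    return father, mother
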