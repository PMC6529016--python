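"""Sparse Cholesky factorization for symmetric positive definite matrices.

Implements the classical up-looking algorithm (elimination tree + row
pattern reach, as in Davis' CSparse) compiled with numba, with an optional
reverse-Cuthill-McKee fill-reducing permutation. The factor supports

* ``solve``      -- x = Sigma^{-1} b via forward/backward substitution,
* ``logdet``     -- 2 * sum(log diag L),
* ``sample``     -- draws from N(0, Sigma) as P (L z), z ~ N(0, I),
* ``refactor``   -- renumeric on a matrix with the identical sparsity
                    pattern, reusing the symbolic analysis (the common case
                    in REML iterations where only variance components move).

Results are invariant to the internal permutation; the permutation only
controls fill-in.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from numba import njit
from scipy.sparse.csgraph import reverse_cuthill_mckee

__all__ = ["SparseCholesky", "CholeskyError"]


class CholeskyError(RuntimeError):
    """Matrix is not positive definite (reports the leading index)."""


@njit(cache=True)
def _etree(n, Ap, Ai):  # pragma: no cover
    parent = np.full(n, -1, dtype=np.int64)
    ancestor = np.full(n, -1, dtype=np.int64)
    for k in range(n):
        for p in range(Ap[k], Ap[k + 1]):
            i = Ai[p]
            while i != -1 and i < k:
                inext = ancestor[i]
                ancestor[i] = k
                if inext == -1:
                    parent[i] = k
                i = inext
    return parent


@njit(cache=True)
def _col_counts(n, Ap, Ai, parent):  # pragma: no cover
    w = np.full(n, -1, dtype=np.int64)
    counts = np.ones(n, dtype=np.int64)  # diagonal entries
    for k in range(n):
        w[k] = k
        for p in range(Ap[k], Ap[k + 1]):
            i = Ai[p]
            if i >= k:
                continue
            while w[i] != k:
                counts[i] += 1  # L(k, i) is structurally nonzero
                w[i] = k
                i = parent[i]
    return counts


@njit(cache=True)
def _numeric(n, Ap, Ai, Ax, parent, Lp):  # pragma: no cover
    nnz = Lp[n]
    Li = np.empty(nnz, dtype=np.int64)
    Lx = np.empty(nnz, dtype=np.float64)
    c = Lp[:n].copy()
    w = np.full(n, -1, dtype=np.int64)
    s = np.empty(n, dtype=np.int64)
    x = np.zeros(n, dtype=np.float64)
    for k in range(n):
        # pattern of row k of L: reach of A[0:k, k] in the etree
        top = n
        w[k] = k
        x[k] = 0.0
        for p in range(Ap[k], Ap[k + 1]):
            i = Ai[p]
            if i > k:
                continue
            x[i] = Ax[p]
            length = 0
            while w[i] != k:
                s[length] = i
                length += 1
                w[i] = k
                i = parent[i]
            while length > 0:
                top -= 1
                length -= 1
                s[top] = s[length]
        # sparse triangular solve L[0:k,0:k] l_k^T = A[0:k,k]
        d = x[k]
        x[k] = 0.0
        for t in range(top, n):
            i = s[t]
            lki = x[i] / Lx[Lp[i]]
            x[i] = 0.0
            for p in range(Lp[i] + 1, c[i]):
                x[Li[p]] -= Lx[p] * lki
            d -= lki * lki
            p = c[i]
            c[i] += 1
            Li[p] = k
            Lx[p] = lki
        if d <= 0.0:
            return Li, Lx, k  # not positive definite at leading index k
        p = c[k]
        c[k] += 1
        Li[p] = k
        Lx[p] = np.sqrt(d)
    return Li, Lx, -1


@njit(cache=True)
def _lsolve(n, Lp, Li, Lx, B):  # pragma: no cover
    m = B.shape[1]
    for j in range(n):
        p0 = Lp[j]
        dj = Lx[p0]
        for col in range(m):
            B[j, col] /= dj
        for p in range(p0 + 1, Lp[j + 1]):
            i = Li[p]
            v = Lx[p]
            for col in range(m):
                B[i, col] -= v * B[j, col]


@njit(cache=True)
def _ltsolve(n, Lp, Li, Lx, B):  # pragma: no cover
    m = B.shape[1]
    for j in range(n - 1, -1, -1):
        p0 = Lp[j]
        for p in range(p0 + 1, Lp[j + 1]):
            i = Li[p]
            v = Lx[p]
            for col in range(m):
                B[j, col] -= v * B[i, col]
        dj = Lx[p0]
        for col in range(m):
            B[j, col] /= dj


@njit(cache=True)
def _lmatvec(n, Lp, Li, Lx, Z, out):  # pragma: no cover
    m = Z.shape[1]
    for j in range(n):
        for p in range(Lp[j], Lp[j + 1]):
            i = Li[p]
            v = Lx[p]
            for col in range(m):
                out[i, col] += v * Z[j, col]


class SparseCholesky:
    """Cholesky factor of a sparse SPD matrix, P^T A P = L L^T."""

    def __init__(self, A: sp.spmatrix, ordering: str = "auto"):
        A = sp.csc_matrix(A)
        if A.shape[0] != A.shape[1]:
            raise ValueError("matrix must be square")
        n = A.shape[0]
        self.n = n
        if ordering not in {"auto", "rcm", "natural"}:
            raise ValueError(f"unknown ordering {ordering!r}")
        candidates = {}
        if ordering in ("natural", "auto"):
            candidates["natural"] = np.arange(n, dtype=np.int64)
        if ordering in ("rcm", "auto"):
            candidates["rcm"] = np.asarray(
                reverse_cuthill_mckee(A.tocsr(), symmetric_mode=True),
                dtype=np.int64,
            )
        best = None
        for name, perm in candidates.items():
            B = self._permute(A, perm)
            parent = _etree(n, B.indptr.astype(np.int64), B.indices.astype(np.int64))
            counts = _col_counts(
                n, B.indptr.astype(np.int64), B.indices.astype(np.int64), parent
            )
            nnz = int(counts.sum())
            if best is None or nnz < best[0]:
                best = (nnz, name, perm, B, parent, counts)
        self.nnz_L, self.ordering, self.perm, B, parent, counts = best
        self._parent = parent
        Lp = np.zeros(n + 1, dtype=np.int64)
        np.cumsum(counts, out=Lp[1:])
        self._Lp = Lp
        self._factor(B)

    @staticmethod
    def _permute(A: sp.csc_matrix, perm: np.ndarray) -> sp.csc_matrix:
        B = A[perm][:, perm].tocsc()
        B.sort_indices()
        return B

    def _factor(self, B: sp.csc_matrix):
        Li, Lx, bad = _numeric(
            self.n,
            B.indptr.astype(np.int64),
            B.indices.astype(np.int64),
            B.data.astype(np.float64),
            self._parent,
            self._Lp,
        )
        if bad >= 0:
            raise CholeskyError(
                f"matrix is not positive definite (failure at leading index "
                f"{int(self.perm[bad])})"
            )
        self._Li, self._Lx = Li, Lx

    def refactor(self, A: sp.spmatrix) -> "SparseCholesky":
        """Numeric refactorization for a matrix with the same pattern."""
        A = sp.csc_matrix(A)
        self._factor(self._permute(A, self.perm))
        return self

    @property
    def logdet(self) -> float:
        return 2.0 * float(np.sum(np.log(self._Lx[self._Lp[:-1]])))

    def _as2d(self, b):
        b = np.asarray(b, dtype=np.float64)
        one_d = b.ndim == 1
        if one_d:
            b = b[:, None]
        return np.ascontiguousarray(b), one_d

    def solve(self, b):
        """x = A^{-1} b (b may be a vector or an (n, m) matrix)."""
        b, one_d = self._as2d(b)
        X = b[self.perm].copy()
        _lsolve(self.n, self._Lp, self._Li, self._Lx, X)
        _ltsolve(self.n, self._Lp, self._Li, self._Lx, X)
        out = np.empty_like(X)
        out[self.perm] = X
        return out[:, 0] if one_d else out

    def solve_Lt(self, z):
        """v with v[perm] = L^{-T} z: satisfies v ~ N(0, A^{-1}) for
        z ~ N(0, I), the adjoint of :meth:`sample`."""
        z, one_d = self._as2d(z)
        X = z.copy()
        _ltsolve(self.n, self._Lp, self._Li, self._Lx, X)
        out = np.empty_like(X)
        out[self.perm] = X
        return out[:, 0] if one_d else out

    def sample(self, z):
        """y with y[perm] = L z, so y ~ N(0, A) for z ~ N(0, I)."""
        z, one_d = self._as2d(z)
        out = np.zeros_like(z)
        _lmatvec(self.n, self._Lp, self._Li, self._Lx, z, out)
        y = np.empty_like(out)
        y[self.perm] = out
        return y[:, 0] if one_d else y


@njit(cache=True)
def _csr_unit_lower_solve(n, Ap, Ai, Ax, B):  # pragma: no cover
    """Solve T X = B in place for T unit-lower-triangular in CSR
    (diagonal entries present and equal to 1)."""
    m = B.shape[1]
    for i in range(n):
        for p in range(Ap[i], Ap[i + 1]):
            j = Ai[p]
            if j == i:
                continue
            v = Ax[p]
            for col in range(m):
                B[i, col] -= v * B[j, col]


class IbdProductCholesky:
    """Factorization of Sigma = sg2 * L H L^T + se2 * I through the
    product form Sigma = L K L^T, K = sg2 * H + se2 * (I-B)(I-B)^T.

    ``ImB`` is the unit-lower-triangular half-parent matrix I - B (row i:
    1 at i, -1/2 at each known parent), i.e. the exact inverse of L. K's
    sparsity graph only joins individuals to their parents, children and
    co-parents, so its Cholesky is near fill-free regardless of pedigree
    depth, and log|Sigma| = log|K| because L has a unit diagonal.

    Provides the same contract as :class:`SparseCholesky` (solve, logdet,
    sample, solve_Lt, refactor) for the single-component additive model.
    """

    def __init__(self, ImB: sp.spmatrix, H: np.ndarray, sg2: float,
                 se2: float, previous: "IbdProductCholesky | None" = None):
        self.ImB = ImB.tocsr()
        self.ImB.sort_indices()
        self.H = np.asarray(H, dtype=float)
        self.n = self.ImB.shape[0]
        self._gram = (
            previous._gram if previous is not None
            else (self.ImB @ self.ImB.T).tocsc()
        )
        K = (sp.diags(sg2 * self.H) + se2 * self._gram).tocsc()
        K.sort_indices()
        if previous is not None and previous._K_nnz == K.nnz:
            self._chol_K = previous._chol_K.refactor(K)
        else:
            self._chol_K = SparseCholesky(K)
        self._K_nnz = K.nnz
        self.nnz_L = self._chol_K.nnz_L

    def refactor_components(self, sg2: float, se2: float
                            ) -> "IbdProductCholesky":
        return IbdProductCholesky(self.ImB, self.H, sg2, se2, previous=self)

    @property
    def logdet(self) -> float:
        return self._chol_K.logdet

    def solve(self, b):
        """Sigma^{-1} b = (I-B)^T K^{-1} (I-B) b."""
        return self.ImB.T @ self._chol_K.solve(self.ImB @ np.asarray(b,
                                                                     float))

    def solve_Lt(self, z):
        """v with cov(v) = Sigma^{-1} for z ~ N(0, I)."""
        return self.ImB.T @ self._chol_K.solve_Lt(z)

    def sample(self, z):
        """y ~ N(0, Sigma): y = L w with w ~ N(0, K)."""
        w = self._chol_K.sample(z)
        W, one_d = self._as2d(w)
        X = np.ascontiguousarray(W.copy())
        _csr_unit_lower_solve(
            self.n,
            self.ImB.indptr.astype(np.int64),
            self.ImB.indices.astype(np.int64),
            self.ImB.data,
            X,
        )
        return X[:, 0] if one_d else X

    @staticmethod
    def _as2d(b):
        b = np.asarray(b, dtype=np.float64)
        if b.ndim == 1:
            return b[:, None], True
        return b, False
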