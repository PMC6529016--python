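"""Sparse relationship matrices from pedigrees.

The additive (IBD / numerator) relationship matrix A is built through its
decomposition A = L H L^T, where L is lower triangular in topological order
(L_ij = expected fraction of the genome individual i shares with ancestor j)
and H is the diagonal of Mendelian-sampling variances. Both factors are
computed by the classical Henderson/Quaas recursion over pedigree rows:
row_i(L) = unit self entry + half the father's row + half the mother's row,
with

    H_ii = 0.5 - 0.25 (f_father + f_mother)   (both parents known)
          0.75 - 0.25 f_parent                (one parent known)
          1                                   (founder)

and the inbreeding coefficient f_i = a(father_i, mother_i) / 2 accumulated
on the fly. Dominance and epistatic matrices are derived from A; their
nonzero pattern is a subset of A's pattern, so no thresholding is ever
applied: sparsity comes purely from absent common ancestry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from numba import njit

from .pedigree import Pedigree

__all__ = [
    "IbdDecomposition",
    "CovarianceSet",
    "build_ibd_decomposition",
    "ibd_matrix",
    "dominance_matrix",
    "epistasis_matrix",
    "relationship_degree",
    "ibd_principal_components",
    "build_covariance_set",
]


@njit(cache=True)
def _build_lh(father, mother):  # pragma: no cover - exercised via wrapper
    n = father.shape[0]
    indptr = np.zeros(n + 1, dtype=np.int64)
    cap = max(16, 4 * n)
    idx = np.empty(cap, dtype=np.int32)
    val = np.empty(cap, dtype=np.float64)
    h = np.empty(n, dtype=np.float64)
    f = np.zeros(n, dtype=np.float64)
    nnz = 0
    for i in range(n):
        fa = father[i]
        mo = mother[i]
        fs, fe = (indptr[fa], indptr[fa + 1]) if fa >= 0 else (0, 0)
        ms, me = (indptr[mo], indptr[mo + 1]) if mo >= 0 else (0, 0)
        need = nnz + (fe - fs) + (me - ms) + 1
        if need > cap:
            newcap = max(need, 2 * cap)
            nidx = np.empty(newcap, dtype=np.int32)
            nval = np.empty(newcap, dtype=np.float64)
            nidx[:nnz] = idx[:nnz]
            nval[:nnz] = val[:nnz]
            idx = nidx
            val = nval
            cap = newcap
        # inbreeding: f_i = 0.5 * a(fa, mo); a(fa,mo) = sum L_fa,k L_mo,k H_k
        if fa >= 0 and mo >= 0:
            a_fm = 0.0
            p, q = fs, ms
            while p < fe and q < me:
                cp = idx[p]
                cq = idx[q]
                if cp == cq:
                    a_fm += val[p] * val[q] * h[cp]
                    p += 1
                    q += 1
                elif cp < cq:
                    p += 1
                else:
                    q += 1
            f[i] = 0.5 * a_fm
            h[i] = 0.5 - 0.25 * (f[fa] + f[mo])
        elif fa >= 0:
            h[i] = 0.75 - 0.25 * f[fa]
        elif mo >= 0:
            h[i] = 0.75 - 0.25 * f[mo]
        else:
            h[i] = 1.0
        # merge parent rows scaled by 0.5, then the unit self entry
        p, q = fs, ms
        k = nnz
        while p < fe or q < me:
            if q >= me or (p < fe and idx[p] < idx[q]):
                idx[k] = idx[p]
                val[k] = 0.5 * val[p]
                p += 1
            elif p >= fe or idx[q] < idx[p]:
                idx[k] = idx[q]
                val[k] = 0.5 * val[q]
                q += 1
            else:
                idx[k] = idx[p]
                val[k] = 0.5 * (val[p] + val[q])
                p += 1
                q += 1
            k += 1
        idx[k] = i
        val[k] = 1.0
        k += 1
        nnz = k
        indptr[i + 1] = nnz
    return indptr, idx[:nnz], val[:nnz], h, f


def parent_link_matrix(ped: Pedigree) -> sp.csr_matrix:
    """The unit-lower-triangular matrix I - B, where B holds 1/2 at each
    (child, known parent) position: the exact inverse of L."""
    n = ped.n
    rows = list(range(n))
    cols = list(range(n))
    vals = [1.0] * n
    for i in range(n):
        for p in (int(ped.father[i]), int(ped.mother[i])):
            if p >= 0:
                rows.append(i)
                cols.append(p)
                vals.append(-0.5)
    M = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    M.sort_indices()
    return M


@dataclass
class IbdDecomposition:
    """Sparse factors of the additive relationship matrix A = L H L^T."""

    L: sp.csr_matrix
    H: np.ndarray  # diagonal of H (Mendelian sampling variances)
    inbreeding: np.ndarray  # f_i per individual

    @property
    def n(self) -> int:
        return self.L.shape[0]


def build_ibd_decomposition(ped: Pedigree) -> IbdDecomposition:
    """Henderson recursion over a topologically ordered pedigree."""
    indptr, idx, val, h, f = _build_lh(
        ped.father.astype(np.int64), ped.mother.astype(np.int64)
    )
    L = sp.csr_matrix((val, idx, indptr), shape=(ped.n, ped.n))
    return IbdDecomposition(L=L, H=h, inbreeding=f)


def ibd_matrix(dec: IbdDecomposition) -> sp.csr_matrix:
    """Assemble A = L H L^T with explicit symmetric storage.

    Diagonal entries are 1 + f_i; off-diagonals are the classical numerator
    relationships (0.5 parent-child, 0.5 full sibs, 0.25 half sibs, ...).
    """
    LH = dec.L @ sp.diags(dec.H, format="csr")
    A = (LH @ dec.L.T).tocsr()
    A.sum_duplicates()
    return A


@njit(cache=True)
def _dominance_values(
    indptr, indices, data, father, mother
):  # pragma: no cover
    n = indptr.shape[0] - 1
    out = np.zeros(data.shape[0], dtype=np.float64)

    for i in range(n):
        fi = father[i]
        mi = mother[i]
        for p in range(indptr[i], indptr[i + 1]):
            j = indices[p]
            if j == i:
                out[p] = 1.0
                continue
            if fi < 0 or mi < 0:
                continue
            fj = father[j]
            mj = mother[j]
            if fj < 0 or mj < 0:
                continue
            a1 = _lookup(indptr, indices, data, fi, fj) * _lookup(
                indptr, indices, data, mi, mj
            )
            a2 = _lookup(indptr, indices, data, fi, mj) * _lookup(
                indptr, indices, data, mi, fj
            )
            out[p] = 0.25 * (a1 + a2)
    return out


@njit(cache=True)
def _lookup(indptr, indices, data, i, j):  # pragma: no cover
    lo = indptr[i]
    hi = indptr[i + 1]
    while lo < hi:
        mid = (lo + hi) // 2
        c = indices[mid]
        if c == j:
            return data[mid]
        if c < j:
            lo = mid + 1
        else:
            hi = mid
    return 0.0


def dominance_matrix(ped: Pedigree, A: sp.csr_matrix) -> sp.csr_matrix:
    """Pedigree dominance relationships.

    D_ij = (A[f_i,f_j] A[m_i,m_j] + A[f_i,m_j] A[m_i,f_j]) / 4 for i != j,
    D_ii = 1 by convention. Entries are evaluated only where A_ij != 0 (a
    nonzero IBD relationship is necessary for nonzero dominance), so the
    pattern of D is a subset of A's. Rows of individuals with an unknown
    parent are zero off-diagonal.
    """
    A = A.tocsr()
    A.sort_indices()
    vals = _dominance_values(
        A.indptr,
        A.indices.astype(np.int64),
        A.data,
        ped.father.astype(np.int64),
        ped.mother.astype(np.int64),
    )
    D = sp.csr_matrix((vals, A.indices.copy(), A.indptr.copy()), shape=A.shape)
    D.eliminate_zeros()
    return D


def epistasis_matrix(A: sp.csr_matrix, order: int = 2) -> sp.csr_matrix:
    """Elementwise power of A: (A_kl)^order for `order`-locus epistasis."""
    if order < 2:
        raise ValueError("epistasis order must be >= 2")
    return A.power(order).tocsr()


def relationship_degree(K):
    """Degree of relationship implied by an IBD coefficient: -log2(K) - 1.

    0 for parent-child or full siblings (K = 0.5), 1 for half-sibs,
    grandparents and avuncular pairs (K = 0.25), and so on.
    """
    K = np.asarray(K, dtype=float)
    if np.any(K <= 0):
        raise ValueError("relationship degree is undefined for K <= 0")
    out = -np.log2(K) - 1.0
    return float(out) if out.ndim == 0 else out


def ibd_principal_components(A: sp.spmatrix, k: int, return_eigenvalues=False):
    """Top-k eigenvectors of A (orthonormal, deterministic sign).

    The sign of each eigenvector is fixed so its largest-magnitude
    component is positive; eigenvalues are returned in decreasing order.
    """
    n = A.shape[0]
    if not 1 <= k < n:
        raise ValueError(f"need 1 <= k < n, got k={k}, n={n}")
    v0 = np.full(n, 1.0 / np.sqrt(n))
    w, V = sp.linalg.eigsh(A.asfptype(), k=k, which="LA", v0=v0)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    for j in range(k):
        imax = int(np.argmax(np.abs(V[:, j])))
        if V[imax, j] < 0:
            V[:, j] = -V[:, j]
    return (V, w) if return_eigenvalues else V


@dataclass
class CovarianceSet:
    """Ordered list of sparse symmetric covariance structures M^1..M^d
    sharing one index space with the pedigree they came from."""

    matrices: list
    labels: list
    n_individuals: int | None = None  # required when the set is empty

    @property
    def d(self) -> int:
        return len(self.matrices)

    @property
    def n(self) -> int:
        if self.matrices:
            return self.matrices[0].shape[0]
        if self.n_individuals is None:
            raise ValueError("empty CovarianceSet needs n_individuals")
        return self.n_individuals

    def __iter__(self):
        return iter(self.matrices)

    def subset(self, labels) -> "CovarianceSet":
        pick = [self.labels.index(lb) for lb in labels]
        return CovarianceSet(
            matrices=[self.matrices[i] for i in pick], labels=list(labels)
        )


def build_covariance_set(
    ped: Pedigree, labels=("ibd",), dec: IbdDecomposition | None = None
) -> CovarianceSet:
    """Build the requested relationship matrices on a shared index space.

    Labels: ``ibd``, ``dominance``, ``epistasis<p>`` (p >= 2).
    """
    if dec is None:
        dec = build_ibd_decomposition(ped)
    A = ibd_matrix(dec)
    mats = []
    for lb in labels:
        if lb == "ibd":
            mats.append(A)
        elif lb == "dominance":
            mats.append(dominance_matrix(ped, A))
        elif lb.startswith("epistasis"):
            order = int(lb[len("epistasis"):] or 2)
            mats.append(epistasis_matrix(A, order))
        else:
            raise ValueError(f"unknown covariance matrix label {lb!r}")
    return CovarianceSet(matrices=mats, labels=list(labels))
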