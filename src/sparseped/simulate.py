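"""Pedigree and phenotype simulation with known ground truth.

The generator grows a population generation by generation, mimicking the
demographic shape of large genealogy registries: the first generation has
two individuals and each successive generation is 40% larger, half female
and half male. Within each generation, households are formed at a ratio of
0.625 households per individual; 68% of households are male-female pairs
(the only ones that can become parents) and the rest are singles, and an
individual can sit in any number of households. Every individual outside
the founding generation is born to a randomly chosen pair household from
the previous generation (probability 0.80) or from two generations back
(0.20). Consanguinity, half-siblings and single-parent records arise
implicitly from households being sampled with replacement.

Relatedness sparsity is then tuned by deleting parent-child links uniformly
at random until the IBD matrix has the requested fraction of nonzero
entries (within a relative tolerance), and phenotypes are drawn from
y ~ N(C beta, Sigma) with variance components drawn from U(0,1) and
rescaled to sum to one, 5 binary + 5 normal covariates, and fixed effects
from N(0, 1000/n). The returned phenotype is standardized to unit sample
variance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp
from numba import njit

from .cholesky import CholeskyError, SparseCholesky
from .kinship import (
    CovarianceSet,
    IbdDecomposition,
    build_covariance_set,
    build_ibd_decomposition,
)
from .pedigree import Pedigree

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "generate_pedigree",
    "thin_to_sparsity",
    "estimate_ibd_sparsity",
    "generate_phenotypes",
    "simulate_dataset",
    "run_simulation_study",
    "summarize_rmse",
]


@dataclass
class SimulationConfig:
    """All generator parameters, with the study defaults."""

    n_target: int = 10_000
    growth_rate: float = 1.40
    household_ratio: float = 0.625
    pair_household_frac: float = 0.68
    prev_gen_frac: float = 0.80
    sparsity_target: float | None = None  # e.g. 0.0005 / 0.001 / 0.005
    sparsity_tolerance: float = 0.10
    n_binary_covars: int = 5
    n_normal_covars: int = 5
    beta_variance: float | None = None  # default 1000 / n
    seed: int = 0

    def __post_init__(self):
        if self.n_target < 2:
            raise ValueError("n_target must be >= 2")
        if self.growth_rate <= 1:
            raise ValueError("growth_rate must exceed 1")
        for name in ("household_ratio", "pair_household_frac",
                     "prev_gen_frac"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class GeneratorStats:
    """Bookkeeping recorded while generating a pedigree."""

    generation: np.ndarray  # generation index per individual
    n_generations: int = 0
    n_households: int = 0
    n_pair_households: int = 0
    n_children_assigned: int = 0  # children (gen >= 2) that got parents
    n_children_prev_gen: int = 0  # ... whose household is one gen back
    n_founder_fallback: int = 0  # children left parentless by fallback

    @property
    def pair_household_fraction(self) -> float:
        return self.n_pair_households / self.n_households

    @property
    def prev_generation_fraction(self) -> float:
        return self.n_children_prev_gen / self.n_children_assigned


def generation_sizes(cfg: SimulationConfig) -> list:
    """Generation sizes round(2 * growth^g), truncated so they sum to
    exactly ``n_target``."""
    sizes = []
    total = 0
    g = 0
    while total < cfg.n_target:
        s = max(1, int(round(2 * cfg.growth_rate ** g)))
        s = min(s, cfg.n_target - total)
        sizes.append(s)
        total += s
        g += 1
    return sizes


def generate_pedigree(cfg: SimulationConfig, seed=None,
                      return_stats: bool = False):
    """Grow a pedigree to ``cfg.n_target`` individuals.

    Individual ids are ``I0000001``... in generation order (hence already
    topological). With ``return_stats`` the realized household and
    parent-generation counts are returned alongside.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    sizes = generation_sizes(cfg)
    n = sum(sizes)
    starts = np.concatenate([[0], np.cumsum(sizes)])
    generation = np.concatenate(
        [np.full(s, g, dtype=np.int64) for g, s in enumerate(sizes)]
    )
    # alternate female/male within each generation: exact halves (+-1)
    local = np.concatenate([np.arange(s) for s in sizes])
    is_female = local % 2 == 0

    father = np.full(n, -1, dtype=np.int64)
    mother = np.full(n, -1, dtype=np.int64)
    stats = GeneratorStats(generation=generation)

    pair_hh = []  # per generation: (fathers, mothers) arrays
    for g, s in enumerate(sizes):
        members = np.arange(starts[g], starts[g + 1])
        females = members[is_female[members]]
        males = members[~is_female[members]]
        nh = int(round(cfg.household_ratio * s))
        pair = rng.random(nh) < cfg.pair_household_frac
        if len(females) == 0 or len(males) == 0:
            pair[:] = False
        npair = int(pair.sum())
        hf = rng.choice(females, size=npair) if npair else np.empty(0, int)
        hm = rng.choice(males, size=npair) if npair else np.empty(0, int)
        pair_hh.append((hm, hf))
        stats.n_households += nh
        stats.n_pair_households += npair

        if g == 0:
            continue
        children = members
        use_prev = (
            rng.random(s) < cfg.prev_gen_frac
            if g >= 2
            else np.ones(s, dtype=bool)
        )
        for want_prev in (True, False):
            sel = children[use_prev == want_prev]
            if len(sel) == 0:
                continue
            src = g - 1 if want_prev else g - 2
            alt = g - 2 if (want_prev and g >= 2) else g - 1
            hm_src, hf_src = pair_hh[src]
            realized = src
            if len(hm_src) == 0:  # no pair household in that generation
                hm_src, hf_src = pair_hh[alt]
                realized = alt
            if len(hm_src) == 0:
                stats.n_founder_fallback += len(sel)
                continue
            hh = rng.integers(0, len(hm_src), size=len(sel))
            father[sel] = hm_src[hh]
            mother[sel] = hf_src[hh]
            if g >= 2:
                stats.n_children_assigned += len(sel)
                if realized == g - 1:
                    stats.n_children_prev_gen += len(sel)
    stats.n_generations = len(sizes)

    width = len(str(n))
    ids = np.array([f"I{i:0{width}d}" for i in range(n)], dtype=object)
    sex = np.where(is_female, "female", "male").astype(object)
    ped = Pedigree(ids=ids, father=father, mother=mother, sex=sex)
    return (ped, stats) if return_stats else ped


# ---------------------------------------------------------------------------
# sparsity measurement and edge thinning


@njit(cache=True)
def _sampled_related_fraction(
    father, mother, n_pairs, seed, cap
):  # pragma: no cover
    """Fraction of uniformly sampled (i, j) pairs (diagonal included) whose
    ancestor closures intersect, i.e. with a nonzero IBD entry. Walks whose
    node count exceeds ``cap`` count as related (conservative)."""
    n = father.shape[0]
    mark_i = np.full(n, -1, dtype=np.int64)
    mark_j = np.full(n, -1, dtype=np.int64)
    stack = np.empty(n, dtype=np.int64)
    related = 0
    np.random.seed(seed)
    for t in range(n_pairs):
        i = np.random.randint(0, n)
        j = np.random.randint(0, n)
        if i == j:
            related += 1
            continue
        # ancestor closure of i, marked with stamp t
        top = 1
        stack[0] = i
        mark_i[i] = t
        cnt = 0
        capped = False
        while top > 0:
            top -= 1
            v = stack[top]
            cnt += 1
            if cnt > cap:
                capped = True
                break
            f = father[v]
            if f >= 0 and mark_i[f] != t:
                mark_i[f] = t
                stack[top] = f
                top += 1
            m = mother[v]
            if m >= 0 and mark_i[m] != t:
                mark_i[m] = t
                stack[top] = m
                top += 1
        if capped:
            related += 1
            continue
        # walk ancestors of j, stopping at the first shared node
        hit = False
        top = 1
        stack[0] = j
        mark_j[j] = t
        cnt = 0
        while top > 0:
            top -= 1
            v = stack[top]
            cnt += 1
            if cnt > cap:
                hit = True
                break
            if mark_i[v] == t:
                hit = True
                break
            f = father[v]
            if f >= 0 and mark_j[f] != t:
                mark_j[f] = t
                stack[top] = f
                top += 1
            m = mother[v]
            if m >= 0 and mark_j[m] != t:
                mark_j[m] = t
                stack[top] = m
                top += 1
        if hit:
            related += 1
    return related / n_pairs


def _exact_sparsity(father, mother) -> float:
    """Exact IBD nonzero fraction via the dense pattern recursion
    (quadratic memory; used below a size cutoff and in tests)."""
    n = len(father)
    pat = np.zeros((n, n), dtype=bool)
    for i in range(n):
        f, m = father[i], mother[i]
        if f >= 0:
            pat[i, :i] |= pat[f, :i]
        if m >= 0:
            pat[i, :i] |= pat[m, :i]
        pat[:i, i] = pat[i, :i]
        pat[i, i] = True
    return pat.sum() / float(n) ** 2


_EXACT_N = 4000


def estimate_ibd_sparsity(
    ped: Pedigree, n_pairs: int = 200_000, seed: int = 0,
    cap: int = 100_000
) -> float:
    """Fraction of nonzero IBD entries (including the diagonal).

    Exact below n=4000, otherwise a seeded pair-sampling estimate based on
    ancestor-closure intersection.
    """
    if ped.n <= _EXACT_N:
        return _exact_sparsity(ped.father, ped.mother)
    return float(
        _sampled_related_fraction(
            ped.father.astype(np.int64),
            ped.mother.astype(np.int64),
            n_pairs,
            seed & 0x7FFFFFFF,
            cap,
        )
    )


def thin_to_sparsity(
    ped: Pedigree,
    target: float,
    tol: float = 0.10,
    seed: int = 0,
    n_pairs: int = 200_000,
    n_pairs_final: int = 1_000_000,
):
    """Remove parent-child links uniformly at random until the IBD nonzero
    fraction is within ``tol`` (relative) of ``target``.

    The removal order is a fixed seeded permutation, so the kept set is a
    prefix and sparsity is monotone in the number of kept links; the link
    count is found by a coarse geometric sweep from the sparse side
    followed by bisection. Returns ``(thinned_pedigree, achieved)``; if
    the pedigree is already at or below the target, it is returned
    unchanged with a warning.
    """
    rng = np.random.default_rng(seed)
    child = []
    slot = []
    for i in range(ped.n):
        if ped.father[i] >= 0:
            child.append(i)
            slot.append(0)
        if ped.mother[i] >= 0:
            child.append(i)
            slot.append(1)
    child = np.asarray(child, dtype=np.int64)
    slot = np.asarray(slot, dtype=np.int64)
    E = len(child)
    perm = rng.permutation(E)
    child, slot = child[perm], slot[perm]

    def arrays_for(k):
        fa = np.full(ped.n, -1, dtype=np.int64)
        mo = np.full(ped.n, -1, dtype=np.int64)
        c, s = child[:k], slot[:k]
        fa[c[s == 0]] = ped.father[c[s == 0]]
        mo[c[s == 1]] = ped.mother[c[s == 1]]
        return fa, mo

    sub = [0]

    def sparsity_at(k, pairs=n_pairs):
        fa, mo = arrays_for(k)
        if ped.n <= _EXACT_N:
            return _exact_sparsity(fa, mo)
        sub[0] += 1
        return float(
            _sampled_related_fraction(
                fa, mo, pairs, (seed * 1000003 + sub[0]) & 0x7FFFFFFF,
                100_000,
            )
        )

    def confirmed(k):
        """Fine-grained estimate at k (exact below the size cutoff)."""
        return sparsity_at(k, pairs=n_pairs_final)

    # geometric sweep from the heavily thinned side
    k_lo, k_hi = 0, E
    k = max(1, E // 50)
    while True:
        s = sparsity_at(k)
        if s >= target:
            k_hi = k
            break
        k_lo = k
        if k == E:
            s = confirmed(E)
            if s >= target * (1 - tol):
                return ped, s
            warnings.warn(
                f"pedigree sparsity {s:.3g} is below target {target:.3g}; "
                "returning unthinned pedigree"
            )
            return ped, s
        k = min(E, int(k * 1.25) + 1)
    # bisect on the kept-link count; accept only with a fine-grained
    # confirmation comfortably inside the tolerance band
    k_best, s_best = k_hi, s
    accept_lo, accept_hi = target * (1 - 0.7 * tol), target * (1 + 0.7 * tol)
    while k_hi - k_lo > 1:
        mid = (k_lo + k_hi) // 2
        s = sparsity_at(mid)
        if target * (1 - tol / 2) <= s <= target * (1 + tol / 2):
            s = confirmed(mid)
            if accept_lo <= s <= accept_hi:
                k_best, s_best = mid, s
                break
        if abs(s - target) < abs(s_best - target):
            k_best, s_best = mid, s
        if s < target:
            k_lo = mid
        else:
            k_hi = mid
    fa, mo = arrays_for(k_best)
    thinned = Pedigree(
        ids=ped.ids.copy(), father=fa, mother=mo,
        sex=ped.sex.copy() if ped.sex is not None else None,
    )
    achieved = (
        estimate_ibd_sparsity(thinned, n_pairs=n_pairs_final,
                              seed=seed * 7 + 13)
        if ped.n > _EXACT_N
        else _exact_sparsity(fa, mo)
    )
    if not (target * (1 - tol) <= achieved <= target * (1 + tol)):
        warnings.warn(
            f"achieved sparsity {achieved:.3g} outside +-{tol:.0%} of "
            f"target {target:.3g}"
        )
    logger.info(
        "thinning kept %d/%d links; achieved sparsity %.4g", k_best, E,
        achieved,
    )
    return thinned, achieved


# ---------------------------------------------------------------------------
# phenotypes


@dataclass
class SimulatedDataset:
    """A pedigree, its covariance matrices, and a phenotype with known
    variance components (which sum to exactly 1; the residual component is
    last)."""

    pedigree: Pedigree
    covariances: CovarianceSet
    true_sigma2: np.ndarray  # d genetic components + residual, sums to 1
    C: np.ndarray
    beta: np.ndarray
    y: np.ndarray  # random part has unit variance by construction
    scale: float  # sample sd of y (includes fixed-effect variance)
    covar_names: list
    config: SimulationConfig
    achieved_sparsity: float | None = None
    ibd_decomposition: IbdDecomposition | None = None

    def lmm(self):
        """An :class:`sparseped.reml.LmmModel` over this dataset (wired for
        the fast additive factorization when the model is IBD-only)."""
        from .kinship import parent_link_matrix
        from .reml import LmmModel

        use_fast = self.covariances.labels == ["ibd"] and \
            self.ibd_decomposition is not None
        return LmmModel(
            y=self.y,
            C=self.C,
            M=self.covariances,
            ibd_decomposition=self.ibd_decomposition if use_fast else None,
            parent_matrix=parent_link_matrix(self.pedigree)
            if use_fast else None,
        )

    @property
    def labels(self):
        return list(self.covariances.labels) + ["residual"]


def _component_factor(label: str, Mk, dec: IbdDecomposition | None):
    """A sampler z -> x with cov(x) = Mk."""
    if label == "ibd" and dec is not None:
        L = dec.L
        sqH = np.sqrt(dec.H)

        def draw(z):
            return L @ (sqH * z)

        return draw
    jitter = 0.0
    base = float(Mk.diagonal().mean()) or 1.0
    while True:
        try:
            shifted = Mk if jitter == 0 else (
                Mk + jitter * sp.identity(Mk.shape[0], format="csc")
            )
            f = SparseCholesky(shifted)
            break
        except CholeskyError:
            jitter = base * 1e-10 if jitter == 0 else jitter * 100
            if jitter > base * 1e-4:
                raise
    if jitter:
        logger.info("added diagonal jitter %.3g to factor %s", jitter, label)
    return f.sample


def generate_phenotypes(
    ped: Pedigree,
    M: CovarianceSet,
    cfg: SimulationConfig,
    seed=None,
    dec: IbdDecomposition | None = None,
    achieved_sparsity: float | None = None,
) -> SimulatedDataset:
    """Draw y ~ N(C beta, sum_k sigma2_k M^k + sigma2_e I).

    Variance components (including the residual) are U(0,1) draws rescaled
    to sum to 1, so the random part of the phenotype has unit variance by
    construction and estimation errors read directly as fractions of
    phenotypic variance. Covariates are an intercept, 5 Bernoulli(1/2) and
    5 standard normal columns; fixed effects are N(0, 1000/n). Each
    genetic component is sampled through a factor of its matrix (the IBD
    component uses L sqrt(H) directly). The sample sd of the raw phenotype
    is recorded as ``scale``; y itself is not rescaled, which would bias
    every component by the variance explained by the fixed effects.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n = ped.n
    d = M.d
    s2 = rng.uniform(0.0, 1.0, d + 1)
    s2 = s2 / s2.sum()

    cols = [np.ones(n)]
    names = ["intercept"]
    for b in range(cfg.n_binary_covars):
        cols.append(rng.integers(0, 2, n).astype(float))
        names.append(f"bin{b + 1}")
    for b in range(cfg.n_normal_covars):
        cols.append(rng.standard_normal(n))
        names.append(f"norm{b + 1}")
    C = np.column_stack(cols)
    beta_var = cfg.beta_variance if cfg.beta_variance is not None else 1000.0 / n
    beta = rng.normal(0.0, np.sqrt(beta_var), C.shape[1])

    y = C @ beta
    if d and dec is None and "ibd" in M.labels:
        dec = build_ibd_decomposition(ped)
    for k, (lb, Mk) in enumerate(zip(M.labels, M.matrices)):
        draw = _component_factor(lb, Mk.tocsc(), dec)
        y = y + np.sqrt(s2[k]) * draw(rng.standard_normal(n))
    y = y + np.sqrt(s2[d]) * rng.standard_normal(n)
    scale = float(np.std(y))
    return SimulatedDataset(
        pedigree=ped,
        covariances=M,
        true_sigma2=s2,
        C=C,
        beta=beta,
        y=y,
        scale=scale,
        covar_names=names,
        config=cfg,
        achieved_sparsity=achieved_sparsity,
        ibd_decomposition=dec,
    )


def simulate_dataset(
    cfg: SimulationConfig, matrices=("ibd",), seed=None
) -> SimulatedDataset:
    """Full pipeline: pedigree -> thinning -> matrices -> phenotype.

    All stages draw from child seeds of one seed sequence, so the same
    seed reproduces the dataset exactly.
    """
    s = cfg.seed if seed is None else seed
    root = s if isinstance(s, np.random.SeedSequence) else \
        np.random.SeedSequence(s)
    s_ped, s_thin, s_phen = root.spawn(3)
    ped = generate_pedigree(cfg, seed=s_ped)
    achieved = None
    if cfg.sparsity_target is not None:
        ped, achieved = thin_to_sparsity(
            ped,
            cfg.sparsity_target,
            tol=cfg.sparsity_tolerance,
            seed=int(s_thin.generate_state(1)[0] & 0x7FFFFFFF),
        )
    dec = build_ibd_decomposition(ped)
    M = build_covariance_set(ped, labels=matrices, dec=dec)
    return generate_phenotypes(
        ped, M, cfg, seed=s_phen, dec=dec, achieved_sparsity=achieved
    )


# ---------------------------------------------------------------------------
# RMSE evaluation harness


def run_simulation_study(
    n_values,
    sparsity_values,
    matrix_sets,
    replicates: int = 10,
    estimators=("he", "reml"),
    seed: int = 0,
    he_opts: dict | None = None,
    reml_opts: dict | None = None,
    base_config: SimulationConfig | None = None,
) -> pd.DataFrame:
    """Estimate variance components on simulated datasets across a grid.

    Returns a long-format frame with one row per (setting, replicate,
    estimator, component): columns n, sparsity, matrices, estimator,
    replicate, component, truth, estimate, error. Estimator failures are
    recorded as rows with NaN estimates (and excluded by
    :func:`summarize_rmse`, which reports their count).
    """
    from .he import fit_he
    from .reml import LmmModel, fit_reml

    he_opts = dict(he_opts or {})
    reml_opts = dict(reml_opts or {})
    base = base_config or SimulationConfig()
    rows = []
    for n in n_values:
        for si, sparsity in enumerate(sparsity_values):
            for mi, mats in enumerate(matrix_sets):
                for rep in range(replicates):
                    child = np.random.SeedSequence(
                        [int(seed), int(n), si, mi, rep]
                    )
                    cfg = replace(
                        base, n_target=int(n), sparsity_target=sparsity
                    )
                    ds = simulate_dataset(cfg, matrices=mats, seed=child)
                    fit_seed = int(child.generate_state(2)[1] & 0x7FFFFFFF)
                    for est in estimators:
                        try:
                            if est == "he":
                                fit = fit_he(
                                    ds.y, ds.C, ds.covariances,
                                    se_mode=None, **he_opts,
                                )
                            elif est == "reml":
                                fit = fit_reml(
                                    ds.lmm(), seed=fit_seed,
                                    compute_se=False, **reml_opts,
                                )
                            else:
                                raise ValueError(
                                    f"unknown estimator {est!r}")
                            ests = list(fit.sigma2) + [fit.sigma2_e]
                        except Exception as e:  # recorded, not fatal
                            logger.warning(
                                "%s failed (n=%d rep=%d): %s", est, n, rep, e
                            )
                            ests = [np.nan] * (len(mats) + 1)
                        for comp, tru, est_v in zip(
                            list(mats) + ["residual"], ds.true_sigma2, ests
                        ):
                            rows.append(
                                dict(
                                    n=int(n),
                                    sparsity=sparsity,
                                    matrices="+".join(mats),
                                    estimator=est,
                                    replicate=rep,
                                    component=comp,
                                    truth=float(tru),
                                    estimate=float(est_v),
                                    error=float(est_v - tru),
                                )
                            )
    return pd.DataFrame(rows)


def summarize_rmse(results: pd.DataFrame) -> pd.DataFrame:
    """RMSE pooled over components and replicates, per setting/estimator."""
    def agg(g):
        ok = g["error"].notna()
        return pd.Series(
            {
                "rmse": float(np.sqrt(np.mean(g.loc[ok, "error"] ** 2))),
                "n_estimates": int(ok.sum()),
                "n_failed": int((~ok).sum()),
            }
        )

    return (
        results.groupby(["n", "sparsity", "matrices", "estimator"],
                        dropna=False)
        .apply(agg, include_groups=False)
        .reset_index()
    )
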