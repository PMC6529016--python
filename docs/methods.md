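# Methods

## Model

For $n$ individuals with phenotypes $y$ and covariates $C$ (including an
intercept), the package fits the linear mixed model

$$ y \sim N(C\beta,\ \Sigma), \qquad
   \Sigma = \sum_{k=1}^{d} \sigma_k^2 M^k + \sigma_e^2 I , $$

where each $M^k$ is an $n\times n$ sparse symmetric relationship matrix
derived from a pedigree and $\sigma_1^2,\dots,\sigma_d^2,\sigma_e^2$ are
the variance components to estimate. The central premise is sparsity: a
pair of individuals with no recorded common ancestor has zero entries in
every $M^k$, so population-scale family trees yield matrices with a tiny
fraction of nonzero entries, and everything downstream is built to run in
time and memory proportional to those nonzeros.

## Relationship matrices

**Additive (IBD).** The numerator relationship matrix $A$ (entries
$a_{ij}$, diagonal $1+f_i$ with $f_i$ the inbreeding coefficient) is
constructed through its decomposition $A = LHL^\top$ in topological
order: row $i$ of $L$ is the unit self entry plus half of each parent's
row, and $H$ is the diagonal of Mendelian-sampling variances

* $H_{ii} = \tfrac12 - \tfrac14(f_{f_i}+f_{m_i})$ with both parents known,
* $H_{ii} = \tfrac34 - \tfrac14 f_p$ with one known parent $p$,
* $H_{ii} = 1$ for founders.

Inbreeding is accumulated on the fly as $f_i = \tfrac12 a_{f_i m_i}$ via a
sparse dot product of the parents' $L$-rows. $A$ is assembled as
$(LH)L^\top$ with sparse matrix products. An equivalent pairwise
path-counting formula exists but is not used: the recursion is exact,
$O(\mathrm{nnz})$, and testable against a dense oracle. No numerical
thresholding is ever applied; zeros arise only from absent common
ancestry. An individual with exactly one recorded parent is treated as
having a unique, unrelated, non-inbred second parent (the standard
animal-breeding convention).

**Dominance.** $D_{ij} =
\tfrac14(A_{f_if_j}A_{m_im_j} + A_{f_im_j}A_{m_if_j})$ for $i\ne j$,
$D_{ii}=1$, evaluated only where $A_{ij}\ne 0$ (a nonzero additive
relationship is necessary for nonzero dominance), so
$\mathrm{pattern}(D)\subseteq\mathrm{pattern}(A)$. Rows of individuals
with an unknown parent are zero off-diagonal.

**Epistasis.** Order-$p$ multiplicative interactions:
the elementwise power $(A_{ij})^p$, $p\ge 2$, applied to the whole matrix
including the diagonal (the simplest consistent reading; on non-inbred
pedigrees the diagonal stays 1 either way).

**Degree of relationship.** $-\log_2 K - 1$ for an IBD coefficient $K$:
0 for parent-child and full siblings, 1 for half-siblings, etc.

## Pruning

Individuals without phenotype data may still be required: the parents of
two phenotyped siblings carry their relationship even if unphenotyped.
The pruning rule keeps exactly the informative individuals plus everyone
on a lineage path from an informative individual up to a least common
ancestor of an informative pair. Implementation: take the
ancestor closure of the informative set, then repeatedly delete
non-informative members with no retained children, and non-informative
founders (within the subset) with a single retained child, to a fixpoint.
The cascade handles chains of single-child ancestors. This provably
preserves every IBD value among informative individuals — a founder with
one retained child contributes to no relationship, and removing it turns
its child's parent into "unknown founder", which is distributionally
identical — and the property is tested exactly against the dense
recursion on random pedigrees.

## Haseman–Elston regression

The two-step moment estimator: fixed effects by OLS, then regression of
residual pair products on the covariance entries over all pairs of
distinct individuals, which collapses to $\hat\sigma^2 = S^{-1}q$ with

$$ q_k = \sum_{i\ne j} M^k_{ij} r_i r_j, \qquad
   S_{kl} = \sum_{i\ne j} M^k_{ij} M^l_{ij} . $$

Both are $O(\mathrm{nnz})$ elementwise sparse sums. The textbook shortcut
$q_k = y^\top(M^k - I)y$ assumes unit diagonals; we subtract the actual
diagonals so the estimator remains exact under inbreeding (identical when
$\mathrm{diag}=1$). The residual variance is not a regression coefficient
(diagonal pairs never enter); it is reported as
$\mathrm{var}(r) - \sum_k \hat\sigma_k^2$, clipped at zero. Negative
component estimates are reported unclipped with a warning — clipping
would destroy the estimator's unbiasedness.

Sampling covariance: $S^{-1}\,\mathrm{var}(q)\,S^{-1}$ with
$\mathrm{var}(q)_{kl} = 2\,\mathrm{tr}(\hat\Sigma \tilde M^k \hat\Sigma
\tilde M^l)$, $\tilde M = M - \mathrm{diag}(M)$, computed either exactly
(sparse matrix products and an elementwise trace) or by Monte Carlo with
$y'\sim N(0,I)$ probes using the unbiased form
$E[(\hat\Sigma y')^\top \tilde M^k \hat\Sigma (\tilde M^l y')]$
(~100 probes by default; estimates are symmetrized over $(k,l)$).

Pairs can be excluded from the regression (e.g. spouses, to limit shared-
environment confounding) by zeroing their entries in every matrix, both
orientations; the individuals themselves stay in the model.

## REML

The restricted log-likelihood

$$ \ell_R = \ell + \tfrac{c}{2}\log 2\pi + \tfrac12\log|C^\top C|
   - \tfrac12\log|C^\top\Sigma^{-1}C|, \quad
   \ell = -\tfrac12 r^\top\Sigma^{-1}r - \tfrac12\log|\Sigma|
   - \tfrac{n}{2}\log 2\pi $$

is maximized over $\theta_k=\log\sigma_k^2$ (unconstrained; positivity
for free) with L-BFGS-B, profiling the GLS fixed effects
$\hat\beta = (C^\top\Sigma^{-1}C)^{-1}C^\top\Sigma^{-1}y$ at every step
($c$ solves). The gradient is

$$ \frac{\partial\ell_R}{\partial\sigma_k^2} = \tfrac12\left[
   r^\top\Sigma^{-1}M^k\Sigma^{-1}r - \mathrm{tr}(\Sigma^{-1}M^k)
   + \mathrm{tr}\!\big((C^\top\Sigma^{-1}C)^{-1}
     C^\top\Sigma^{-1}M^k\Sigma^{-1}C\big) \right], $$

with $M^{d+1}=I$ for the residual component. The sign conventions were
fixed by validating against central finite differences of $\ell_R$ (some
published statements of these formulas differ in the sign of the
quadratic term). The quadratic and correction terms are exact; the trace
term is the only approximation:
$\mathrm{tr}(\Sigma^{-1}M) = E[y'^\top\Sigma^{-1}M\Sigma^{-1}y']$ for
$y'\sim N(0,\Sigma)$, estimated with (default) 100 probe vectors
$y' = Lz$. The standard normal seeds $z$ are drawn once per fit and
reused across iterations (common random numbers), which makes the
stochastic gradient field smooth and quasi-Newton convergence
well-defined; each probe then costs a single triangular solve,
$w = L^{-\top}z$, and the estimate is $\overline{w^\top M w}$. 100,000
probes reproduce exact traces to <0.5% in tests; with `exact_traces=True`
the whole fit is deterministic (used for oracle comparisons).

Standard errors come from the average-information approximation
$\mathrm{AI}_{kl} = \tfrac12\, y^\top P M^k P M^l P y$ with
$P = \Sigma^{-1}-\Sigma^{-1}C(C^\top\Sigma^{-1}C)^{-1}C^\top\Sigma^{-1}$;
the reported s.e. are the square roots of the diagonal of
$\mathrm{AI}^{-1}$, inflated by $(1 + 1/\text{probes})$ to account for
the Monte-Carlo trace noise.

Defaults: initialization at $\mathrm{var}(\text{OLS residuals})/(d{+}1)$
per component; convergence at relative $\ell_R$ change $<10^{-6}$ and
projected gradient norm $<10^{-4}$ on the log scale; at most 200
iterations; components below $e^{-20}\mathrm{var}(y)$ reported as exact
zeros (the log scale cannot represent zero; very sparse designs can have
boundary maxima). An optional multi-start (`extra_starts`) perturbs the
initialization to guard against those boundary solutions; the squared-
gradient minimization variant found in the literature is deliberately not
implemented for the same reason.

## Sparse Cholesky backends

No CHOLMOD binding is used; the package carries its own up-looking sparse
Cholesky (elimination tree + row-pattern reach, CSparse-style) compiled
with numba, choosing between the natural and reverse-Cuthill-McKee
orderings by predicted fill. It exposes solve, log-determinant, sampling
($y = Lz \sim N(0,\Sigma)$) and numeric refactorization under a fixed
pattern — the per-iteration operation in REML.

For the additive-only model there is an exact product form that sidesteps
fill-in entirely: with $A = LHL^\top$ and $L^{-1} = I-B$ ($B$ the
half-parent matrix, two entries per row),

$$ \Sigma = \sigma_g^2 LHL^\top + \sigma_e^2 I
   = L\,\big(\sigma_g^2 H + \sigma_e^2 (I{-}B)(I{-}B)^\top\big)\,L^\top
   = L K L^\top , $$

where $K$'s graph joins only parents, children and co-parents (~7
nonzeros per row regardless of pedigree depth) and
$\log|\Sigma| = \log|K|$ since $L$ is unit triangular. Solves, sampling
and log-determinants all route through $\mathrm{chol}(K)$ and the sparse
triangular $I-B$. This cuts an $n{=}50{,}000$ REML fit from minutes per
iteration to about a second, with results identical to the direct
factorization (tested to $10^{-8}$). It is used automatically whenever
the model contains exactly the IBD matrix over a full pedigree.

## Synthetic data

The generator emulates the demographic shape of large genealogy
registries. Defaults (all overridable in `SimulationConfig`):

| parameter | default | meaning |
|---|---|---|
| `growth_rate` | 1.40 | per-generation size multiplier, from 2 founders |
| `household_ratio` | 0.625 | households per individual per generation |
| `pair_household_frac` | 0.68 | households that are male-female pairs |
| `prev_gen_frac` | 0.80 | children with parents one generation back (else two) |
| `sparsity_target` | none | IBD nonzero fraction after edge thinning |
| `sparsity_tolerance` | 0.10 | relative tolerance on the target |
| `n_binary_covars` / `n_normal_covars` | 5 / 5 | covariate design |
| `beta_variance` | 1000/n | fixed-effect variance |

Generation sizes are $\mathrm{round}(2\cdot 1.4^g)$, truncated to hit the
requested $n$ exactly; sexes alternate within a generation (exact halves
up to rounding); pair households draw one female and one male uniformly
with replacement, so an individual can sit in several households and
consanguinity, half-siblings and single-parent records arise implicitly.
Children of the first post-founder generation necessarily use the
previous generation; if the chosen generation happens to contain no pair
household the other one is tried, and failing that the child is recorded
parentless.

Sparsity is tuned by deleting parent-child links uniformly at random. The
kept set is a prefix of one seeded permutation, so the nonzero fraction
is monotone in the number of kept links; a geometric sweep from the
sparse side plus bisection finds the count whose (estimated) sparsity
falls within the tolerance band. The IBD nonzero fraction itself is
measured exactly below $n=4000$ (dense pattern recursion) and otherwise
by seeded pair sampling with an early-exit ancestor-closure intersection
test; accepted candidates are confirmed at 10^6 sampled pairs (≈3%
relative noise at a target of 0.001, well inside the ±10% band).

Phenotypes: variance components (including residual) drawn $U(0,1)$ and
rescaled to sum to exactly 1; intercept + 5 binary + 5 normal covariates;
$\beta \sim N(0, 1000/n)$; each genetic component sampled through a
factor of its matrix (the IBD component via $L\sqrt{H}z$, others via a
sparse Cholesky, with an escalating diagonal jitter from $10^{-10}$ of
the mean diagonal only if the matrix is numerically semidefinite). The
random part of $y$ therefore has unit variance by construction and
estimation errors read as fractions of phenotypic variance; $y$ is *not*
divided by its sample standard deviation, since that includes the
fixed-effect variance and would bias every component downward by
$1/\mathrm{sd}^2(y)$.

What the generator does **not** emulate: real mortality and record-
quality processes, assortative mating, genetic nurture, shared-household
environmental covariance, or any correlation between covariates and
genetic values. Passing tests therefore demonstrate correctness of the
estimators *under the model's own assumptions* — unbiasedness and
calibrated uncertainties when the covariance structure is correctly
specified — not robustness to the confounding that real genealogies
carry.

## Study harness and problem sizes

`run_simulation_study` fits HE and/or REML over a grid of sample sizes,
sparsity factors and matrix subsets, recording per-component errors;
`summarize_rmse` pools the squared errors over components and replicates
(the RMSE of an experiment with $d{+}1$ components is the root mean of
their squared errors). Estimator failures are recorded and excluded from
the RMSE with a count. The package's own accuracy checks use 3 replicates
at $n=250{,}000$ (HE, sparsity 0.001) and 10 replicates at $n=50{,}000$
(HE and REML); these sizes keep a full verification run in tens of
minutes on one CPU while leaving the Monte-Carlo error of the checks well
below the tolerances they assert.

## Numerical notes and limitations

* All randomness flows from `numpy` `SeedSequence`s; one seed reproduces
  a dataset byte-for-byte, and fits with fixed seeds are bit-identical.
* The HE system solve refuses condition numbers above $10^{12}$
  (proportional matrices); the factorization reports the leading index at
  which positive-definiteness fails.
* Principal components use a deterministic start vector and fix each
  eigenvector's sign by its largest-magnitude component.
* Pair exclusion applies to HE only; excluding pairs under REML could
  make $\Sigma$ indefinite and is not offered.
* REML cost is dominated by one sparse refactorization per objective
  evaluation in the general (multi-matrix) case; very large multi-matrix
  fits are better served by HE, whose cost is a few elementwise passes
  over the nonzeros.
* The dominance matrix is a classical approximation and is not guaranteed
  positive semidefinite on inbred pedigrees; the simulator's factor adds
  a vanishing diagonal jitter in that case.
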