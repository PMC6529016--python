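"""Model/results front-end for pedigree variance-component estimation.

`PedigreeVarianceModel` bundles a phenotype, covariates and a set of sparse
relationship matrices; ``fit(method="reml")`` or ``fit(method="he")``
returns a results object carrying estimates, standard errors and a
``summary()`` table, in the spirit of statsmodels model/results pairs.

    >>> model = PedigreeVarianceModel.from_pedigree(ped, pheno_df,
    ...     pheno_col="y", covar_cols=["sex"], matrices=("ibd",))
    >>> res = model.fit(method="he")
    >>> print(res.summary())
"""

from __future__ import annotations

import numpy as np

from . import he as _he
from . import reml as _reml
from .kinship import CovarianceSet, build_covariance_set
from .pedigree import Pedigree, align_phenotypes, prune_uninformative

__all__ = ["PedigreeVarianceModel", "VarianceComponentResults"]


class PedigreeVarianceModel:
    """Linear mixed model y ~ N(C beta, sum_k sigma2_k M^k + sigma2_e I).

    Parameters
    ----------
    y : array
        Phenotype vector.
    C : array
        Covariate matrix including an intercept column.
    covariances : CovarianceSet
        Sparse symmetric relationship matrices on the same index space.
    ids : array, optional
        External ids for the rows (used to translate excluded pairs).
    """

    def __init__(self, y, C, covariances: CovarianceSet, ids=None):
        self.y = np.asarray(y, dtype=float)
        self.C = np.asarray(C, dtype=float)
        if self.C.ndim == 1:
            self.C = self.C[:, None]
        self.covariances = covariances
        self.ids = None if ids is None else np.asarray(ids, dtype=object)
        if len(self.y) != covariances.n:
            raise ValueError(
                f"phenotype length {len(self.y)} does not match matrix "
                f"dimension {covariances.n}"
            )

    @classmethod
    def from_pedigree(
        cls,
        ped: Pedigree,
        table,
        pheno_col: str,
        covar_cols=None,
        matrices=("ibd",),
        prune: bool = True,
    ) -> "PedigreeVarianceModel":
        """Build matrices from a pedigree and align a phenotype table.

        With ``prune`` the pedigree is first restricted to phenotyped
        individuals and the ancestors required for their relationships;
        the covariance matrices are then subset to the phenotyped rows.
        """
        pt = align_phenotypes(ped, table, pheno_col, covar_cols)
        if prune:
            ped = prune_uninformative(ped, list(pt.ids))
        M = build_covariance_set(ped, labels=matrices)
        rows = np.asarray([ped.index_of(i) for i in pt.ids])
        mats = [Mk[rows][:, rows].tocsr() for Mk in M.matrices]
        return cls(
            y=pt.y,
            C=pt.C,
            covariances=CovarianceSet(matrices=mats, labels=M.labels),
            ids=pt.ids,
        )

    def _pairs_to_idx(self, excluded_pairs):
        if excluded_pairs is None:
            return None
        out = []
        for a, b in excluded_pairs:
            if isinstance(a, (int, np.integer)):
                out.append((int(a), int(b)))
            else:
                pos = {iid: i for i, iid in enumerate(self.ids)}
                out.append((pos[str(a)], pos[str(b)]))
        return out

    def fit(self, method: str = "reml", **opts) -> "VarianceComponentResults":
        """Estimate the variance components.

        ``method='he'`` accepts ``excluded_pairs``, ``se_mode``
        ('exact'/'mc'/None), ``n_probes`` and ``seed``; ``method='reml'``
        accepts the :func:`sparseped.reml.fit_reml` options (``probes``,
        ``seed``, ``max_iter``, ``extra_starts``, ``exact_traces`` ...).
        """
        if method == "he":
            opts["excluded"] = self._pairs_to_idx(opts.pop("excluded_pairs",
                                                           None))
            fit = _he.fit_he(self.y, self.C, self.covariances, **opts)
        elif method == "reml":
            model = _reml.LmmModel(y=self.y, C=self.C, M=self.covariances)
            fit = _reml.fit_reml(model, **opts)
        else:
            raise ValueError(f"unknown method {method!r}")
        return VarianceComponentResults(self, method, fit)


class VarianceComponentResults:
    """Variance-component estimates with uncertainties and diagnostics."""

    def __init__(self, model: PedigreeVarianceModel, method: str, fit):
        self.model = model
        self.method = method
        self._fit = fit
        self.labels = list(fit.labels) + ["residual"]
        self.sigma2 = np.append(fit.sigma2, fit.sigma2_e)
        self.se = fit.se
        self.beta_hat = fit.beta_hat
        self.converged = getattr(fit, "converged", True)
        self.restricted_ll = getattr(fit, "restricted_ll", None)
        self.n = fit.n if fit.n else len(model.y)

    @property
    def variance_fractions(self) -> np.ndarray:
        """Each component as a fraction of the total modeled variance."""
        tot = float(np.sum(self.sigma2))
        return self.sigma2 / tot if tot > 0 else self.sigma2 * np.nan

    def summary(self) -> str:
        lines = []
        title = f"Variance components ({self.method.upper()}), n = {self.n}"
        lines.append(title)
        lines.append("=" * len(title))
        hdr = f"{'component':<14}{'sigma2':>12}{'s.e.':>12}{'fraction':>12}"
        lines.append(hdr)
        lines.append("-" * len(hdr))
        fracs = self.variance_fractions
        d = len(self._fit.sigma2)
        for k, lb in enumerate(self.labels):
            if self.se is None:
                se_s = "--"
            elif self.method == "he" and k >= d:
                se_s = "--"  # residual is derived, not estimated, under HE
            else:
                se_k = self.se[k] if k < len(self.se) else np.nan
                se_s = f"{se_k:.4f}"
            lines.append(
                f"{lb:<14}{self.sigma2[k]:>12.4f}{se_s:>12}{fracs[k]:>12.4f}"
            )
        lines.append("-" * len(hdr))
        if self.restricted_ll is not None:
            lines.append(f"restricted log-likelihood: {self.restricted_ll:.4f}")
            lines.append(f"converged: {self.converged}")
        if getattr(self._fit, "excluded_pairs", 0):
            lines.append(f"excluded pairs: {self._fit.excluded_pairs}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        from .io import fit_to_dict

        return fit_to_dict(self._fit, extra={"method": self.method})

    def __repr__(self):
        parts = ", ".join(
            f"{lb}={v:.3f}" for lb, v in zip(self.labels, self.sigma2)
        )
        return f"<VarianceComponentResults {self.method}: {parts}>"
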