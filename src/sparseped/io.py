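"""Serialization: MatrixMarket covariance matrices with an index-map
sidecar, phenotype tables, and fit results as JSON."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .kinship import CovarianceSet
from .pedigree import Pedigree

__all__ = [
    "save_covariance_set",
    "load_covariance_set",
    "save_index_map",
    "load_index_map",
    "fit_to_dict",
    "save_fit",
]


def save_index_map(ids, path) -> None:
    pd.DataFrame({"index": np.arange(len(ids)), "id": ids}).to_csv(
        path, sep="\t", index=False
    )


def load_index_map(path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    return df.sort_values("index")["id"].to_numpy(object)


def save_covariance_set(M: CovarianceSet, outdir, ids=None) -> None:
    """One ``<label>.mtx`` (symmetric coordinate) per matrix, plus
    ``index_map.tsv`` when ids are given."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for lb, Mk in zip(M.labels, M.matrices):
        scipy.io.mmwrite(
            str(outdir / f"{lb}.mtx"), sp.tril(Mk).tocoo(),
            symmetry="symmetric",
        )
    if ids is not None:
        save_index_map(ids, outdir / "index_map.tsv")


def load_covariance_set(indir, labels=None) -> CovarianceSet:
    indir = Path(indir)
    if labels is None:
        labels = sorted(p.stem for p in indir.glob("*.mtx"))
        # keep the additive matrix first if present
        labels = [lb for lb in ("ibd",) if lb in labels] + [
            lb for lb in labels if lb != "ibd"
        ]
    mats = []
    for lb in labels:
        f = indir / f"{lb}.mtx"
        if not f.exists():
            raise FileNotFoundError(f"missing covariance matrix file {f}")
        mats.append(sp.csr_matrix(scipy.io.mmread(str(f))))
    return CovarianceSet(matrices=mats, labels=list(labels))


def fit_to_dict(fit, extra=None) -> dict:
    """JSON-ready summary of an HE or REML fit."""
    out = {
        "labels": list(fit.labels),
        "sigma2": [float(v) for v in fit.sigma2],
        "sigma2_e": float(fit.sigma2_e),
        "se": None if fit.se is None else [float(v) for v in fit.se],
        "beta_hat": None
        if fit.beta_hat is None
        else [float(v) for v in fit.beta_hat],
        "n": int(fit.n),
    }
    for attr in ("restricted_ll", "converged", "n_probes", "n_iter",
                 "excluded_pairs", "message"):
        if hasattr(fit, attr):
            v = getattr(fit, attr)
            out[attr] = v if not isinstance(v, (np.floating, np.integer)) \
                else float(v)
    if getattr(fit, "settings", None):
        out["settings"] = fit.settings
    if extra:
        out.update(extra)
    return out


def save_fit(fit, path, extra=None) -> None:
    with open(path, "w") as fh:
        json.dump(fit_to_dict(fit, extra=extra), fh, indent=2)


def read_pairs(path, ped: Pedigree) -> list:
    """Excluded-pairs TSV (two id columns) to internal index pairs."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str,
                     comment="#")
    if df.iloc[0, 0].lower() in {"id1", "id_a", "left"}:
        df = df.iloc[1:]
    return [
        (ped.index_of(a), ped.index_of(b))
        for a, b in zip(df.iloc[:, 0], df.iloc[:, 1])
    ]
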