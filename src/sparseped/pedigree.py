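"""Pedigree containers, validation, I/O, pruning, and phenotype alignment.

A pedigree is a directed acyclic parent-link graph: every individual has at
most one recorded father and one recorded mother; individuals with no
recorded parents are founders, assumed non-inbred and mutually unrelated.
Internally individuals are mapped to a dense integer index in topological
order (every parent precedes all of its children), which is the order every
downstream matrix routine relies on.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING_TOKENS = {"", "0", "NA", "na", "nan", ".", "-"}


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (cycles, duplicate ids...)."""


@dataclass
class Pedigree:
    """A validated pedigree in dense topological index order.

    Attributes
    ----------
    ids : ndarray of object
        External identifiers, position = internal index. Topologically
        sorted: ``father[i] < i`` and ``mother[i] < i`` whenever known.
    father, mother : ndarray of int
        Internal index of each individual's parents, ``-1`` if unknown.
    sex : ndarray of object or None
        Optional per-individual sex labels ('female'/'male'/'unknown').
    """

    ids: np.ndarray
    father: np.ndarray
    mother: np.ndarray
    sex: np.ndarray | None = None
    _pos: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if not self._pos:
            self._pos = {iid: i for i, iid in enumerate(self.ids)}

    @property
    def n(self) -> int:
        return len(self.ids)

    def __len__(self) -> int:
        return self.n

    def index_of(self, external_id) -> int:
        return self._pos[external_id]

    @property
    def founders(self) -> np.ndarray:
        """Indices of individuals with no recorded parents."""
        return np.flatnonzero((self.father < 0) & (self.mother < 0))

    @classmethod
    def from_records(cls, ids, father_ids, mother_ids, sex=None) -> "Pedigree":
        """Build a validated, topologically indexed pedigree.

        Parent ids never declared as individuals are implicitly created as
        founders (logged). Raises :class:`PedigreeError` on duplicate ids or
        cycles (an individual that is its own ancestor).
        """
        ids = [str(x) for x in ids]
        father_ids = [None if _is_missing(x) else str(x) for x in father_ids]
        mother_ids = [None if _is_missing(x) else str(x) for x in mother_ids]

        seen = set()
        for iid in ids:
            if iid in seen:
                raise PedigreeError(f"duplicate individual id {iid!r}")
            seen.add(iid)

        implicit = []
        for plist in (father_ids, mother_ids):
            for p in plist:
                if p is not None and p not in seen:
                    seen.add(p)
                    implicit.append(p)
        if implicit:
            logger.info(
                "%d parent ids not declared as individuals; created as founders",
                len(implicit),
            )
        all_ids = list(ids) + implicit
        fmap = dict(zip(ids, father_ids))
        mmap = dict(zip(ids, mother_ids))
        smap = dict(zip(ids, sex)) if sex is not None else {}

        order = _topological_order(all_ids, fmap, mmap)
        pos = {iid: i for i, iid in enumerate(order)}
        n = len(order)
        fa = np.full(n, -1, dtype=np.int64)
        mo = np.full(n, -1, dtype=np.int64)
        for iid in ids:
            i = pos[iid]
            if fmap[iid] is not None:
                fa[i] = pos[fmap[iid]]
            if mmap[iid] is not None:
                mo[i] = pos[mmap[iid]]
        sx = None
        if sex is not None:
            sx = np.array(
                [_norm_sex(smap.get(iid)) for iid in order], dtype=object
            )
        return cls(
            ids=np.array(order, dtype=object),
            father=fa,
            mother=mo,
            sex=sx,
            _pos=pos,
        )

    def subset(self, keep: np.ndarray) -> "Pedigree":
        """Sub-pedigree over ``keep`` (indices); parent links leaving the
        subset become unknown. Relative order is preserved (still topological)."""
        keep = np.asarray(sorted(set(int(k) for k in keep)), dtype=np.int64)
        old2new = {int(o): i for i, o in enumerate(keep)}
        fa = np.full(len(keep), -1, dtype=np.int64)
        mo = np.full(len(keep), -1, dtype=np.int64)
        for new, old in enumerate(keep):
            f, m = int(self.father[old]), int(self.mother[old])
            if f in old2new:
                fa[new] = old2new[f]
            if m in old2new:
                mo[new] = old2new[m]
        return Pedigree(
            ids=self.ids[keep].copy(),
            father=fa,
            mother=mo,
            sex=self.sex[keep].copy() if self.sex is not None else None,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "id": self.ids,
                "father": [self.ids[f] if f >= 0 else "0" for f in self.father],
                "mother": [self.ids[m] if m >= 0 else "0" for m in self.mother],
            }
        )
        if self.sex is not None:
            df["sex"] = self.sex
        return df


def _is_missing(x) -> bool:
    if x is None:
        return True
    if isinstance(x, float) and np.isnan(x):
        return True
    return str(x).strip() in MISSING_TOKENS


def _norm_sex(x):
    if x is None or _is_missing(x):
        return "unknown"
    s = str(x).strip().lower()
    if s in {"f", "female", "2"}:
        return "female"
    if s in {"m", "male", "1"}:
        return "male"
    return "unknown"


def _topological_order(all_ids, fmap, mmap):
    """Kahn layering with stable tie-break on external id string order."""
    children: dict = {iid: [] for iid in all_ids}
    indeg = {iid: 0 for iid in all_ids}
    for iid in all_ids:
        for p in (fmap.get(iid), mmap.get(iid)):
            if p is not None:
                children[p].append(iid)
                indeg[iid] += 1
    frontier = sorted(iid for iid in all_ids if indeg[iid] == 0)
    order = []
    while frontier:
        nxt = []
        for iid in frontier:
            order.append(iid)
            for c in children[iid]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    nxt.append(c)
        frontier = sorted(set(nxt))
    if len(order) != len(all_ids):
        stuck = next(iid for iid in all_ids if indeg[iid] > 0)
        raise PedigreeError(
            f"pedigree contains a cycle involving individual {stuck!r}"
        )
    return order


# ---------------------------------------------------------------------------
# file I/O


def read_pedigree(path, dialect: str = "tsv") -> Pedigree:
    """Read a parent-link table (id, father, mother[, sex]).

    Tab-separated by default, LINKAGE/PLINK-fam style: token ``0`` or empty
    means unknown parent. A header line is auto-detected (first row starting
    with 'id' case-insensitively, or containing non-unique placeholder names).
    """
    sep = {"tsv": "\t", "csv": ","}[dialect]
    with open(path) as fh:
        first = fh.readline()
    has_header = first.lower().lstrip().startswith(("id", "#id", "iid"))
    df = pd.read_csv(
        path,
        sep=sep,
        header=0 if has_header else None,
        dtype=str,
        keep_default_na=False,
    )
    if not has_header:
        cols = ["id", "father", "mother", "sex"][: df.shape[1]]
        df.columns = cols + list(df.columns[len(cols):])
    sex = df["sex"] if "sex" in df.columns else None
    return Pedigree.from_records(
        df["id"], df["father"], df["mother"], sex=sex
    )


def write_pedigree(ped: Pedigree, path) -> None:
    ped.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# pruning


def ancestor_closure(ped: Pedigree, seed_idx) -> np.ndarray:
    """Indices of all ancestors-or-self of ``seed_idx`` (boolean mask)."""
    mask = np.zeros(ped.n, dtype=bool)
    stack = [int(i) for i in seed_idx]
    mask[stack] = True
    while stack:
        i = stack.pop()
        for p in (int(ped.father[i]), int(ped.mother[i])):
            if p >= 0 and not mask[p]:
                mask[p] = True
                stack.append(p)
    return mask


def prune_uninformative(ped: Pedigree, informative) -> Pedigree:
    """Restrict the pedigree to individuals required for IBD computation
    among the ``informative`` set (ids or indices).

    Required individuals are the informative ones plus every individual on
    a lineage path connecting two informative individuals with one of their
    least common ancestors. Implemented as the ancestor closure of the
    informative set followed by iterated removal of (a) non-informative
    members with no retained children and (b) non-informative founders (in
    the retained subset) with a single retained child, until fixpoint.
    The IBD submatrix over informative individuals is exactly preserved.
    """
    informative = list(informative)
    if len(informative) == 0:
        warnings.warn("empty informative set: returning empty pedigree")
        return ped.subset(np.array([], dtype=np.int64))
    if all(isinstance(x, (int, np.integer)) for x in informative):
        info_idx = np.asarray(informative, dtype=np.int64)
    else:
        info_idx = np.asarray(
            [ped.index_of(str(x)) for x in informative], dtype=np.int64
        )
    keep = ancestor_closure(ped, info_idx)
    is_info = np.zeros(ped.n, dtype=bool)
    is_info[info_idx] = True

    nchild = np.zeros(ped.n, dtype=np.int64)
    for arr in (ped.father, ped.mother):
        for c in np.flatnonzero(keep):
            p = int(arr[c])
            if p >= 0 and keep[p]:
                nchild[p] += 1
    changed = True
    while changed:
        changed = False
        for i in np.flatnonzero(keep & ~is_info):
            f, m = int(ped.father[i]), int(ped.mother[i])
            has_parent = (f >= 0 and keep[f]) or (m >= 0 and keep[m])
            if nchild[i] == 0 or (nchild[i] == 1 and not has_parent):
                keep[i] = False
                changed = True
                for p in (f, m):
                    if p >= 0 and keep[p]:
                        nchild[p] -= 1
    removed = ped.n - int(keep.sum())
    if removed:
        logger.info("pruned %d uninformative individuals", removed)
    return ped.subset(np.flatnonzero(keep))


# ---------------------------------------------------------------------------
# phenotype alignment


@dataclass
class PhenotypeTable:
    """Phenotype vector and covariate matrix aligned to pedigree order.

    ``C`` always contains an intercept column (all ones, first column).
    """

    y: np.ndarray
    C: np.ndarray
    ids: np.ndarray
    covar_names: list

    @property
    def n(self) -> int:
        return len(self.y)


def align_phenotypes(
    ped: Pedigree,
    table: pd.DataFrame,
    pheno_col: str,
    covar_cols: list | None = None,
    id_col: str = "id",
) -> PhenotypeTable:
    """Reorder phenotype/covariate records to pedigree index order.

    Individuals with a missing phenotype are dropped (count logged); an
    intercept column is prepended if the covariates do not already contain
    a constant column. Records whose id is absent from the pedigree raise.
    """
    df = table.copy()
    df[id_col] = df[id_col].astype(str)
    unknown = [i for i in df[id_col] if i not in ped._pos]
    if unknown:
        raise KeyError(
            f"{len(unknown)} phenotype ids not in pedigree (e.g. {unknown[0]!r})"
        )
    df["_idx"] = [ped.index_of(i) for i in df[id_col]]
    n0 = len(df)
    df = df[pd.to_numeric(df[pheno_col], errors="coerce").notna()]
    dropped = n0 - len(df)
    if dropped:
        logger.info("dropped %d records with missing phenotype", dropped)
    df = df.sort_values("_idx", kind="stable")

    y = df[pheno_col].astype(float).to_numpy()
    covar_cols = list(covar_cols or [])
    cols = []
    names = []
    for c in covar_cols:
        v = df[c].astype(float).to_numpy()
        if np.ptp(v) == 0 and not np.all(v == 1):
            warnings.warn(f"covariate {c!r} has zero variance")
        cols.append(v)
        names.append(c)
    have_intercept = any(np.all(v == 1) for v in cols)
    if not have_intercept:
        cols.insert(0, np.ones(len(df)))
        names.insert(0, "intercept")
    C = np.column_stack(cols) if cols else np.ones((len(df), 1))
    return PhenotypeTable(
        y=y, C=C, ids=df[id_col].to_numpy(object), covar_names=names
    )
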