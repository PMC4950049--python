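"""Pedigree ingestion, validation, inbreeding coefficients and ancestry tiers.

A pedigree is a directed acyclic parent map: every individual has a sire and a
dam, either of which may be unknown. The expected inbreeding coefficient of an
individual, ``F_ped``, is the kinship coefficient between its parents; kinship
is computed by the classical recursive (tabular-equivalent) method, which is
exact given the pedigree. Individuals with any unknown parent receive F = 0,
i.e. the unknown parent is assumed unrelated — the systematic underestimation
this causes in real pedigrees is precisely why genomic estimators are compared
against F_ped downstream.

Ancestry-completeness tiers classify how much pedigree information supports an
individual's F_ped: no parents, one parent, both parents, both parents plus at
least one maternal grandparent, or all four grandparents. The tiers are nested
and are used to filter analysis datasets.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

UNKNOWN = ""
_UNKNOWN_CODES = {"0", "NA", "na", "NaN", "nan", ".", "", "-9"}


class AncestryTier(enum.IntEnum):
    """Nested pedigree-information tiers, ordered by increasing completeness."""

    NO_PARENTS = 0
    ONE_PARENT = 1
    BOTH_PARENTS = 2
    BOTH_PARENTS_PLUS_MATERNAL_GP = 3
    FOUR_GRANDPARENTS = 4


class PedigreeError(ValueError):
    pass


@dataclass
class Pedigree:
    """Validated pedigree in topological order (parents precede offspring).

    Parameters
    ----------
    ids : sequence of str
        Individual identifiers, topologically sorted.
    sire, dam : mapping id -> id or ``UNKNOWN``.
    birth_cohort : optional mapping id -> int.
    """

    ids: list[str]
    sire: dict[str, str]
    dam: dict[str, str]
    birth_cohort: dict[str, int] = field(default_factory=dict)
    sex: dict[str, str] = field(default_factory=dict)  # optional, "F"/"M"

    def __post_init__(self) -> None:
        self._index = {iid: k for k, iid in enumerate(self.ids)}
        if len(self._index) != len(self.ids):
            dup = pd.Series(self.ids).value_counts()
            raise PedigreeError(f"duplicate individual id: {dup.index[0]!r}")
        for iid in self.ids:
            for par in (self.sire[iid], self.dam[iid]):
                if par != UNKNOWN and self._index[par] >= self._index[iid]:
                    raise PedigreeError(
                        f"pedigree not topologically ordered at {iid!r}"
                    )
        self._kinship_cache: dict[tuple[str, str], float] = {}

    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, iid: str) -> bool:
        return iid in self._index

    def parents(self, iid: str) -> tuple[str, str]:
        return self.sire[iid], self.dam[iid]

    def is_founder(self, iid: str) -> bool:
        return self.sire[iid] == UNKNOWN and self.dam[iid] == UNKNOWN

    @property
    def founders(self) -> list[str]:
        return [i for i in self.ids if self.is_founder(i)]

    # ------------------------------------------------------------------
    # construction
    # ------------------------------------------------------------------

    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple],
        birth_cohort: Mapping[str, int] | None = None,
    ) -> "Pedigree":
        """Build from (id, sire, dam) triples in any order.

        Parents referenced but never listed as individuals are auto-added as
        founders. Raises on duplicate ids and on cycles (naming an individual
        on the cycle).
        """
        sire: dict[str, str] = {}
        dam: dict[str, str] = {}
        order: list[str] = []
        for rec in records:
            iid, s, d = (str(x).strip() for x in rec[:3])
            if iid in _UNKNOWN_CODES:
                raise PedigreeError(f"invalid individual id {iid!r}")
            if iid in sire:
                raise PedigreeError(f"duplicate individual id: {iid!r}")
            s = UNKNOWN if s in _UNKNOWN_CODES else s
            d = UNKNOWN if d in _UNKNOWN_CODES else d
            sire[iid] = s
            dam[iid] = d
            order.append(iid)
        # auto-add referenced-but-unlisted parents as founders
        for iid in list(order):
            for par in (sire[iid], dam[iid]):
                if par != UNKNOWN and par not in sire:
                    sire[par] = UNKNOWN
                    dam[par] = UNKNOWN
                    order.append(par)
        ids = _topological_order(order, sire, dam)
        cohort = dict(birth_cohort or {})
        return cls(ids=ids, sire=sire, dam=dam, birth_cohort=cohort)

    # ------------------------------------------------------------------
    # kinship / inbreeding
    # ------------------------------------------------------------------

    def kinship(self, a: str, b: str) -> float:
        """Kinship (coancestry) coefficient between two individuals.

        Recursive with memoization; equivalent to the tabular method.
        ``kinship(a, a) = (1 + F_a) / 2``.
        """
        if a == UNKNOWN or b == UNKNOWN:
            return 0.0
        if a not in self._index or b not in self._index:
            raise PedigreeError(f"unknown individual in kinship query: {a!r}/{b!r}")
        return self._kinship(a, b)

    def _kinship(self, a: str, b: str) -> float:
        # order the pair so the cache key is canonical and recursion always
        # descends through the individual later in topological order
        if self._index[a] < self._index[b]:
            a, b = b, a
        key = (a, b)
        cached = self._kinship_cache.get(key)
        if cached is not None:
            return cached
        sa, da = self.sire[a], self.dam[a]
        if a == b:
            f = 0.0
            if sa != UNKNOWN and da != UNKNOWN:
                f = self._kinship(sa, da)
            val = 0.5 * (1.0 + f)
        else:
            val = 0.0
            if sa != UNKNOWN:
                val += 0.5 * self._kinship(sa, b)
            if da != UNKNOWN:
                val += 0.5 * self._kinship(da, b)
        self._kinship_cache[key] = val
        return val

    def inbreeding(self, iid: str) -> float:
        """F_ped of one individual: kinship of its parents (0 if any unknown)."""
        s, d = self.sire[iid], self.dam[iid]
        if s == UNKNOWN or d == UNKNOWN:
            return 0.0
        return self._kinship(s, d)


def read_pedigree(path: str | Path) -> Pedigree:
    """Read a whitespace/tab-separated pedigree file (id, sire, dam[, cohort]).

    Unknown parents are coded ``0`` or ``NA``. A header row is optional and is
    autodetected: if the first row's third column is not a known id/code and
    the row matches common header names, it is skipped.
    """
    df = pd.read_csv(path, sep=r"\s+", header=None, dtype=str, comment="#")
    if df.shape[1] < 3:
        raise PedigreeError(f"{path}: expected >=3 columns (id, sire, dam)")
    first = [str(x).strip().lower() for x in df.iloc[0, :3]]
    if first[0] in {"id", "iid", "individual", "animal"} or (
        first[1] in {"sire", "father", "fatherid"} and first[2] in {"dam", "mother", "motherid"}
    ):
        df = df.iloc[1:].reset_index(drop=True)
    cohort: dict[str, int] = {}
    if df.shape[1] >= 4:
        for iid, c in zip(df.iloc[:, 0], df.iloc[:, 3]):
            c = str(c).strip()
            if c not in _UNKNOWN_CODES:
                try:
                    cohort[str(iid).strip()] = int(float(c))
                except ValueError:
                    pass
    return Pedigree.from_records(
        df.iloc[:, :3].itertuples(index=False, name=None), birth_cohort=cohort
    )


def _topological_order(
    order: Sequence[str], sire: Mapping[str, str], dam: Mapping[str, str]
) -> list[str]:
    """Kahn's algorithm on parent->child edges; stable w.r.t. input order."""
    children: dict[str, list[str]] = {i: [] for i in order}
    indeg = {i: 0 for i in order}
    for iid in order:
        for par in (sire[iid], dam[iid]):
            if par != UNKNOWN:
                children[par].append(iid)
                indeg[iid] += 1
    queue = [i for i in order if indeg[i] == 0]
    out: list[str] = []
    head = 0
    while head < len(queue):
        node = queue[head]
        head += 1
        out.append(node)
        for ch in children[node]:
            indeg[ch] -= 1
            if indeg[ch] == 0:
                queue.append(ch)
    if len(out) != len(order):
        on_cycle = next(i for i in order if indeg[i] > 0)
        raise PedigreeError(
            f"pedigree contains a cycle (individual {on_cycle!r} is its own ancestor)"
        )
    return out


def f_ped(ped: Pedigree) -> dict[str, float]:
    """Expected inbreeding coefficient per individual (kinship of its parents)."""
    return {iid: ped.inbreeding(iid) for iid in ped.ids}


def kinship_matrix(
    ped: Pedigree, subset: Sequence[str] | None = None
) -> pd.DataFrame:
    """Symmetric kinship matrix by the tabular method.

    Diagonal entries are ``(1 + F_i) / 2``; the numerator relationship matrix
    of the animal model is twice this matrix. Built in topological order in
    O(n^2) with vectorised row updates.
    """
    if subset is not None:
        missing = [s for s in subset if s not in ped]
        if missing:
            raise PedigreeError(f"subset ids not in pedigree: {missing[:5]}")
    ids = ped.ids
    n = len(ids)
    idx = {iid: k for k, iid in enumerate(ids)}
    K = np.zeros((n, n))
    for i, iid in enumerate(ids):
        s, d = ped.parents(iid)
        si = idx[s] if s != UNKNOWN else -1
        di = idx[d] if d != UNKNOWN else -1
        row = np.zeros(i)
        if si >= 0:
            row += 0.5 * K[si, :i]
        if di >= 0:
            row += 0.5 * K[di, :i]
        K[i, :i] = row
        K[:i, i] = row
        f = K[si, di] if (si >= 0 and di >= 0) else 0.0
        K[i, i] = 0.5 * (1.0 + f)
    df = pd.DataFrame(K, index=ids, columns=ids)
    if subset is not None:
        df = df.loc[list(subset), list(subset)]
    return df


def write_kinship_matrix(km: pd.DataFrame, path: str | Path) -> None:
    km.to_csv(path, sep="\t", index_label="id")


def classify_ancestry(ped: Pedigree) -> dict[str, AncestryTier]:
    """Ancestry-completeness tier per individual.

    ``FOUR_GRANDPARENTS`` requires all four grandparents known;
    ``BOTH_PARENTS_PLUS_MATERNAL_GP`` requires both parents and at least one
    maternal grandparent. Tiers are reported as the most complete one attained.
    """
    tiers: dict[str, AncestryTier] = {}
    for iid in ped.ids:
        s, d = ped.parents(iid)
        n_par = (s != UNKNOWN) + (d != UNKNOWN)
        if n_par == 0:
            tiers[iid] = AncestryTier.NO_PARENTS
            continue
        if n_par == 1:
            tiers[iid] = AncestryTier.ONE_PARENT
            continue
        pgs, pgd = ped.parents(s)
        mgs, mgd = ped.parents(d)
        n_mat_gp = (mgs != UNKNOWN) + (mgd != UNKNOWN)
        n_pat_gp = (pgs != UNKNOWN) + (pgd != UNKNOWN)
        if n_mat_gp == 2 and n_pat_gp == 2:
            tiers[iid] = AncestryTier.FOUR_GRANDPARENTS
        elif n_mat_gp >= 1:
            tiers[iid] = AncestryTier.BOTH_PARENTS_PLUS_MATERNAL_GP
        else:
            tiers[iid] = AncestryTier.BOTH_PARENTS
    return tiers


def write_pedigree(ped: Pedigree, path: str | Path) -> None:
    """Write pedigree TSV (id, sire, dam[, cohort]); unknown parents as 0."""
    rows = []
    for iid in ped.ids:
        s, d = ped.parents(iid)
        row = [iid, s or "0", d or "0"]
        if ped.birth_cohort:
            row.append(str(ped.birth_cohort.get(iid, "NA")))
        rows.append(row)
    cols = ["id", "sire", "dam"] + (["cohort"] if ped.birth_cohort else [])
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)
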