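"""Pedigrees, block-diallel crossing designs, and the additive relationship matrix.

The breeding designs handled here are block diallels: within each block of
parents, every ordered (sire, dam) combination is crossed, including selfs and
reciprocals.  Selfing generates inbreeding, so the additive relationship matrix
A carries diagonal entries 1 + F (F the inbreeding coefficient) and is computed
with the standard tabular recursion::

    A[j, k] = 0.5 * (A[k, sire(j)] + A[k, dam(j)])
    A[j, j] = 1 + 0.5 * A[sire(j), dam(j)]

with unknown parents contributing 0.  Pedigrees are small here (a few hundred
individuals), so A is stored dense.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CrossRecord",
    "Pedigree",
    "RelatednessMatrix",
    "build_pedigree",
    "additive_relationship_matrix",
    "generate_block_diallel",
    "read_pedigree",
    "write_pedigree",
    "read_matrix",
    "write_matrix",
]

UNKNOWN = ""


@dataclass(frozen=True)
class CrossRecord:
    """One offspring (or cross family) with its sire and dam.

    ``sire_id == dam_id`` denotes a selfing cross.  An empty string marks an
    unknown parent.
    """

    offspring_id: str
    sire_id: str = UNKNOWN
    dam_id: str = UNKNOWN
    block_id: Optional[str] = None

    def is_self(self) -> bool:
        return self.sire_id != UNKNOWN and self.sire_id == self.dam_id


@dataclass
class Pedigree:
    """Topologically sorted pedigree: parents always precede offspring.

    ``sire`` / ``dam`` hold the index of each individual's parent within
    ``ids`` (-1 = unknown founder parent).
    """

    ids: list[str]
    sire: np.ndarray
    dam: np.ndarray

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def founders(self) -> np.ndarray:
        """Boolean mask of individuals with both parents unknown."""
        return (self.sire < 0) & (self.dam < 0)

    def index_of(self, ids: Iterable[str]) -> np.ndarray:
        lookup = {v: i for i, v in enumerate(self.ids)}
        return np.array([lookup[i] for i in ids], dtype=int)


@dataclass
class RelatednessMatrix:
    """Dense additive relationship matrix A with its individual labels."""

    ids: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.ids), len(self.ids)):
            raise ValueError("A must be square with one row per individual")

    def inbreeding(self) -> np.ndarray:
        """Inbreeding coefficients F_i = A_ii - 1."""
        return np.diag(self.values) - 1.0

    def submatrix(self, ids: Sequence[str]) -> "RelatednessMatrix":
        idx = Pedigree(self.ids, np.empty(0), np.empty(0)).index_of(ids)
        return RelatednessMatrix(list(ids), self.values[np.ix_(idx, idx)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


class PedigreeError(ValueError):
    """Structural problem in a set of cross records (cycle, duplicate id)."""


def build_pedigree(records: Iterable[CrossRecord]) -> Pedigree:
    """Assemble cross records into a topologically sorted pedigree.

    Parents that never appear as offspring become founders.  The sort is
    stable: generation first, then input order, so the resulting individual
    ordering (and hence A) is reproducible bit-for-bit.

    Raises
    ------
    PedigreeError
        If an offspring id is duplicated or the parent links contain a cycle
        (including the length-1 cycle of an individual listed as its own
        parent).
    """
    records = list(records)
    seen: dict[str, CrossRecord] = {}
    for rec in records:
        if rec.offspring_id in seen:
            raise PedigreeError(f"duplicate offspring id {rec.offspring_id!r}")
        if rec.offspring_id in (rec.sire_id, rec.dam_id):
            raise PedigreeError(
                f"{rec.offspring_id!r} is listed as its own parent"
            )
        seen[rec.offspring_id] = rec

    # founders: parents never listed as offspring, in order of first mention
    order: list[str] = []
    for rec in records:
        for pid in (rec.sire_id, rec.dam_id):
            if pid != UNKNOWN and pid not in seen and pid not in order:
                order.append(pid)
    founders = order[:]

    # Kahn-style topological sort, stable in input order.
    placed = set(founders)
    remaining = [r for r in records]
    while remaining:
        progressed = False
        deferred = []
        for rec in remaining:
            ok = all(
                p == UNKNOWN or p in placed for p in (rec.sire_id, rec.dam_id)
            )
            if ok:
                order.append(rec.offspring_id)
                placed.add(rec.offspring_id)
                progressed = True
            else:
                deferred.append(rec)
        if not progressed:
            stuck = ", ".join(r.offspring_id for r in deferred)
            raise PedigreeError(f"cycle detected among: {stuck}")
        remaining = deferred

    index = {v: i for i, v in enumerate(order)}
    sire = np.full(len(order), -1, dtype=int)
    dam = np.full(len(order), -1, dtype=int)
    for rec in records:
        j = index[rec.offspring_id]
        if rec.sire_id != UNKNOWN:
            sire[j] = index[rec.sire_id]
        if rec.dam_id != UNKNOWN:
            dam[j] = index[rec.dam_id]
    return Pedigree(order, sire, dam)


def additive_relationship_matrix(ped: Pedigree) -> RelatednessMatrix:
    """Tabular-method A over all pedigree members (dense, deterministic)."""
    n = len(ped)
    A = np.zeros((n, n))
    s, d = ped.sire, ped.dam
    for j in range(n):
        sj, dj = s[j], d[j]
        if j > 0:
            k = np.arange(j)
            row = np.zeros(j)
            if sj >= 0:
                row += A[k, sj]
            if dj >= 0:
                row += A[k, dj]
            row *= 0.5
            A[j, :j] = row
            A[:j, j] = row
        A[j, j] = 1.0 + (0.5 * A[sj, dj] if sj >= 0 and dj >= 0 else 0.0)
    return RelatednessMatrix(ped.ids, A)


def generate_block_diallel(
    n_blocks: int,
    parents_per_block: int,
    block_prefix: str = "B",
    parent_prefix: str = "P",
    family_prefix: str = "F",
) -> list[CrossRecord]:
    """All ordered (sire, dam) crosses, including selfs, within each block.

    Parents are distinct across blocks, so a design of ``n_blocks`` x
    ``parents_per_block`` yields ``n_blocks * parents_per_block**2`` crosses
    and ``n_blocks * parents_per_block`` half-sib groups.  Each returned
    record stands for one cross family; its offspring id is the family label.
    """
    if n_blocks < 1 or parents_per_block < 1:
        raise ValueError("n_blocks and parents_per_block must be positive")
    crosses: list[CrossRecord] = []
    fam = 0
    for b in range(1, n_blocks + 1):
        block = f"{block_prefix}{b:02d}"
        parents = [
            f"{parent_prefix}{b:02d}_{p}" for p in range(1, parents_per_block + 1)
        ]
        for sire in parents:
            for dam in parents:
                fam += 1
                crosses.append(
                    CrossRecord(f"{family_prefix}{fam:03d}", sire, dam, block)
                )
    return crosses


# ---------------------------------------------------------------------------
# text formats: pedigree as `id,sire,dam` rows; A as a labelled square matrix


def write_pedigree(ped: Pedigree, path) -> None:
    sire = [ped.ids[i] if i >= 0 else "" for i in ped.sire]
    dam = [ped.ids[i] if i >= 0 else "" for i in ped.dam]
    pd.DataFrame({"id": ped.ids, "sire": sire, "dam": dam}).to_csv(
        path, index=False
    )


def read_pedigree(path) -> Pedigree:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    records = [
        CrossRecord(r["id"], r.get("sire", ""), r.get("dam", ""))
        for _, r in df.iterrows()
    ]
    # rows whose parents are all unknown and that are never referenced still
    # need to appear: build_pedigree keeps every offspring row.
    return build_pedigree(records)


def write_matrix(mat: RelatednessMatrix | pd.DataFrame, path) -> None:
    df = mat.to_frame() if isinstance(mat, RelatednessMatrix) else mat
    df.to_csv(path)


def read_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    if df.shape[0] != df.shape[1]:
        raise ValueError(f"matrix file {path} is not square")
    return df
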