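"""Pedigree handling and pedigree-based relationship computations.

A pedigree is a topologically ordered list of individual records
(id, sire, dam, sex, generation, hatch).  From it we compute the
numerator relationship matrix A (tabular method, with inbreeding),
per-individual inbreeding coefficients F = A_ii - 1, and the sparse
inverse of A via the Henderson/Quaas rules.  Unknown parents are
treated as unrelated, non-inbred founders; no genetic groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import sparse

UNKNOWN = "0"

__all__ = [
    "PedigreeError",
    "PedigreeCycleError",
    "ParentSexError",
    "DuplicateIdError",
    "Pedigree",
    "RelationshipMatrix",
    "IndividualPartition",
    "load_pedigree",
    "numerator_relationship",
    "inbreeding",
    "a_inverse",
    "partition_individuals",
]


class PedigreeError(ValueError):
    """Base class for pedigree validation failures."""


class PedigreeCycleError(PedigreeError):
    """An individual is its own ancestor."""


class ParentSexError(PedigreeError):
    """A sire is recorded as female or a dam as male."""


class DuplicateIdError(PedigreeError):
    """The same id appears in more than one record."""


@dataclass(frozen=True)
class PedigreeRecord:
    id: str
    sire: str  # UNKNOWN for missing
    dam: str
    sex: str  # "M" or "F"
    generation: int
    hatch: str


@dataclass
class Pedigree:
    """Validated, topologically sorted pedigree (parents before offspring)."""

    records: list[PedigreeRecord]
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._index = {r.id: i for i, r in enumerate(self.records)}

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, iid: str) -> bool:
        return iid in self._index

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def index(self, iid: str) -> int:
        return self._index[iid]

    def record(self, iid: str) -> PedigreeRecord:
        return self.records[self._index[iid]]

    def parents(self, iid: str) -> tuple[str | None, str | None]:
        r = self.record(iid)
        return (
            r.sire if r.sire != UNKNOWN else None,
            r.dam if r.dam != UNKNOWN else None,
        )

    def parent_ids(self) -> set[str]:
        """Ids of all individuals that appear as sire or dam."""
        out: set[str] = set()
        for r in self.records:
            if r.sire != UNKNOWN:
                out.add(r.sire)
            if r.dam != UNKNOWN:
                out.add(r.dam)
        return out

    # parent index arrays, -1 for unknown; used by the matrix builders
    def parent_indices(self) -> tuple[np.ndarray, np.ndarray]:
        n = len(self.records)
        si = np.full(n, -1, dtype=np.int64)
        di = np.full(n, -1, dtype=np.int64)
        for i, r in enumerate(self.records):
            if r.sire != UNKNOWN:
                si[i] = self._index[r.sire]
            if r.dam != UNKNOWN:
                di[i] = self._index[r.dam]
        return si, di

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [r.id for r in self.records],
                "sire": [r.sire for r in self.records],
                "dam": [r.dam for r in self.records],
                "sex": [r.sex for r in self.records],
                "generation": [r.generation for r in self.records],
                "hatch": [r.hatch for r in self.records],
            }
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, strict: bool = True) -> "Pedigree":
        return _build_pedigree(df, strict=strict)


@dataclass
class RelationshipMatrix:
    """Labeled symmetric relationship matrix (pedigree A or genomic G)."""

    labels: list[str]
    values: np.ndarray
    kind: str  # "pedigree_A" or "genomic_G"
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.labels), len(self.labels)):
            raise ValueError("relationship matrix shape does not match labels")
        self._index = {lab: i for i, lab in enumerate(self.labels)}

    def index(self, iid: str) -> int:
        return self._index[iid]

    def submatrix(self, ids: Sequence[str]) -> "RelationshipMatrix":
        idx = np.array([self._index[i] for i in ids])
        return RelationshipMatrix(list(ids), self.values[np.ix_(idx, idx)], self.kind)

    def loc(self, i: str, j: str) -> float:
        return float(self.values[self._index[i], self._index[j]])


@dataclass
class IndividualPartition:
    """Genotyped parents / genotyped non-parents / non-genotyped non-parents.

    ``nongenotyped_parents`` lists parents lacking genotypes; PBLUP can
    proceed with them but RAM-GBLUP raises downstream.
    """

    genotyped_parents: set[str]
    genotyped_nonparents: set[str]
    nongenotyped_nonparents: set[str]
    nongenotyped_parents: set[str] = field(default_factory=set)

    @property
    def genotyped(self) -> set[str]:
        return self.genotyped_parents | self.genotyped_nonparents


def _build_pedigree(df: pd.DataFrame, strict: bool = True) -> Pedigree:
    df = df.copy()
    for col in ("id", "sire", "dam"):
        df[col] = df[col].astype(str).str.strip()
        df[col] = df[col].replace({"": UNKNOWN, "nan": UNKNOWN, "NA": UNKNOWN})
    ids = df["id"].tolist()
    if len(set(ids)) != len(ids):
        dupes = df["id"][df["id"].duplicated()].tolist()
        raise DuplicateIdError(f"duplicate pedigree ids: {dupes}")
    known = set(ids)
    for col in ("sire", "dam"):
        missing = set(df[col]) - known - {UNKNOWN}
        if missing:
            raise PedigreeError(f"{col}s not present as records: {sorted(missing)}")

    sex = dict(zip(df["id"], df["sex"].astype(str).str.upper()))
    problems = []
    for s in set(df["sire"]) - {UNKNOWN}:
        if sex.get(s) != "M":
            problems.append(f"sire {s} has sex {sex.get(s)}")
    for d in set(df["dam"]) - {UNKNOWN}:
        if sex.get(d) != "F":
            problems.append(f"dam {d} has sex {sex.get(d)}")
    if problems:
        msg = "; ".join(problems)
        if strict:
            raise ParentSexError(msg)
        import warnings

        warnings.warn(f"parent sex inconsistency: {msg}", stacklevel=3)

    # topological sort (Kahn) with cycle detection
    children: dict[str, list[str]] = {i: [] for i in ids}
    indeg = {i: 0 for i in ids}
    rows = {r.id: r for r in df.itertuples(index=False)}
    for r in df.itertuples(index=False):
        for p in (r.sire, r.dam):
            if p != UNKNOWN:
                if p == r.id:
                    raise PedigreeCycleError(f"{r.id} listed as its own parent")
                children[p].append(r.id)
                indeg[r.id] += 1
    # keep input order when it is already topological (stable round-trips)
    seen: set[str] = set()
    already_sorted = True
    for r in df.itertuples(index=False):
        for p in (r.sire, r.dam):
            if p != UNKNOWN and p not in seen:
                already_sorted = False
                break
        if not already_sorted:
            break
        seen.add(r.id)
    if already_sorted:
        order = ids
    else:
        order = []
        queue = [i for i in ids if indeg[i] == 0]
        while queue:
            nxt = queue.pop(0)
            order.append(nxt)
            for c in children[nxt]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    queue.append(c)
        if len(order) != len(ids):
            stuck = sorted(i for i in ids if indeg[i] > 0)
            raise PedigreeCycleError(f"pedigree contains a cycle involving: {stuck}")

    records = [
        PedigreeRecord(
            id=r.id,
            sire=r.sire,
            dam=r.dam,
            sex=str(rows[r.id].sex).upper(),
            generation=int(rows[r.id].generation),
            hatch=str(rows[r.id].hatch),
        )
        for r in (rows[i] for i in order)
    ]
    return Pedigree(records)


def load_pedigree(path, strict: bool = True) -> Pedigree:
    """Read a pedigree CSV (columns id,sire,dam,sex,generation,hatch).

    Missing parents may be coded ``0`` or left empty.  Returns a validated
    pedigree in topological order, founders first.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"id", "sire", "dam", "sex", "generation", "hatch"}
    if not required.issubset(df.columns):
        raise PedigreeError(f"pedigree file must have columns {sorted(required)}")
    return _build_pedigree(df, strict=strict)


def numerator_relationship(ped: Pedigree) -> RelationshipMatrix:
    """Numerator relationship matrix A by the tabular method, with inbreeding.

    A_ii = 1 + 0.5 * A(sire, dam); A_ij = 0.5 * (A(j, sire_i) + A(j, dam_i))
    for j earlier in topological order.  Unknown parents contribute zero.
    """
    n = len(ped)
    si, di = ped.parent_indices()
    A = np.zeros((n, n))
    for i in range(n):
        s, d = si[i], di[i]
        row = np.zeros(i)
        if s >= 0:
            row += 0.5 * A[s, :i]
        if d >= 0:
            row += 0.5 * A[d, :i]
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0)
    return RelationshipMatrix(ped.ids, A, "pedigree_A")


def inbreeding(ped: Pedigree) -> pd.Series:
    """Inbreeding coefficients F_i = A_ii - 1."""
    A = numerator_relationship(ped)
    return pd.Series(np.diag(A.values) - 1.0, index=ped.ids, name="F")


def a_inverse(ped: Pedigree) -> sparse.csr_matrix:
    """Sparse inverse of A via Henderson's rules with Quaas' inbreeding
    adjustment.

    For individual i with parents s, d the Mendelian sampling variance is
    m_i = 0.5 - 0.25 (F_s + F_d) when both parents are known (0.75 - 0.25 F_p
    with one parent, 1 with none); 1/m_i enters the usual (-1, 0.5) pattern.
    """
    n = len(ped)
    si, di = ped.parent_indices()
    F = inbreeding(ped).to_numpy()
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []

    def add(r: int, c: int, v: float) -> None:
        rows.append(r)
        cols.append(c)
        vals.append(v)

    for i in range(n):
        s, d = si[i], di[i]
        if s >= 0 and d >= 0:
            m = 0.5 - 0.25 * (F[s] + F[d])
        elif s >= 0 or d >= 0:
            p = s if s >= 0 else d
            m = 0.75 - 0.25 * F[p]
        else:
            m = 1.0
        k = 1.0 / m
        add(i, i, k)
        for p in (s, d):
            if p >= 0:
                add(p, i, -0.5 * k)
                add(i, p, -0.5 * k)
                for q in (s, d):
                    if q >= 0:
                        add(p, q, 0.25 * k)
    return sparse.csr_matrix(
        sparse.coo_matrix((vals, (rows, cols)), shape=(n, n))
    )


def partition_individuals(
    ped: Pedigree, genotyped: Iterable[str], phenotyped: Iterable[str]
) -> IndividualPartition:
    """Split individuals into genotyped parents, genotyped non-parents and
    non-genotyped non-parents; parents lacking genotypes are flagged (not an
    error, so a pedigree-only analysis can proceed)."""
    genotyped = set(genotyped)
    phenotyped = set(phenotyped)
    for name, s in (("genotyped", genotyped), ("phenotyped", phenotyped)):
        unknown = s - set(ped.ids)
        if unknown:
            raise PedigreeError(f"{name} ids not in pedigree: {sorted(unknown)[:5]}")
    parents = ped.parent_ids()
    return IndividualPartition(
        genotyped_parents=genotyped & parents,
        genotyped_nonparents=genotyped - parents,
        nongenotyped_nonparents=(phenotyped - genotyped) - parents,
        nongenotyped_parents=parents - genotyped,
    )
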