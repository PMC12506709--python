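"""Pedigree validation and relationship algebra.

The numerator relationship matrix ``A`` holds the expected additive genetic
relationships among all animals in a pedigree; its diagonal is ``1 + F`` where
``F`` is the inbreeding coefficient.  The animal-model mixed-model equations
need ``A^-1``, which Henderson's rules build directly from the pedigree in
sparse form, with inbreeding handled through the Mendelian-sampling variances
computed by the Meuwissen–Luo ancestor-tracing algorithm.

Identifiers are opaque strings; ``"0"`` (or an empty field) marks an unknown
parent.  Unknown parents are treated as unrelated, non-inbred founders.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from sireval.errors import PedigreeCycleError, PedigreeOrderError

UNKNOWN = "0"

__all__ = [
    "UNKNOWN",
    "PedigreeTable",
    "RelationshipMatrix",
    "validate_and_sort",
    "relationship_matrix",
    "inbreeding_coefficients",
    "a_inverse",
    "read_pedigree_csv",
    "write_pedigree_csv",
    "write_a_inverse_coo",
]


def _clean_id(value) -> str:
    """Normalize an identifier cell; missing/blank/'0' become UNKNOWN."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return UNKNOWN
    s = str(value).strip()
    return s if s and s != UNKNOWN else UNKNOWN


@dataclass
class PedigreeTable:
    """Animal/sire/dam triples, one row per animal.

    Attributes
    ----------
    data : pandas.DataFrame
        Columns ``animal``, ``sire``, ``dam`` (strings; ``"0"`` = unknown).
    is_sorted : bool
        True once :func:`validate_and_sort` has run (parents precede
        offspring and every named parent has its own row).
    n_founders_inserted : int
        Parents that were referenced but not listed, auto-inserted as
        founder rows during validation.
    """

    data: pd.DataFrame
    is_sorted: bool = False
    n_founders_inserted: int = 0

    def __post_init__(self) -> None:
        df = self.data.copy()
        for col in ("animal", "sire", "dam"):
            if col not in df.columns:
                raise KeyError(f"pedigree table lacks required column {col!r}")
            df[col] = df[col].map(_clean_id)
        self.data = df[["animal", "sire", "dam"]].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def ids(self) -> list[str]:
        return self.data["animal"].tolist()

    def indices(self) -> dict[str, int]:
        """Map animal id -> dense row index in the current order."""
        return {a: i for i, a in enumerate(self.data["animal"])}

    def parent_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """Sire/dam row indices per animal (-1 = unknown). Requires sorting."""
        if not self.is_sorted:
            raise PedigreeOrderError("pedigree must be validated and sorted first")
        idx = self.indices()
        sire = np.array([idx.get(s, -1) for s in self.data["sire"]], dtype=np.int64)
        dam = np.array([idx.get(d, -1) for d in self.data["dam"]], dtype=np.int64)
        return sire, dam


@dataclass
class RelationshipMatrix:
    """Dense numerator relationship matrix over an ordered animal list."""

    values: np.ndarray
    ids: list[str] = field(default_factory=list)

    @property
    def inbreeding(self) -> pd.Series:
        """F per animal: diagonal minus one."""
        return pd.Series(np.diag(self.values) - 1.0, index=self.ids, name="F")

    def loc(self, a: str, b: str) -> float:
        i = self.ids.index(a)
        j = self.ids.index(b)
        return float(self.values[i, j])


def validate_and_sort(ped: PedigreeTable | pd.DataFrame) -> PedigreeTable:
    """Validate a raw pedigree and return it in parent-first order.

    Missing parent rows are inserted as founders (unknown parents) ahead of
    the sort; the count of insertions is reported on the result.  The sort is
    Kahn's algorithm with ties broken by original input position, so repeated
    runs on the same input give the same order.

    Raises
    ------
    PedigreeCycleError
        If some animal is its own ancestor; the message names one animal on
        the cycle.
    ValueError
        If an animal id is duplicated.
    """
    if isinstance(ped, pd.DataFrame):
        ped = PedigreeTable(ped)
    df = ped.data

    animals = df["animal"]
    dup = animals[animals.duplicated()]
    if len(dup):
        raise ValueError(f"duplicate animal id(s) in pedigree: {sorted(set(dup))[:5]}")
    if (animals == UNKNOWN).any():
        raise ValueError('"0" is reserved for unknown parents and cannot be an animal id')

    known = set(animals)
    referenced = [
        p
        for col in ("sire", "dam")
        for p in df[col]
        if p != UNKNOWN and p not in known
    ]
    inserted = list(dict.fromkeys(referenced))  # de-dup, keep first-seen order
    if inserted:
        founders = pd.DataFrame(
            {"animal": inserted, "sire": UNKNOWN, "dam": UNKNOWN}
        )
        df = pd.concat([founders, df], ignore_index=True)

    # Kahn's algorithm; priority = original row position for stable ties.
    pos = {a: i for i, a in enumerate(df["animal"])}
    parents = {
        row.animal: [p for p in (row.sire, row.dam) if p != UNKNOWN]
        for row in df.itertuples()
    }
    children: dict[str, list[str]] = {a: [] for a in pos}
    indegree: dict[str, int] = {}
    for a, ps in parents.items():
        indegree[a] = len(ps)
        for p in ps:
            children[p].append(a)

    ready = [(pos[a], a) for a, deg in indegree.items() if deg == 0]
    heapq.heapify(ready)
    order: list[str] = []
    while ready:
        _, a = heapq.heappop(ready)
        order.append(a)
        for c in children[a]:
            indegree[c] -= 1
            if indegree[c] == 0:
                heapq.heappush(ready, (pos[c], c))
    if len(order) < len(pos):
        stuck = sorted(a for a, deg in indegree.items() if deg > 0)
        raise PedigreeCycleError(
            f"pedigree contains a cycle; animal {stuck[0]!r} is its own ancestor"
        )

    out = df.set_index("animal").loc[order].reset_index()
    return PedigreeTable(out, is_sorted=True, n_founders_inserted=len(inserted))


def _require_sorted(ped: PedigreeTable) -> None:
    if not ped.is_sorted:
        raise PedigreeOrderError(
            "pedigree must be passed through validate_and_sort() first"
        )


def relationship_matrix(ped: PedigreeTable) -> RelationshipMatrix:
    """Dense ``A`` by the tabular method.

    ``a_ij = 0.5 (a_j,sire(i) + a_j,dam(i))`` for previously placed ``j`` and
    ``a_ii = 1 + 0.5 a_sire(i),dam(i)``; unknown parents contribute zero.
    Intended for founder tests and desk-scale pedigrees — the evaluation
    pipeline itself only ever needs the sparse inverse.
    """
    _require_sorted(ped)
    sire, dam = ped.parent_indices()
    n = len(ped)
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        if s >= 0 and d >= 0:
            row = 0.5 * (A[s, :i] + A[d, :i])
            aii = 1.0 + 0.5 * A[s, d]
        elif s >= 0:
            row = 0.5 * A[s, :i]
            aii = 1.0
        elif d >= 0:
            row = 0.5 * A[d, :i]
            aii = 1.0
        else:
            row = 0.0
            aii = 1.0
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = aii
    return RelationshipMatrix(A, ped.ids)


def _mendelian_variances(
    sire: np.ndarray, dam: np.ndarray, F: np.ndarray
) -> np.ndarray:
    """Within-family (Mendelian-sampling) variance d_i given parental F."""
    n = len(sire)
    d = np.ones(n)
    both = (sire >= 0) & (dam >= 0)
    only_s = (sire >= 0) & (dam < 0)
    only_d = (sire < 0) & (dam >= 0)
    d[both] = 0.5 - 0.25 * (F[sire[both]] + F[dam[both]])
    d[only_s] = 0.75 - 0.25 * F[sire[only_s]]
    d[only_d] = 0.75 - 0.25 * F[dam[only_d]]
    return d


def _kinship_pair(
    i1: int,
    i2: int,
    sire: np.ndarray,
    dam: np.ndarray,
    dvec: np.ndarray,
) -> float:
    """Additive relationship a(i1, i2) by descending ancestor tracing.

    Uses the decomposition A = T D T': each animal's genome-contribution row
    of T is expanded lazily toward its ancestors, and the cross-product with
    the Mendelian variances accumulates the relationship.  Processing indices
    in descending order guarantees a coefficient is final when popped,
    because parents always precede offspring in a sorted pedigree.
    """
    t1: dict[int, float] = {i1: 1.0}
    t2: dict[int, float] = {i2: 1.0}
    heap = [-i1, -i2] if i1 != i2 else [-i1]
    heapq.heapify(heap)
    seen = set(heap)
    acc = 0.0
    while heap:
        j = -heapq.heappop(heap)
        c1 = t1.pop(j, 0.0)
        c2 = t2.pop(j, 0.0)
        acc += c1 * c2 * dvec[j]
        for p in (sire[j], dam[j]):
            if p < 0:
                continue
            if c1:
                t1[p] = t1.get(p, 0.0) + 0.5 * c1
            if c2:
                t2[p] = t2.get(p, 0.0) + 0.5 * c2
            if -p not in seen:
                heapq.heappush(heap, -p)
                seen.add(-p)
    return acc


def inbreeding_coefficients(ped: PedigreeTable) -> pd.Series:
    """Inbreeding coefficient per animal (Meuwissen–Luo ancestor tracing).

    Matches ``diag(A) - 1`` from the tabular method exactly, without ever
    forming the dense matrix.
    """
    _require_sorted(ped)
    sire, dam = ped.parent_indices()
    n = len(ped)
    F = np.zeros(n)
    d = np.ones(n)
    for i in range(n):
        s, t = sire[i], dam[i]
        if s >= 0 and t >= 0:
            F[i] = 0.5 * _kinship_pair(s, t, sire, dam, d[:i])
            d[i] = 0.5 - 0.25 * (F[s] + F[t])
        elif s >= 0:
            d[i] = 0.75 - 0.25 * F[s]
        elif t >= 0:
            d[i] = 0.75 - 0.25 * F[t]
    return pd.Series(F, index=ped.ids, name="F")


def a_inverse(ped: PedigreeTable) -> sp.csr_matrix:
    """Sparse ``A^-1`` by Henderson's rules with inbreeding.

    The nonzero pattern touches only {animal, sire, dam} triplets; row/column
    order follows the sorted pedigree (``ped.ids``).
    """
    _require_sorted(ped)
    sire, dam = ped.parent_indices()
    F = inbreeding_coefficients(ped).to_numpy()
    alpha = 1.0 / _mendelian_variances(sire, dam, F)

    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []

    def add(i: int, j: int, v: float) -> None:
        rows.append(i)
        cols.append(j)
        vals.append(v)

    n = len(ped)
    for i in range(n):
        a = alpha[i]
        add(i, i, a)
        known = [p for p in (sire[i], dam[i]) if p >= 0]
        for p in known:
            add(i, p, -0.5 * a)
            add(p, i, -0.5 * a)
        for p in known:
            for q in known:
                add(p, q, 0.25 * a)
    return sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()


# ---------------------------------------------------------------------------
# I/O

def read_pedigree_csv(path) -> PedigreeTable:
    """Read an animal,sire,dam CSV ("0" = unknown parent)."""
    df = pd.read_csv(path, dtype=str)
    return PedigreeTable(df)


def write_pedigree_csv(ped: PedigreeTable, path) -> None:
    ped.data.to_csv(path, index=False)


def write_a_inverse_coo(ainv: sp.spmatrix, ids: list[str], path) -> None:
    """Export A^-1 as coordinate-format text: animal_i, animal_j, value."""
    coo = sp.coo_matrix(sp.triu(ainv))
    out = pd.DataFrame(
        {
            "animal_i": [ids[i] for i in coo.row],
            "animal_j": [ids[j] for j in coo.col],
            "value": coo.data,
        }
    )
    out.to_csv(path, index=False)
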