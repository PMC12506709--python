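"""Single-trait animal-model BLUP via Henderson's mixed-model equations.

Model: ``y = X b + Z u + e`` with ``u ~ N(0, A sigma2_a)`` and
``e ~ N(0, I sigma2_e)``.  The MME are::

    [ X'X        X'Z            ] [ b ]   [ X'y ]
    [ Z'X   Z'Z + lambda A^-1   ] [ u ] = [ Z'y ],   lambda = sigma2_e / sigma2_a

Fixed effects use reference coding (first level of each factor dropped, plus
an intercept), which makes the fixed block full rank for connected data.
Prediction-error variances come from the diagonal of the inverse coefficient
matrix: ``PEV_i = C^uu_ii * sigma2_e``; reliability is ``1 - PEV/sigma2_a``
(clamped to [0, 1]) and accuracy its square root.  PTA — the predicted
transmitting ability, i.e. the expected deviation passed to progeny — is half
the EBV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from sireval.errors import IdentifiabilityError, LinkageError

__all__ = [
    "ModelSpec",
    "MMESystem",
    "EBVSet",
    "design_matrix",
    "build_mme",
    "solve_blup",
    "accuracy_from_pev",
]

# Above this many equations the full inverse is skipped and PEVs are computed
# only for requested animals by unit-vector solves against the LU factors.
_DENSE_PEV_LIMIT = 2000


@dataclass
class ModelSpec:
    """Fixed-effects structure of a single-trait analysis.

    ``fixed_factors`` is an ordered list of column names; a 2-tuple denotes
    an interaction between two factors.  Interaction cells with fewer than
    ``min_interaction_records`` observations get no parameter (they are
    absorbed into the residual).
    """

    response: str
    fixed_factors: Sequence[str | tuple[str, str]] = field(default_factory=list)
    min_interaction_records: int = 2

    def factor_columns(self) -> list[str]:
        cols: list[str] = []
        for f in self.fixed_factors:
            cols.extend(f if isinstance(f, tuple) else (f,))
        return list(dict.fromkeys(cols))


def design_matrix(
    records: pd.DataFrame, spec: ModelSpec
) -> tuple[np.ndarray, list[str]]:
    """Reference-coded fixed-effects design matrix with an intercept.

    Returns the dense ``n x p`` matrix and the parameter names
    (``"(intercept)"``, then ``factor=level`` per retained non-reference
    level in factor order).
    """
    n = len(records)
    columns: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["(intercept)"]
    for f in spec.fixed_factors:
        if isinstance(f, tuple):
            fa, fb = f
            lab = records[fa].astype(str) + "*" + records[fb].astype(str)
            counts = lab.value_counts()
            keep = sorted(counts.index[counts >= spec.min_interaction_records])
            fname = f"{fa}:{fb}"
            levels = keep[1:]  # first retained cell is the reference
            for lv in levels:
                columns.append((lab == lv).to_numpy(dtype=float))
                names.append(f"{fname}={lv}")
        else:
            lab = records[f].astype(str)
            levels = sorted(lab.unique())[1:]
            for lv in levels:
                columns.append((lab == lv).to_numpy(dtype=float))
                names.append(f"{f}={lv}")
    X = np.column_stack(columns)
    return X, names


def _check_fixed_rank(X: np.ndarray, names: list[str]) -> None:
    s = np.linalg.svd(X, compute_uv=False)
    tol = s.max() * max(X.shape) * np.finfo(float).eps
    rank = int((s > tol).sum())
    if rank < X.shape[1]:
        # identify aliased columns via pivoted QR
        from scipy.linalg import qr

        _, rmat, piv = qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(rmat))
        bad = [names[piv[k]] for k in range(len(diag)) if diag[k] <= tol * 10]
        bad = bad or [names[piv[k]] for k in range(rank, X.shape[1])]
        raise IdentifiabilityError(
            f"aliased fixed-effect levels after reference coding: {bad}"
        )


@dataclass
class MMESystem:
    """Assembled mixed-model equations (sparse) plus index bookkeeping."""

    coeff: sp.csr_matrix
    rhs: np.ndarray
    fixed_names: list[str]
    animal_ids: list[str]
    sigma2_a: float
    sigma2_e: float
    yty: float
    n_records: int
    n_progeny_records: pd.Series

    @property
    def lambda_(self) -> float:
        return self.sigma2_e / self.sigma2_a

    @property
    def n_fixed(self) -> int:
        return len(self.fixed_names)


@dataclass
class EBVSet:
    """Per-animal evaluation: EBV, PEV, reliability, accuracy, PTA.

    ``table`` is indexed by animal id with columns ``ebv``, ``pev``,
    ``reliability``, ``accuracy``, ``pta``, ``n_progeny_records``.  PEV (and
    hence reliability/accuracy) may be NaN for animals it was not requested
    for on large systems.
    """

    table: pd.DataFrame
    sigma2_a: float

    def __len__(self) -> int:
        return len(self.table)


def accuracy_from_pev(pev: float, sigma2_a: float) -> tuple[float, float]:
    """(reliability, accuracy) from a prediction-error variance.

    reliability = 1 - PEV/sigma2_a clamped to [0, 1]; accuracy = sqrt(rel).
    """
    if pev < 0 or sigma2_a <= 0:
        raise ValueError(
            f"need pev >= 0 and sigma2_a > 0, got pev={pev}, sigma2_a={sigma2_a}"
        )
    rel = float(np.clip(1.0 - pev / sigma2_a, 0.0, 1.0))
    return rel, float(np.sqrt(rel))


def build_mme(
    records: pd.DataFrame,
    spec: ModelSpec,
    a_inv: sp.spmatrix,
    sigma2_a: float,
    sigma2_e: float,
    animal_ids: Sequence[str],
) -> MMESystem:
    """Assemble Henderson's MME for one trait.

    ``a_inv`` is the sparse inverse numerator relationship matrix whose
    row/column order is ``animal_ids`` (the sorted pedigree order).  Records
    with a missing response are dropped.  Every recorded animal must appear
    in ``animal_ids``.
    """
    if sigma2_a <= 0 or sigma2_e <= 0:
        raise ValueError("variance components must be positive")
    animal_ids = list(animal_ids)
    recs = records.dropna(subset=[spec.response])
    idx = {a: i for i, a in enumerate(animal_ids)}
    missing = [a for a in recs["animal"].astype(str) if a not in idx]
    if missing:
        raise LinkageError(
            f"{len(missing)} recorded animal(s) absent from pedigree, "
            f"e.g. {missing[:3]}"
        )

    y = recs[spec.response].to_numpy(dtype=float)
    n = len(recs)
    q = len(animal_ids)
    X, fixed_names = design_matrix(recs, spec)
    _check_fixed_rank(X, fixed_names)
    p = X.shape[1]

    rows = np.array([idx[a] for a in recs["animal"].astype(str)])
    Z = sp.coo_matrix((np.ones(n), (np.arange(n), rows)), shape=(n, q)).tocsr()

    lam = sigma2_e / sigma2_a
    Xs = sp.csr_matrix(X)
    top = sp.hstack([Xs.T @ Xs, Xs.T @ Z], format="csr")
    bottom = sp.hstack([Z.T @ Xs, Z.T @ Z + lam * a_inv.tocsr()], format="csr")
    coeff = sp.vstack([top, bottom], format="csr")
    rhs = np.concatenate([X.T @ y, Z.T @ y])

    if "sire" in recs.columns:
        prog = recs["sire"].astype(str).value_counts()
        n_prog = pd.Series(0, index=animal_ids, dtype=int)
        common = prog.index.intersection(n_prog.index)
        n_prog.loc[common] = prog.loc[common].astype(int)
    else:
        n_prog = pd.Series(0, index=animal_ids, dtype=int)

    return MMESystem(
        coeff=coeff,
        rhs=rhs,
        fixed_names=fixed_names,
        animal_ids=animal_ids,
        sigma2_a=float(sigma2_a),
        sigma2_e=float(sigma2_e),
        yty=float(y @ y),
        n_records=n,
        n_progeny_records=n_prog,
    )


def solve_blup(
    system: MMESystem, pev_for: Sequence[str] | None = None
) -> tuple[pd.Series, EBVSet]:
    """Solve the MME and return fixed-effect solutions plus an EBV set.

    PEVs come from the diagonal of the inverse coefficient matrix.  Small
    systems invert densely; larger ones solve one unit vector per animal in
    ``pev_for`` (default: every animal with progeny records, i.e. the
    parents under evaluation) against the sparse LU factors.
    """
    M = system.coeff.tocsc()
    dim = M.shape[0]
    try:
        lu = spla.splu(M)
    except RuntimeError as exc:  # pragma: no cover - guarded by rank check
        raise IdentifiabilityError(f"singular mixed-model equations: {exc}") from exc
    sol = lu.solve(system.rhs)
    resid = np.linalg.norm(M @ sol - system.rhs)
    scale = np.linalg.norm(system.rhs)
    if scale > 0 and resid > 1e-8 * scale:
        sol += lu.solve(system.rhs - M @ sol)  # one refinement step

    p = system.n_fixed
    fixed = pd.Series(sol[:p], index=system.fixed_names, name="solution")
    ebv = sol[p:]

    pev = np.full(len(system.animal_ids), np.nan)
    if dim <= _DENSE_PEV_LIMIT:
        cinv = np.linalg.inv(M.toarray())
        pev = np.diag(cinv)[p:] * system.sigma2_e
    else:
        if pev_for is None:
            wanted = system.n_progeny_records[system.n_progeny_records > 0].index
        else:
            wanted = pd.Index(pev_for)
        pos = {a: i for i, a in enumerate(system.animal_ids)}
        cols = np.array([pos[a] for a in wanted], dtype=int)
        if len(cols):
            rhs = np.zeros((dim, len(cols)))
            rhs[p + cols, np.arange(len(cols))] = 1.0
            sols = lu.solve(rhs)
            pev[cols] = sols[p + cols, np.arange(len(cols))] * system.sigma2_e

    rel = np.clip(1.0 - pev / system.sigma2_a, 0.0, 1.0)
    table = pd.DataFrame(
        {
            "ebv": ebv,
            "pev": pev,
            "reliability": rel,
            "accuracy": np.sqrt(rel),
            "pta": ebv / 2.0,
            "n_progeny_records": system.n_progeny_records.to_numpy(),
        },
        index=pd.Index(system.animal_ids, name="animal"),
    )
    return fixed, EBVSet(table=table, sigma2_a=system.sigma2_a)
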