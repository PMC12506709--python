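"""Half-sib progeny-test simulator.

Generates pedigrees and daughter phenotype records with a known genetic
architecture (additive covariance ``G``, residual covariance ``E``, fixed
effects for genotype grade, parity and location), so that every downstream
estimation stage — REML, BLUP, correlations, the selection index — can be
validated against truth without any external data.

The default family structure is paternal half-sib: every daughter gets a
unique, unrelated dam, so daughters of one sire share only that sire
(expected additive relationship 0.25).  A shared-dam policy producing
full-sib groups is available but off by default.

Breeding values are generated founder-by-founder from ``N(0, G)`` and
transmitted down the pedigree as the mid-parent average plus a
Mendelian-sampling deviation with covariance ``0.5 G`` scaled by
``(1 - mean parental inbreeding)``, which reproduces the numerator
relationship matrix exactly.  A single RNG stream keyed by the seed is used,
with a fixed draw order (founder/progeny breeding-value normals, then parity
levels, location levels, and residuals), so a fixed seed gives bit-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from sireval.errors import InvalidDesignError, ModelError
from sireval.pedigree import (
    PedigreeTable,
    UNKNOWN,
    inbreeding_coefficients,
    validate_and_sort,
)

__all__ = [
    "SimDesign",
    "TraitModel",
    "SimulatedPedigree",
    "SimulatedPhenotypes",
    "simulate_pedigree",
    "simulate_phenotypes",
]

_PSD_TOL = 1e-8


@dataclass
class SimDesign:
    """Design of a progeny-test simulation.

    Parameters
    ----------
    n_sires : int
        Number of sires under test.
    progeny_per_sire : int or sequence of int
        Daughters per sire; a scalar applies to every sire.
    genotype_grades : mapping of grade label -> number of sires
        Allocation of sires to genetic groups; must sum to ``n_sires``.
        Grades act as a sire-level fixed effect inherited by daughters.
    dam_policy : {"unique", "shared"}
        "unique": one unrelated dam per daughter (paternal half-sibs).
        "shared": dams drawn from a pool of ``n_shared_dams``, producing
        full-sib groups.
    n_shared_dams : int
        Size of the dam pool under the "shared" policy.
    seed : int
        Seed for the single RNG stream.
    """

    n_sires: int
    progeny_per_sire: int | Sequence[int] = 1
    genotype_grades: Mapping[str, int] | None = None
    dam_policy: str = "unique"
    n_shared_dams: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sires < 1:
            raise InvalidDesignError(f"n_sires must be >= 1, got {self.n_sires}")
        counts = self.progeny_counts()
        if (counts < 1).any():
            raise InvalidDesignError("every per-sire progeny count must be >= 1")
        if self.genotype_grades is not None:
            total = sum(self.genotype_grades.values())
            if total != self.n_sires:
                raise InvalidDesignError(
                    f"grade allocation sums to {total}, expected n_sires={self.n_sires}"
                )
        if self.dam_policy not in ("unique", "shared"):
            raise InvalidDesignError(f"unknown dam_policy {self.dam_policy!r}")
        if self.dam_policy == "shared" and self.n_shared_dams < 1:
            raise InvalidDesignError("shared dam_policy needs n_shared_dams >= 1")

    def progeny_counts(self) -> np.ndarray:
        if np.isscalar(self.progeny_per_sire):
            return np.full(self.n_sires, int(self.progeny_per_sire), dtype=np.int64)
        counts = np.asarray(list(self.progeny_per_sire), dtype=np.int64)
        if len(counts) != self.n_sires:
            raise InvalidDesignError(
                f"progeny_per_sire has {len(counts)} entries for {self.n_sires} sires"
            )
        return counts

    def sire_grade_labels(self) -> list[str]:
        """Grade label per sire, in sire order."""
        if self.genotype_grades is None:
            return ["-"] * self.n_sires
        labels: list[str] = []
        for grade, k in self.genotype_grades.items():
            labels.extend([grade] * k)
        return labels


def _check_psd(m: np.ndarray, name: str) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ModelError(f"{name} must be square, got shape {m.shape}")
    if not np.allclose(m, m.T, atol=1e-10):
        raise ModelError(f"{name} must be symmetric")
    w = np.linalg.eigvalsh(m)
    if w.min() < -_PSD_TOL * max(1.0, w.max()):
        raise ModelError(f"{name} is not positive semi-definite (min eig {w.min():.3g})")
    return m


def _psd_sqrt(m: np.ndarray) -> np.ndarray:
    """Symmetric square root tolerant of PSD-singular matrices."""
    w, v = np.linalg.eigh(m)
    w = np.clip(w, 0.0, None)
    return v * np.sqrt(w) @ v.T


@dataclass
class TraitModel:
    """Genetic architecture for one or more traits.

    ``G`` and ``E`` are additive-genetic and residual variance-covariance
    matrices (trait x trait); the implied heritability of trait *t* is
    ``G[t,t] / (G[t,t] + E[t,t])``.  ``fixed_effects`` maps factor name ->
    {level -> per-trait effect vector}; the "grade" factor is taken from the
    pedigree's sire grades, all other factors are assigned to records
    uniformly at random.
    """

    trait_names: Sequence[str]
    G: np.ndarray
    E: np.ndarray
    overall_means: Sequence[float] | None = None
    fixed_effects: Mapping[str, Mapping[str, Sequence[float]]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        t = len(self.trait_names)
        self.G = _check_psd(self.G, "G")
        self.E = _check_psd(self.E, "E")
        if self.G.shape != (t, t) or self.E.shape != (t, t):
            raise ModelError(
                f"G/E shapes {self.G.shape}/{self.E.shape} do not match {t} traits"
            )
        if self.overall_means is None:
            self.overall_means = np.zeros(t)
        self.overall_means = np.asarray(self.overall_means, dtype=float)
        if self.overall_means.shape != (t,):
            raise ModelError("overall_means length must equal number of traits")
        for factor, levels in self.fixed_effects.items():
            for level, eff in levels.items():
                if len(np.atleast_1d(eff)) != t:
                    raise ModelError(
                        f"effect vector for {factor}={level} must have {t} entries"
                    )

    @property
    def n_traits(self) -> int:
        return len(self.trait_names)

    def heritabilities(self) -> np.ndarray:
        dg = np.diag(self.G)
        return dg / (dg + np.diag(self.E))


@dataclass
class SimulatedPedigree(PedigreeTable):
    """Pedigree plus simulation metadata (grade per sire, sire of each daughter)."""

    sire_grades: dict[str, str] = field(default_factory=dict)


@dataclass
class SimulatedPhenotypes:
    """Daughter records plus the true breeding values behind them.

    ``records`` has one row per daughter: animal, sire, parity, location,
    grade, then one column per trait.  ``breeding_values`` holds the true
    additive genetic values for *every* animal in the pedigree (useful for
    checking estimators against truth).
    """

    records: pd.DataFrame
    breeding_values: pd.DataFrame


def simulate_pedigree(design: SimDesign) -> SimulatedPedigree:
    """Build the pedigree implied by a design: sire founders, dams, daughters.

    Deterministic for a fixed design (dam assignment under the "shared"
    policy uses the design seed).
    """
    counts = design.progeny_counts()
    n_prog = int(counts.sum())
    rng = np.random.default_rng(design.seed)

    sw = max(3, len(str(design.n_sires)))
    pw = max(5, len(str(n_prog)))
    sire_ids = [f"S{i + 1:0{sw}d}" for i in range(design.n_sires)]

    if design.dam_policy == "unique":
        dam_ids = [f"D{i + 1:0{pw}d}" for i in range(n_prog)]
        dam_of = list(range(n_prog))
    else:
        dam_ids = [f"D{i + 1:0{pw}d}" for i in range(design.n_shared_dams)]
        dam_of = rng.integers(0, design.n_shared_dams, size=n_prog).tolist()

    prog_ids = [f"P{i + 1:0{pw}d}" for i in range(n_prog)]
    sire_of = np.repeat(np.arange(design.n_sires), counts)

    rows = (
        [(s, UNKNOWN, UNKNOWN) for s in sire_ids]
        + [(d, UNKNOWN, UNKNOWN) for d in dam_ids]
        + [
            (prog_ids[k], sire_ids[sire_of[k]], dam_ids[dam_of[k]])
            for k in range(n_prog)
        ]
    )
    df = pd.DataFrame(rows, columns=["animal", "sire", "dam"])
    sorted_ped = validate_and_sort(PedigreeTable(df))
    grades = dict(zip(sire_ids, design.sire_grade_labels()))
    return SimulatedPedigree(
        sorted_ped.data, is_sorted=True, sire_grades=grades
    )


def simulate_phenotypes(
    pedigree: PedigreeTable, model: TraitModel, seed: int
) -> SimulatedPhenotypes:
    """Draw breeding values down the pedigree and phenotypes for progeny.

    Phenotype = overall mean + fixed effects + breeding value + residual.
    Only animals with at least one known parent ("progeny") receive records.
    """
    if not pedigree.is_sorted:
        pedigree = validate_and_sort(pedigree)
    rng = np.random.default_rng(seed)
    t = model.n_traits
    n = len(pedigree)
    ids = pedigree.ids
    sire_idx, dam_idx = pedigree.parent_indices()
    F = inbreeding_coefficients(pedigree).to_numpy()

    sqrt_g = _psd_sqrt(model.G)
    sqrt_e = _psd_sqrt(model.E)

    # Draw order: one standard-normal row per animal (founders and progeny
    # alike, pedigree order), then factor levels, then residuals.
    z = rng.standard_normal((n, t))
    bv = np.empty((n, t))
    for i in range(n):
        s, d = sire_idx[i], dam_idx[i]
        if s < 0 and d < 0:
            bv[i] = sqrt_g @ z[i]
            continue
        mid = np.zeros(t)
        mend = 1.0
        if s >= 0 and d >= 0:
            mid = 0.5 * (bv[s] + bv[d])
            mend = 0.5 * (1.0 - 0.5 * (F[s] + F[d]))
        elif s >= 0:
            mid = 0.5 * bv[s]
            mend = 0.75 - 0.25 * F[s]
        else:
            mid = 0.5 * bv[d]
            mend = 0.75 - 0.25 * F[d]
        bv[i] = mid + np.sqrt(mend) * (sqrt_g @ z[i])

    is_prog = (sire_idx >= 0) | (dam_idx >= 0)
    prog = np.flatnonzero(is_prog)
    n_rec = len(prog)

    sire_grades = getattr(pedigree, "sire_grades", {})
    sires = pedigree.data["sire"].to_numpy()

    cols: dict[str, object] = {
        "animal": [ids[i] for i in prog],
        "sire": [sires[i] for i in prog],
    }
    effects = np.zeros((n_rec, t))
    for factor in ("parity", "location"):
        levels = model.fixed_effects.get(factor)
        if levels:
            names = list(levels)
            draw = rng.integers(0, len(names), size=n_rec)
            cols[factor] = [names[k] for k in draw]
            eff = np.asarray([np.atleast_1d(levels[nm]) for nm in names], dtype=float)
            effects += eff[draw]
        else:
            cols[factor] = ["1"] * n_rec
    grade_levels = model.fixed_effects.get("grade", {})
    grade_col = [sire_grades.get(s, "-") for s in (sires[i] for i in prog)]
    cols["grade"] = grade_col
    for k, g in enumerate(grade_col):
        if g in grade_levels:
            effects[k] += np.atleast_1d(grade_levels[g])

    resid = rng.standard_normal((n_rec, t)) @ sqrt_e.T
    y = model.overall_means + effects + bv[prog] + resid

    records = pd.DataFrame(cols)
    for j, trait in enumerate(model.trait_names):
        records[trait] = y[:, j]
    bv_df = pd.DataFrame(bv, index=ids, columns=list(model.trait_names))
    bv_df.index.name = "animal"
    return SimulatedPhenotypes(records=records, breeding_values=bv_df)
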