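"""Shipped study conditions for the crossbred progeny-test example.

These presets describe a Holstein-Friesian x Local (HF x L) crossbred
progeny-testing scheme: 51 sires in three genotype grades (50%, 62.5% and
75% HF ancestry, with 8, 12 and 31 sires respectively), 4,319 daughter
records with per-sire family sizes ranging from 7 to 628, and eight
productive/reproductive traits:

====  =======================  =========
code  trait                    unit
====  =======================  =========
BWT   birth weight of calf     kg
AFC   age at first conception  months
SPC   services per conception  count
DMY   daily milk yield         l/day
PMY   peak milk yield          l/day
LL    lactation length         days
DO    days open                days
CI    calving interval         months
====  =======================  =========

The genetic architecture (additive and residual variances, genetic and
phenotypic correlations), per-grade trait means and the economic-value
vector are the published estimates for this population, so simulations run
under these presets have realistic heritabilities (0.09-0.32) and a
realistic unbalanced family-size distribution.  The residual covariance is
derived as ``E = P - G`` from the phenotypic and genetic matrices; because
the published correlations were estimated pairwise, the implied ``E`` can
have slightly negative eigenvalues and is projected to the nearest
positive semi-definite matrix (eigenvalue floor) before use.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq

from sireval.synthetic_data import SimDesign, TraitModel

__all__ = [
    "TRAITS",
    "TRAIT_UNITS",
    "GENOTYPE_GRADES",
    "SIGMA2_A",
    "SIGMA2_E",
    "ECONOMIC_WEIGHTS",
    "genetic_correlations",
    "phenotypic_correlations",
    "family_sizes",
    "crossbred_design",
    "crossbred_trait_model",
    "index_matrices",
]

TRAITS = ["BWT", "AFC", "SPC", "DMY", "PMY", "LL", "DO", "CI"]
TRAIT_UNITS = {
    "BWT": "kg",
    "AFC": "months",
    "SPC": "count",
    "DMY": "l/day",
    "PMY": "l/day",
    "LL": "days",
    "DO": "days",
    "CI": "months",
}

GENOTYPE_GRADES = {"50%HF": 8, "62.5%HF": 12, "75%HF": 31}

# additive genetic and residual variances per trait
SIGMA2_A = dict(
    zip(TRAITS, [3.42, 3.78, 0.05, 1.66, 2.46, 263.29, 141.94, 1.07])
)
SIGMA2_E = dict(
    zip(TRAITS, [17.95, 10.41, 0.44, 5.32, 7.05, 1242.60, 705.53, 2.21])
)

# economic value per unit of each trait (relative units)
ECONOMIC_WEIGHTS = dict(
    zip(TRAITS, [-8.93, -12.61, -30.91, -20.36, -4.03, -0.98, 0.44, 29.86])
)

# upper triangle of the genetic correlation matrix, row by row
_RG_UPPER = [
    [-0.14, 0.33, 0.06, 0.07, -0.17, -0.12, 0.20],
    [0.35, -0.34, -0.40, -0.17, 0.17, 0.06],
    [-0.16, -0.16, -0.24, 0.19, 0.01],
    [0.97, -0.06, 0.11, 0.20],
    [-0.06, 0.14, 0.29],
    [0.04, -0.08],
    [0.50],
]

# lower triangle of the phenotypic correlation matrix, row by row
_RP_LOWER = [
    [-0.07],
    [-0.02, 0.016],
    [0.23, -0.25, -0.02],
    [0.26, -0.26, -0.03, 0.92],
    [0.06, -0.05, -0.06, 0.02, 0.08],
    [-0.04, 0.12, 0.03, 0.09, 0.06, -0.11],
    [0.06, 0.07, 0.01, 0.02, 0.03, -0.15, 0.25],
]

# per-grade daughter trait means (grade order: 50%HF, 62.5%HF, 75%HF)
GRADE_MEANS = {
    "BWT": [24.60, 25.61, 27.20],
    "AFC": [22.17, 20.45, 19.66],
    "SPC": [1.66, 1.56, 1.60],
    "DMY": [6.59, 7.48, 8.55],
    "PMY": [8.05, 9.32, 10.44],
    "LL": [215.32, 218.20, 233.53],
    "DO": [107.48, 110.19, 101.13],
    "CI": [13.09, 13.69, 12.97],
}
# approximate daughter counts per grade, used to weight the overall mean
_GRADE_N = np.array([959.0, 822.0, 2589.0])

N_SIRES = 51
N_DAUGHTERS = 4319
MIN_FAMILY = 7
MAX_FAMILY = 628


def genetic_correlations() -> np.ndarray:
    t = len(TRAITS)
    R = np.eye(t)
    for i, row in enumerate(_RG_UPPER):
        R[i, i + 1 :] = row
        R[i + 1 :, i] = row
    return R


def phenotypic_correlations() -> np.ndarray:
    t = len(TRAITS)
    R = np.eye(t)
    for i, row in enumerate(_RP_LOWER):
        R[i + 1, : i + 1] = row
        R[: i + 1, i + 1] = row
    return R


def family_sizes(
    n_sires: int = N_SIRES,
    total: int = N_DAUGHTERS,
    smallest: int = MIN_FAMILY,
    largest: int = MAX_FAMILY,
) -> np.ndarray:
    """Deterministic right-skewed family-size vector.

    Sizes follow ``smallest + a * exp(b i / (n-1))`` with ``a, b`` solved so
    the largest family and the total come out exactly; fractional parts are
    resolved by largest-remainder rounding.  The default reproduces the
    shipped design: 51 families, sizes 7..628, summing to 4,319.
    """
    n = n_sires
    spread = largest - smallest
    budget = total - n * smallest

    i = np.arange(n)

    def total_for(b: float) -> float:
        a = spread / np.exp(b)
        return float((a * np.exp(b * i / (n - 1))).sum()) - budget

    b = brentq(total_for, 1e-6, 50.0)
    x = smallest + (spread / np.exp(b)) * np.exp(b * i / (n - 1))
    base = np.floor(x).astype(np.int64)
    short = int(total - base.sum())
    order = np.argsort(-(x - base), kind="stable")
    base[order[:short]] += 1
    # pin the extreme family sizes exactly, compensating in the middle
    for pos, target in ((0, smallest), (n - 1, largest)):
        delta = target - base[pos]
        base[pos] += delta
        base[n // 2] -= delta
    assert base.sum() == total and base.min() >= smallest and base.max() == largest
    return base


def _grade_effects() -> dict[str, dict[str, list[float]]]:
    w = _GRADE_N / _GRADE_N.sum()
    grades = list(GENOTYPE_GRADES)
    eff: dict[str, list[float]] = {g: [] for g in grades}
    for trait in TRAITS:
        means = np.array(GRADE_MEANS[trait])
        overall = float(w @ means)
        for g, m in zip(grades, means):
            eff[g].append(m - overall)
    return eff


def _spread_effects(factor_levels: list[str], scale: float) -> dict[str, list[float]]:
    """Symmetric per-level effects spanning ``scale`` phenotypic SDs."""
    sd_p = np.sqrt(
        np.array([SIGMA2_A[t] + SIGMA2_E[t] for t in TRAITS])
    )
    k = len(factor_levels)
    out = {}
    for j, lv in enumerate(factor_levels):
        frac = (j - (k - 1) / 2) / max(k - 1, 1)
        out[lv] = list(frac * scale * sd_p)
    return out


def overall_means() -> np.ndarray:
    w = _GRADE_N / _GRADE_N.sum()
    return np.array([float(w @ np.array(GRADE_MEANS[t])) for t in TRAITS])


def crossbred_design(
    seed: int = 0,
    n_sires: int = N_SIRES,
    total_daughters: int = N_DAUGHTERS,
) -> SimDesign:
    """The shipped 51-sire, 4,319-daughter half-sib design (scalable)."""
    if n_sires == N_SIRES and total_daughters == N_DAUGHTERS:
        counts = family_sizes()
        grades = dict(GENOTYPE_GRADES)
    else:
        per = max(1, total_daughters // n_sires)
        counts = np.full(n_sires, per, dtype=np.int64)
        counts[-1] += total_daughters - counts.sum()
        shares = np.array(list(GENOTYPE_GRADES.values()), dtype=float)
        alloc = np.floor(shares / shares.sum() * n_sires).astype(int)
        alloc[-1] += n_sires - alloc.sum()
        grades = dict(zip(GENOTYPE_GRADES, alloc.tolist()))
        grades = {g: k for g, k in grades.items() if k > 0}
    return SimDesign(
        n_sires=n_sires,
        progeny_per_sire=counts.tolist(),
        genotype_grades=grades,
        dam_policy="unique",
        seed=seed,
    )


def crossbred_trait_model(
    n_parity: int = 3, n_locations: int = 6
) -> TraitModel:
    """Eight-trait model with the published (co)variance structure.

    Parity and location effects are deterministic symmetric spreads of 0.2
    and 0.3 phenotypic SDs respectively; genotype-grade effects reproduce
    the per-grade mean differences.
    """
    sd_a = np.sqrt([SIGMA2_A[t] for t in TRAITS])
    sd_p = np.sqrt([SIGMA2_A[t] + SIGMA2_E[t] for t in TRAITS])
    G = np.outer(sd_a, sd_a) * genetic_correlations()
    P = np.outer(sd_p, sd_p) * phenotypic_correlations()
    E = P - G
    # pairwise-estimated published correlations need not yield a PSD E
    w, v = np.linalg.eigh(E)
    if w.min() < 0:
        w = np.clip(w, 1e-6 * w.max(), None)
        E = (v * w) @ v.T
    fixed = {
        "grade": _grade_effects(),
        "parity": _spread_effects([str(k) for k in range(1, n_parity + 1)], 0.2),
        "location": _spread_effects(
            [f"L{k}" for k in range(1, n_locations + 1)], 0.3
        ),
    }
    return TraitModel(
        trait_names=TRAITS,
        G=G,
        E=E,
        overall_means=overall_means(),
        fixed_effects=fixed,
    )


def index_matrices() -> tuple[np.ndarray, np.ndarray]:
    """(P, G) variance-covariance matrices in shipped trait order."""
    model = crossbred_trait_model()
    return model.G + model.E, model.G
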