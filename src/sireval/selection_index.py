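"""Multi-trait economic selection index (Hazel index).

The index coefficients are ``b = P^-1 G a`` where ``P`` is the phenotypic
variance-covariance matrix of the indicator traits, ``G`` the genetic
variance-covariance matrix, and ``a`` the vector of economic values per unit
of each trait.  Each candidate bull's total score is the weighted sum of its
standardized breeding values, ``I = sum_t b_t X_t``; bulls are ranked by
``I`` and the top fraction selected.

Traits where "lower is better" enter through the sign of their supplied
weight — no sign flipping is applied here.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from sireval.errors import ConditioningError

__all__ = [
    "IndexInputs",
    "IndexResult",
    "index_weights",
    "standardize_ebv",
    "total_score",
    "rank_and_select",
    "build_index",
]


@dataclass
class IndexInputs:
    """P, G and the economic-value vector a, over a shared trait order."""

    P: np.ndarray
    G: np.ndarray
    a: np.ndarray
    trait_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        self.G = np.asarray(self.G, dtype=float)
        self.a = np.asarray(self.a, dtype=float).ravel()
        t = len(self.a)
        if self.P.shape != (t, t) or self.G.shape != (t, t):
            raise ValueError(
                f"P {self.P.shape}, G {self.G.shape} and a ({t}) disagree in size"
            )
        if not np.allclose(self.P, self.P.T, atol=1e-10):
            raise ValueError("P must be symmetric")
        if not np.allclose(self.G, self.G.T, atol=1e-10):
            raise ValueError("G must be symmetric")


def index_weights(inputs: IndexInputs) -> np.ndarray:
    """Coefficient vector ``b = P^-1 G a``; no normalization applied."""
    eigmin = float(np.linalg.eigvalsh(inputs.P).min())
    if eigmin <= 0:
        raise ConditioningError(
            f"P is not positive definite (smallest eigenvalue {eigmin:.3g})"
        )
    return np.linalg.solve(inputs.P, inputs.G @ inputs.a)


def standardize_ebv(ebvs: pd.DataFrame, sample_sd: bool = False) -> pd.DataFrame:
    """Z-score each trait's EBVs across the candidate bulls.

    Population-SD convention by default (``ddof=0``); ``sample_sd=True``
    switches to ddof=1.  A zero-variance trait standardizes to all zeros
    with a warning.
    """
    if len(ebvs) < 2:
        raise ValueError("standardization needs at least 2 bulls")
    ddof = 1 if sample_sd else 0
    out = {}
    for trait in ebvs.columns:
        x = ebvs[trait].to_numpy(dtype=float)
        sd = x.std(ddof=ddof)
        if sd == 0:
            warnings.warn(f"trait {trait!r} has zero EBV variance; X set to 0")
            out[trait] = np.zeros(len(x))
        else:
            out[trait] = (x - x.mean()) / sd
    return pd.DataFrame(out, index=ebvs.index)


def total_score(X: pd.DataFrame, weights) -> pd.Series:
    """Per-bull aggregate score ``I = sum_t w_t X_t``."""
    w = np.asarray(weights, dtype=float).ravel()
    if len(w) != X.shape[1]:
        raise ValueError(
            f"{len(w)} weights for {X.shape[1]} traits"
        )
    return pd.Series(X.to_numpy(dtype=float) @ w, index=X.index, name="index_value")


def rank_and_select(scores: pd.Series, fraction: float) -> pd.DataFrame:
    """Rank bulls by descending score and flag the top fraction.

    ``ceil(fraction * n)`` bulls are selected; ties are broken by ascending
    bull identifier so reports are deterministic.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if len(scores) == 0:
        raise ValueError("empty score set")
    order = sorted(scores.index, key=lambda b: (-scores[b], str(b)))
    n_sel = math.ceil(fraction * len(scores))
    out = pd.DataFrame(
        {
            "index_value": [scores[b] for b in order],
            "rank": np.arange(1, len(order) + 1),
            "selected": [k < n_sel for k in range(len(order))],
        },
        index=pd.Index(order, name=scores.index.name or "bull"),
    )
    return out


@dataclass
class IndexResult:
    """Full index computation for a set of candidate bulls."""

    X: pd.DataFrame
    b: np.ndarray
    scores: pd.Series
    ranking: pd.DataFrame

    @property
    def selected(self) -> list:
        return self.ranking.index[self.ranking["selected"]].tolist()


def build_index(
    ebvs: pd.DataFrame,
    weights=None,
    inputs: IndexInputs | None = None,
    fraction: float = 0.2,
    sample_sd: bool = False,
) -> IndexResult:
    """Standardize EBVs, apply weights (given directly or as ``P^-1 G a``),
    score and rank."""
    if weights is None:
        if inputs is None:
            raise ValueError("provide either weights or IndexInputs")
        weights = index_weights(inputs)
    X = standardize_ebv(ebvs, sample_sd=sample_sd)
    scores = total_score(X, weights)
    ranking = rank_and_select(scores, fraction)
    return IndexResult(X=X, b=np.asarray(weights, dtype=float), scores=scores, ranking=ranking)
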