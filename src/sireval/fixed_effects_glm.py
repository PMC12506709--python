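"""Fixed-effects layer: outlier screening, descriptives, LS-means, letters.

This is the "field statistics" side of a progeny-test analysis: screen each
trait for extreme records (two-standard-deviation rule within genotype
group), tabulate descriptive statistics per group, fit the fixed-effects
linear model and report least-squares means with standard errors, an omnibus
F test, and Tukey–Kramer mean-separation letters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import studentized_range

from sireval.errors import EstimabilityError
from sireval.mixed_model import ModelSpec, design_matrix

__all__ = [
    "two_sd_filter",
    "describe",
    "ls_means",
    "mean_separation",
    "LsMeansTable",
]


def two_sd_filter(
    values, groups=None
) -> tuple[pd.Series, pd.Series]:
    """Single-pass two-standard-deviation outlier screen.

    Within each group, records with ``|x - mean| > 2 SD`` are removed, where
    mean and SD (sample SD, ddof=1) come from the unfiltered group.  With all
    values equal (zero variance) nothing is removed.  Returns ``(kept,
    removed)`` as Series preserving the original index.
    """
    s = pd.Series(values).astype(float)
    g = pd.Series(groups, index=s.index) if groups is not None else pd.Series(
        "all", index=s.index
    )
    keep_mask = pd.Series(True, index=s.index)
    for _, sub in s.groupby(g):
        sub = sub.dropna()
        if len(sub) < 2:
            raise ValueError("two_sd_filter needs at least 2 values per group")
        mu = sub.mean()
        sd = sub.std(ddof=1)
        if sd > 0:
            out = sub.index[(sub - mu).abs() > 2.0 * sd]
            keep_mask.loc[out] = False
    return s[keep_mask], s[~keep_mask]


def describe(
    records: pd.DataFrame, trait: str, group_by: str | None = None
) -> pd.DataFrame:
    """Descriptive summary per group: N, min, max, mean, SE, CV%.

    ``SE = SD / sqrt(N)`` and ``CV% = 100 SD / mean`` with sample SD.  Empty
    groups are omitted with a warning.
    """
    df = records[[trait] + ([group_by] if group_by else [])].copy()
    if group_by is None:
        df["_group"] = "all"
        group_by = "_group"
    rows = []
    for level, sub in df.groupby(group_by, sort=True):
        x = sub[trait].dropna().astype(float)
        if len(x) == 0:
            warnings.warn(f"group {level!r} has no records for {trait}; omitted")
            continue
        sd = x.std(ddof=1) if len(x) > 1 else 0.0
        mean = x.mean()
        rows.append(
            {
                "trait": trait,
                "group": level,
                "N": len(x),
                "min": x.min(),
                "max": x.max(),
                "mean": mean,
                "se": sd / np.sqrt(len(x)),
                "cv_pct": 100.0 * sd / mean if mean != 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class LsMeansTable:
    """Least-squares means for one factor with separation letters.

    ``table`` has one row per level: lsmean, se, letters; ``pairwise_p`` is
    the symmetric Tukey–Kramer p-value matrix and ``omnibus_p`` the factor's
    F-test p-value.
    """

    factor: str
    table: pd.DataFrame
    pairwise_p: pd.DataFrame
    omnibus_p: float
    alpha: float


def _term_names(spec: ModelSpec) -> list[str]:
    out = []
    for f in spec.fixed_factors:
        out.append(f"{f[0]}:{f[1]}" if isinstance(f, tuple) else f)
    return out


def ls_means(
    records: pd.DataFrame,
    spec: ModelSpec,
    factor: str,
    alpha: float = 0.05,
) -> LsMeansTable:
    """Least-squares means of ``factor`` under the fixed-effects model.

    The LS-mean of a level is the model prediction at that level, averaging
    over the levels of every other factor with equal weights (the classical
    definition, not observed-frequency weighting).  Pairwise separation uses
    Tukey–Kramer studentized-range p-values on the adjusted means.
    """
    recs = records.dropna(subset=[spec.response]).reset_index(drop=True)
    terms = _term_names(spec)
    if factor not in terms:
        raise EstimabilityError(
            f"factor {factor!r} is not in the model ({terms})"
        )
    X, names = design_matrix(recs, spec)
    y = recs[spec.response].to_numpy(dtype=float)
    fit = sm.OLS(y, X).fit()
    cov = fit.cov_params()

    # contrast rows: per level of `factor`, equal-weight over other factors
    def level_labels(term: str) -> list[str]:
        if ":" in term:
            fa, fb = term.split(":")
            lab = recs[fa].astype(str) + "*" + recs[fb].astype(str)
            counts = lab.value_counts()
            return sorted(counts.index[counts >= spec.min_interaction_records])
        return sorted(recs[term].astype(str).unique())

    def contrast(term: str, level: str) -> np.ndarray:
        L = np.zeros(len(names))
        L[names.index("(intercept)")] = 1.0
        for t in terms:
            lvls = level_labels(t)
            if t == term:
                nm = f"{t}={level}"
                if nm in names:
                    L[names.index(nm)] = 1.0
                elif level not in lvls:
                    raise EstimabilityError(
                        f"level {level!r} of {term!r} is not estimable"
                    )
            else:
                for lv in lvls:
                    nm = f"{t}={lv}"
                    if nm in names:
                        L[names.index(nm)] += 1.0 / len(lvls)
        return L

    levels = level_labels(factor)
    if len(levels) < 1:
        raise EstimabilityError(f"factor {factor!r} has no estimable levels")
    Ls = np.array([contrast(factor, lv) for lv in levels])
    means = Ls @ fit.params
    ses = np.sqrt(np.einsum("ij,jk,ik->i", Ls, cov, Ls))

    # omnibus F: all non-reference coefficients of `factor` equal zero
    coef_idx = [k for k, nm in enumerate(names) if nm.startswith(factor + "=")]
    if coef_idx:
        R = np.zeros((len(coef_idx), len(names)))
        for r, k in enumerate(coef_idx):
            R[r, k] = 1.0
        omnibus_p = float(fit.f_test(R).pvalue)
    else:
        omnibus_p = 1.0

    # Tukey-Kramer pairwise p-values on LS-mean differences
    k = len(levels)
    df_resid = fit.df_resid
    P = pd.DataFrame(np.ones((k, k)), index=levels, columns=levels)
    for i in range(k):
        for j in range(i + 1, k):
            dL = Ls[i] - Ls[j]
            se_diff = float(np.sqrt(dL @ cov @ dL))
            if se_diff == 0:
                p = 1.0
            else:
                q = abs(means[i] - means[j]) / se_diff * np.sqrt(2.0)
                p = float(studentized_range.sf(q, k, df_resid)) if k > 1 else 1.0
            P.iloc[i, j] = P.iloc[j, i] = p

    letters = mean_separation(
        pd.Series(means, index=levels), P, alpha=alpha
    )
    table = pd.DataFrame(
        {
            "level": levels,
            "lsmean": means,
            "se": ses,
            "letters": [letters[lv] for lv in levels],
        }
    )
    return LsMeansTable(
        factor=factor, table=table, pairwise_p=P, omnibus_p=omnibus_p, alpha=alpha
    )


def mean_separation(
    lsmeans: pd.Series, pairwise_p: pd.DataFrame, alpha: float = 0.05
) -> dict[str, str]:
    """Compact letter display by the insert-and-absorb algorithm.

    Any two levels sharing a letter have pairwise p >= alpha; any two sharing
    no letter have p < alpha.  Letters are ordered so that 'a' contains the
    highest mean.
    """
    levels = list(lsmeans.index)
    P = pairwise_p.loc[levels, levels]
    if not np.allclose(P.values, P.values.T, atol=1e-12):
        raise ValueError("pairwise p-value matrix must be symmetric")

    columns: list[set[str]] = [set(levels)]
    for i, a in enumerate(levels):
        for b in levels[i + 1 :]:
            if P.loc[a, b] >= alpha:
                continue
            new_cols: list[set[str]] = []
            for col in columns:
                if a in col and b in col:
                    new_cols.append(col - {a})
                    new_cols.append(col - {b})
                else:
                    new_cols.append(col)
            # absorb: drop columns that are subsets of another
            columns = [
                c
                for k, c in enumerate(new_cols)
                if c
                and not any(
                    c < other or (c == other and k > m)
                    for m, other in enumerate(new_cols)
                )
            ]
    # letter order: by the best mean in each column, descending
    columns.sort(key=lambda c: -max(lsmeans[lv] for lv in c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {lv: "" for lv in levels}
    for k, col in enumerate(columns):
        for lv in col:
            out[lv] += alphabet[k % len(alphabet)]
    return {lv: "".join(sorted(out[lv])) for lv in levels}
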