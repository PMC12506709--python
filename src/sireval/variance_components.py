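"""EM-REML variance components, heritabilities and genetic correlations.

Single-trait model: ``y = X b + g + e`` with ``g ~ N(0, A_rec sigma2_a)``,
``e ~ N(0, I sigma2_e)``, where ``A_rec`` is the numerator relationship
matrix restricted to the recorded animals.  The restricted likelihood of an
animal model depends on the pedigree only through ``A_rec`` (unrecorded
ancestors are integrated out), so estimation works in this marginal form:
with the eigendecomposition ``A_rec = U D U'`` the rotated data
``U'y`` have independent components with variance ``d_i sigma2_a + sigma2_e``
and every EM-REML iteration costs O(n p^2).

The EM fixed-point updates are the classical ones,

    sigma2_k  <-  sigma2_k + (sigma2_k^2 / n) * (y'P M_k P y - tr(P M_k)),

with ``M_A = A_rec``, ``M_E = I`` and ``P`` the REML projection matrix;
the restricted log-likelihood is non-decreasing along the sequence.  The
bivariate fit stacks two traits with 2x2 genetic and residual covariance
blocks per rotated observation and applies the matrix form of the same
update.  Standard errors come from the numerically differentiated observed
information at convergence; the SEs of heritability and of the correlations
follow by the delta method.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from sireval.mixed_model import ModelSpec, design_matrix
from sireval.pedigree import PedigreeTable, RelationshipMatrix, relationship_matrix

__all__ = [
    "VarianceComponents",
    "CorrelationEstimate",
    "RelationshipSpectrum",
    "reml_single_trait",
    "reml_bivariate",
    "heritability",
]

_VARIANCE_FLOOR_FRAC = 1e-8
_MONOTONE_SLACK = 1e-6


@dataclass
class RelationshipSpectrum:
    """Eigendecomposition of the relationship matrix among recorded animals."""

    animals: list[str]
    eigvals: np.ndarray
    eigvecs: np.ndarray

    @classmethod
    def from_matrix(
        cls, rel: RelationshipMatrix, animals: Sequence[str]
    ) -> "RelationshipSpectrum":
        pos = {a: i for i, a in enumerate(rel.ids)}
        idx = np.array([pos[str(a)] for a in animals])
        sub = rel.values[np.ix_(idx, idx)]
        w, v = np.linalg.eigh(sub)
        return cls(list(map(str, animals)), np.clip(w, 0.0, None), v)

    @classmethod
    def from_pedigree(
        cls, ped: PedigreeTable, animals: Sequence[str]
    ) -> "RelationshipSpectrum":
        return cls.from_matrix(relationship_matrix(ped), animals)


@dataclass
class VarianceComponents:
    """REML estimates for one trait.

    ``sigma2_p = sigma2_a + sigma2_e`` holds exactly by construction and
    ``h2 = sigma2_a / sigma2_p``.
    """

    trait: str
    sigma2_a: float
    sigma2_e: float
    se_a: float
    se_e: float
    se_p: float
    h2_se: float
    n_records: int
    n_iter: int
    final_change: float
    converged: bool
    boundary: bool = False
    loglik: float = np.nan
    loglik_path: list[float] = field(default_factory=list, repr=False)

    @property
    def sigma2_p(self) -> float:
        return self.sigma2_a + self.sigma2_e

    @property
    def h2(self) -> float:
        return self.sigma2_a / self.sigma2_p

    def as_row(self) -> dict:
        return {
            "trait": self.trait,
            "sigma2_a": self.sigma2_a,
            "se_a": self.se_a,
            "sigma2_e": self.sigma2_e,
            "se_e": self.se_e,
            "sigma2_p": self.sigma2_p,
            "se_p": self.se_p,
            "h2": self.h2,
            "h2_se": self.h2_se,
            "n_records": self.n_records,
            "n_iter": self.n_iter,
            "converged": self.converged,
        }


@dataclass
class CorrelationEstimate:
    """Genetic and phenotypic correlation for one trait pair."""

    trait_i: str
    trait_j: str
    sigma_a_ij: float
    r_g: float
    r_g_se: float
    r_p: float
    r_p_se: float


def heritability(sigma2_a: float, sigma2_p: float) -> float:
    """h2 = sigma2_a / sigma2_p, with domain checks."""
    if sigma2_p <= 0:
        raise ValueError(f"sigma2_p must be positive, got {sigma2_p}")
    if not 0 <= sigma2_a <= sigma2_p:
        raise ValueError(
            f"need 0 <= sigma2_a <= sigma2_p, got {sigma2_a} vs {sigma2_p}"
        )
    return sigma2_a / sigma2_p


# ---------------------------------------------------------------------------
# single trait


def _rotated_data(records, spec, ped, spectrum):
    recs = records.dropna(subset=[spec.response]).reset_index(drop=True)
    animals = recs["animal"].astype(str).tolist()
    if spectrum is None:
        spectrum = RelationshipSpectrum.from_pedigree(ped, animals)
    elif spectrum.animals != animals:
        raise ValueError("spectrum animal order does not match the records")
    y = recs[spec.response].to_numpy(dtype=float)
    X, _ = design_matrix(recs, spec)
    U = spectrum.eigvecs
    return U.T @ y, U.T @ X, spectrum.eigvals


def _reml_loglik_1t(theta, yt, Xt, d):
    s2a, s2e = theta
    v = d * s2a + s2e
    if (v <= 0).any():
        return -np.inf
    w = 1.0 / v
    XtWX = (Xt * w[:, None]).T @ Xt
    beta = np.linalg.solve(XtWX, Xt.T @ (w * yt))
    r = yt - Xt @ beta
    sign, logdet = np.linalg.slogdet(XtWX)
    return -0.5 * (np.log(v).sum() + logdet + (w * r * r).sum())


def _numeric_hessian(f, theta, rel_step=1e-4):
    theta = np.asarray(theta, dtype=float)
    k = len(theta)
    h = rel_step * np.maximum(np.abs(theta), np.abs(theta).mean() + 1e-12)
    H = np.zeros((k, k))
    f0 = f(theta)
    with np.errstate(invalid="ignore"):
        for i in range(k):
            for j in range(i, k):
                ei = np.zeros(k)
                ej = np.zeros(k)
                ei[i] = h[i]
                ej[j] = h[j]
                if i == j:
                    H[i, i] = (f(theta + ei) - 2 * f0 + f(theta - ei)) / h[i] ** 2
                else:
                    H[i, j] = H[j, i] = (
                        f(theta + ei + ej)
                        - f(theta + ei - ej)
                        - f(theta - ei + ej)
                        + f(theta - ei - ej)
                    ) / (4 * h[i] * h[j])
    if not np.isfinite(H).all():
        H[~np.isfinite(H)] = np.nan
    return H


def _param_cov(f, theta):
    """Asymptotic covariance from the numeric observed information."""
    H = _numeric_hessian(f, theta)
    if not np.isfinite(H).all():
        return np.full((len(theta), len(theta)), np.nan)
    try:
        cov = np.linalg.inv(-H)
    except np.linalg.LinAlgError:
        return np.full((len(theta), len(theta)), np.nan)
    if np.any(np.diag(cov) < 0):
        cov = np.where(np.eye(len(theta), dtype=bool), np.abs(np.diag(cov)), cov)
    return cov


def reml_single_trait(
    records: pd.DataFrame,
    spec: ModelSpec,
    ped: PedigreeTable | None = None,
    init: tuple[float, float] | None = None,
    tol: float = 1e-8,
    max_iter: int = 5000,
    spectrum: RelationshipSpectrum | None = None,
) -> VarianceComponents:
    """EM-REML additive and residual variances for one trait.

    Either a validated pedigree or a precomputed :class:`RelationshipSpectrum`
    over the recorded animals (in record order) must be supplied; passing the
    spectrum amortizes the eigendecomposition across traits and replicates.
    Non-convergence is flagged on the result, not raised; an additive
    variance heading to zero is held at a small positive floor and flagged
    as a boundary estimate.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    yt, Xt, d = _rotated_data(records, spec, ped, spectrum)
    n = len(yt)

    if init is None:
        beta0 = np.linalg.lstsq(Xt, yt, rcond=None)[0]
        s2p0 = float(np.var(yt - Xt @ beta0, ddof=Xt.shape[1]))
        s2a, s2e = 0.5 * s2p0, 0.5 * s2p0
    else:
        s2a, s2e = map(float, init)
        if s2a <= 0 or s2e <= 0:
            raise ValueError("initial variances must be positive")

    floor = _VARIANCE_FLOOR_FRAC * (s2a + s2e)
    ll_path: list[float] = []
    boundary = False
    change = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        v = d * s2a + s2e
        w = 1.0 / v
        XtWX = (Xt * w[:, None]).T @ Xt
        beta = np.linalg.solve(XtWX, Xt.T @ (w * yt))
        r = yt - Xt @ beta
        py = w * r
        # leverage term: diag of P = w - w^2 * x_i' (X'WX)^-1 x_i
        B = np.linalg.solve(XtWX, Xt.T)
        quad = np.einsum("ij,ji->i", Xt, B)
        p_ii = w - w * w * quad

        sign, logdet = np.linalg.slogdet(XtWX)
        ll = -0.5 * (np.log(v).sum() + logdet + (py * r).sum())
        if ll_path:
            assert ll >= ll_path[-1] - _MONOTONE_SLACK * (1 + abs(ll_path[-1])), (
                f"EM log-likelihood decreased at iteration {it}: "
                f"{ll_path[-1]} -> {ll}"
            )
        ll_path.append(ll)

        s2a_new = s2a + (s2a**2 / n) * ((d * py * py).sum() - (d * p_ii).sum())
        s2e_new = s2e + (s2e**2 / n) * ((py * py).sum() - p_ii.sum())
        if s2a_new < floor:
            s2a_new = floor
            boundary = True
        if s2e_new < floor:
            s2e_new = floor
            boundary = True
        change = max(
            abs(s2a_new - s2a) / max(s2a, floor),
            abs(s2e_new - s2e) / max(s2e, floor),
        )
        s2a, s2e = s2a_new, s2e_new
        if change < tol:
            break
    converged = change < tol

    cov = _param_cov(lambda th: _reml_loglik_1t(th, yt, Xt, d), [s2a, s2e])
    se_a = float(np.sqrt(cov[0, 0]))
    se_e = float(np.sqrt(cov[1, 1]))
    se_p = float(np.sqrt(cov.sum()))
    s2p = s2a + s2e
    grad = np.array([s2e, -s2a]) / s2p**2
    h2_se = float(np.sqrt(grad @ cov @ grad))

    return VarianceComponents(
        trait=spec.response,
        sigma2_a=float(s2a),
        sigma2_e=float(s2e),
        se_a=se_a,
        se_e=se_e,
        se_p=se_p,
        h2_se=h2_se,
        n_records=n,
        n_iter=it,
        final_change=float(change),
        converged=bool(converged),
        boundary=boundary,
        loglik=ll_path[-1] if ll_path else np.nan,
        loglik_path=ll_path,
    )


# ---------------------------------------------------------------------------
# bivariate


@dataclass
class BivariateResult:
    """Joint EM-REML fit of a trait pair."""

    G0: np.ndarray
    R0: np.ndarray
    components: tuple[VarianceComponents, VarianceComponents]
    correlation: CorrelationEstimate
    n_iter: int
    converged: bool
    psd_projected: bool
    loglik: float
    loglik_path: list[float] = field(repr=False, default_factory=list)


def _floor_psd(m: np.ndarray, floor: float) -> tuple[np.ndarray, bool]:
    w, v = np.linalg.eigh(m)
    if w.min() >= floor:
        return m, False
    w = np.clip(w, floor, None)
    return (v * w) @ v.T, True


def _bi_loglik(theta, Y, Xs, d):
    g11, g12, g22, r11, r12, r22 = theta
    G0 = np.array([[g11, g12], [g12, g22]])
    R0 = np.array([[r11, r12], [r12, r22]])
    try:
        return _bi_gls(Y, Xs, d, G0, R0)[0]
    except np.linalg.LinAlgError:
        return -np.inf


def _bi_gls(Y, Xs, d, G0, R0):
    """Rotated-basis bivariate GLS pass.

    Returns (loglik, Py (n x 2), P_ii blocks (n x 2 x 2), resid (n x 2),
    Vinv (n x 2 x 2)).
    """
    n = Y.shape[0]
    X1, X2 = Xs
    p1, p2 = X1.shape[1], X2.shape[1]
    V = d[:, None, None] * G0 + R0  # n x 2 x 2
    det = V[:, 0, 0] * V[:, 1, 1] - V[:, 0, 1] ** 2
    if (det <= 0).any() or (V[:, 0, 0] <= 0).any():
        raise np.linalg.LinAlgError("indefinite per-observation covariance")
    Vinv = np.empty_like(V)
    Vinv[:, 0, 0] = V[:, 1, 1] / det
    Vinv[:, 1, 1] = V[:, 0, 0] / det
    Vinv[:, 0, 1] = Vinv[:, 1, 0] = -V[:, 0, 1] / det

    # X' V^-1 X and X' V^-1 y over the block design [X1 0; 0 X2]
    B = np.zeros((p1 + p2, p1 + p2))
    B[:p1, :p1] = (X1 * Vinv[:, 0, 0, None]).T @ X1
    B[:p1, p1:] = (X1 * Vinv[:, 0, 1, None]).T @ X2
    B[p1:, :p1] = B[:p1, p1:].T
    B[p1:, p1:] = (X2 * Vinv[:, 1, 1, None]).T @ X2
    c = np.concatenate(
        [
            X1.T @ (Vinv[:, 0, 0] * Y[:, 0] + Vinv[:, 0, 1] * Y[:, 1]),
            X2.T @ (Vinv[:, 1, 0] * Y[:, 0] + Vinv[:, 1, 1] * Y[:, 1]),
        ]
    )
    beta = np.linalg.solve(B, c)
    resid = np.column_stack([Y[:, 0] - X1 @ beta[:p1], Y[:, 1] - X2 @ beta[p1:]])
    Py = np.einsum("nij,nj->ni", Vinv, resid)

    # T_i = Vinv_i X_i  (2 x (p1+p2)); P_ii = Vinv_i - T_i B^-1 T_i'
    T = np.zeros((n, 2, p1 + p2))
    T[:, 0, :p1] = Vinv[:, 0, 0, None] * X1
    T[:, 0, p1:] = Vinv[:, 0, 1, None] * X2
    T[:, 1, :p1] = Vinv[:, 1, 0, None] * X1
    T[:, 1, p1:] = Vinv[:, 1, 1, None] * X2
    Binv_T = np.linalg.solve(B, T.reshape(-1, p1 + p2).T).T.reshape(n, 2, p1 + p2)
    P_ii = Vinv - np.einsum("nik,njk->nij", T, Binv_T)

    sign, logdetB = np.linalg.slogdet(B)
    ll = -0.5 * (
        np.log(det).sum() + logdetB + np.einsum("ni,ni->", resid, Py)
    )
    return ll, Py, P_ii, resid, Vinv


def reml_bivariate(
    records: pd.DataFrame,
    specs: tuple[ModelSpec, ModelSpec],
    ped: PedigreeTable | None = None,
    init: tuple[np.ndarray, np.ndarray] | None = None,
    tol: float = 1e-8,
    max_iter: int = 5000,
    spectrum: RelationshipSpectrum | None = None,
) -> BivariateResult:
    """EM-REML for a trait pair: 2x2 genetic (G0) and residual (R0) blocks.

    Records missing either response are dropped (complete-case pairing).
    Updates that leave the PSD cone are projected back with an eigenvalue
    floor and flagged.  Correlations: ``r_g = g12 / sqrt(g11 g22)`` and
    ``r_p`` likewise from ``P0 = G0 + R0``; SEs by the delta method from the
    numeric observed information over the six (co)variance parameters.
    """
    spec_i, spec_j = specs
    recs = records.dropna(subset=[spec_i.response, spec_j.response]).reset_index(
        drop=True
    )
    animals = recs["animal"].astype(str).tolist()
    if spectrum is None:
        spectrum = RelationshipSpectrum.from_pedigree(ped, animals)
    elif spectrum.animals != animals:
        raise ValueError("spectrum animal order does not match the records")
    U, d = spectrum.eigvecs, spectrum.eigvals
    Y = U.T @ recs[[spec_i.response, spec_j.response]].to_numpy(dtype=float)
    X1 = U.T @ design_matrix(recs, spec_i)[0]
    X2 = U.T @ design_matrix(recs, spec_j)[0]
    n = len(Y)

    if init is None:
        v0 = np.array(
            [
                np.var(Y[:, 0] - X1 @ np.linalg.lstsq(X1, Y[:, 0], rcond=None)[0]),
                np.var(Y[:, 1] - X2 @ np.linalg.lstsq(X2, Y[:, 1], rcond=None)[0]),
            ]
        )
        G0 = np.diag(0.5 * v0)
        R0 = np.diag(0.5 * v0)
    else:
        G0 = np.asarray(init[0], dtype=float).copy()
        R0 = np.asarray(init[1], dtype=float).copy()

    floor = _VARIANCE_FLOOR_FRAC * float(np.trace(G0) + np.trace(R0))
    ll_path: list[float] = []
    projected = False
    change = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        ll, Py, P_ii, _, _ = _bi_gls(Y, (X1, X2), d, G0, R0)
        if ll_path:
            assert ll >= ll_path[-1] - _MONOTONE_SLACK * (1 + abs(ll_path[-1])), (
                f"EM log-likelihood decreased at iteration {it}"
            )
        ll_path.append(ll)

        outer = np.einsum("ni,nj->nij", Py, Py)
        SG = ((outer - P_ii) * d[:, None, None]).sum(axis=0)
        SR = (outer - P_ii).sum(axis=0)
        G_new = G0 + (G0 @ SG @ G0) / n
        R_new = R0 + (R0 @ SR @ R0) / n
        G_new = 0.5 * (G_new + G_new.T)
        R_new = 0.5 * (R_new + R_new.T)
        G_new, pg = _floor_psd(G_new, floor)
        R_new, pr = _floor_psd(R_new, floor)
        projected = projected or pg or pr

        scale = max(np.abs(np.diag(G0)).max(), np.abs(np.diag(R0)).max())
        change = max(
            np.abs(G_new - G0).max() / scale, np.abs(R_new - R0).max() / scale
        )
        G0, R0 = G_new, R_new
        if change < tol:
            break
    converged = change < tol

    theta = np.array([G0[0, 0], G0[0, 1], G0[1, 1], R0[0, 0], R0[0, 1], R0[1, 1]])
    cov = _param_cov(lambda th: _bi_loglik(th, Y, (X1, X2), d), theta)

    comps = []
    for k, spec in enumerate(specs):
        ia = 0 if k == 0 else 2  # index of g_kk in theta
        ie = 3 if k == 0 else 5
        sub = cov[np.ix_([ia, ie], [ia, ie])]
        s2a, s2e = G0[k, k], R0[k, k]
        s2p = s2a + s2e
        grad = np.array([s2e, -s2a]) / s2p**2
        comps.append(
            VarianceComponents(
                trait=spec.response,
                sigma2_a=float(s2a),
                sigma2_e=float(s2e),
                se_a=float(np.sqrt(sub[0, 0])),
                se_e=float(np.sqrt(sub[1, 1])),
                se_p=float(np.sqrt(sub.sum())),
                h2_se=float(np.sqrt(grad @ sub @ grad)),
                n_records=n,
                n_iter=it,
                final_change=float(change),
                converged=bool(converged),
                loglik=ll_path[-1],
            )
        )

    corr = _correlations_with_se(G0, R0, cov, spec_i.response, spec_j.response)
    return BivariateResult(
        G0=G0,
        R0=R0,
        components=(comps[0], comps[1]),
        correlation=corr,
        n_iter=it,
        converged=bool(converged),
        psd_projected=projected,
        loglik=ll_path[-1],
        loglik_path=ll_path,
    )


def _correlations_with_se(G0, R0, cov, name_i, name_j) -> CorrelationEstimate:
    g11, g12, g22 = G0[0, 0], G0[0, 1], G0[1, 1]
    r_g = g12 / np.sqrt(g11 * g22)
    # d r_g / d(g11, g12, g22)
    grad_g = np.array(
        [
            -0.5 * g12 / (g11 ** 1.5 * np.sqrt(g22)),
            1.0 / np.sqrt(g11 * g22),
            -0.5 * g12 / (g22 ** 1.5 * np.sqrt(g11)),
        ]
    )
    sub_g = cov[np.ix_([0, 1, 2], [0, 1, 2])]
    r_g_se = float(np.sqrt(max(grad_g @ sub_g @ grad_g, 0.0)))

    P0 = G0 + R0
    p11, p12, p22 = P0[0, 0], P0[0, 1], P0[1, 1]
    r_p = p12 / np.sqrt(p11 * p22)
    grad_p3 = np.array(
        [
            -0.5 * p12 / (p11 ** 1.5 * np.sqrt(p22)),
            1.0 / np.sqrt(p11 * p22),
            -0.5 * p12 / (p22 ** 1.5 * np.sqrt(p11)),
        ]
    )
    # p_ab depends on both genetic and residual parameters additively
    J = np.zeros((3, 6))
    J[0, 0] = J[0, 3] = 1.0
    J[1, 1] = J[1, 4] = 1.0
    J[2, 2] = J[2, 5] = 1.0
    grad_p = J.T @ grad_p3
    r_p_se = float(np.sqrt(max(grad_p @ cov @ grad_p, 0.0)))

    return CorrelationEstimate(
        trait_i=name_i,
        trait_j=name_j,
        sigma_a_ij=float(g12),
        r_g=float(np.clip(r_g, -1.0, 1.0)),
        r_g_se=r_g_se,
        r_p=float(np.clip(r_p, -1.0, 1.0)),
        r_p_se=r_p_se,
    )
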