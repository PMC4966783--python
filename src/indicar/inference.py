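"""Joint standard errors, BLUP covariance and conditional AIC.

At convergence of the backfit, the fixed effects ``(beta, gamma)`` are the
GLS solution of the working linear mixed model

.. math::

    Y_{pseudo} = X\\beta + ZU\\gamma + Zb + \\epsilon, \\qquad
    \\epsilon \\sim N(0, W^{-1}), \\quad b \\sim N(0, D),

with ``W = diag(mu)`` and ``Y_pseudo = eta + W^{-1}(Y - mu)``.  Their joint
covariance is ``Q = (C^T V^{-1} C)^{-1}`` with ``C = [X | ZU]`` and
``V = Z D Z^T + W^{-1}``.  ``V`` is ``n x n`` and is never formed: by the
Woodbury identity

.. math::

    V^{-1} = W - W Z D (I + Z^T W Z D)^{-1} Z^T W,

so every term reduces to the individual-level cross-products ``X^T W X`` and
``X^T W Z`` plus ``M x M`` algebra.  This is what makes the corrected
standard errors feasible for very large ``n``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve, lu_factor, lu_solve

from .data_model import IndividualTable, RegionTable
from .spatial import LerouxParams, leroux_covariance, leroux_precision


@dataclass
class WorkingModel:
    """Converged working linear mixed model at the individual level.

    ``weights`` is the diagonal of ``W`` (the fitted Poisson means);
    ``y_pseudo`` the working response; ``D`` the ``M x M`` random-effect
    covariance; ``X``/``U``/``region_index`` define ``C = [X | ZU]``.
    """

    X: np.ndarray
    U: np.ndarray
    region_index: np.ndarray
    n_regions: int
    weights: np.ndarray
    y_pseudo: np.ndarray
    D: np.ndarray


def build_working_model(data: IndividualTable, regions: RegionTable,
                        beta, gamma, b, theta: LerouxParams,
                        R: np.ndarray) -> WorkingModel:
    """Assemble the working LMM at the converged parameter values."""
    U = regions.U
    g = data.region_index
    region_lin = (U @ gamma if U.shape[1] else np.zeros(data.n_regions)) + b
    eta = data.X @ np.asarray(beta, dtype=float) + region_lin[g]
    mu = np.exp(eta)
    y_pseudo = eta + (data.y - mu) / mu
    return WorkingModel(
        X=data.X, U=U, region_index=g, n_regions=data.n_regions,
        weights=mu, y_pseudo=y_pseudo, D=leroux_covariance(theta, R),
    )


def _group_matrix(g, n_regions, values) -> np.ndarray:
    """Scatter-add rows of ``values`` (n x k) into regions: ``Z^T values``."""
    out = np.zeros((n_regions, values.shape[1]))
    np.add.at(out, g, values)
    return out


def fixed_covariance_from_working(work: WorkingModel) -> np.ndarray:
    """Joint covariance ``Q`` of ``(beta, gamma)`` via the Woodbury blocks.

    Computes the inverse-information blocks

    ``a11 = X'WX - X'WZ D K^{-1} Z'WX``,
    ``a12 = X'WZU - X'WZ D K^{-1} Z'WZU``,  ``a21 = a12'``,
    ``a22 = U'Z'WZU - U'Z'WZ D K^{-1} Z'WZU``,

    with ``K = I + Z'WZ D``, touching individual-level data only through
    ``X^T W X`` and ``X^T W Z``; returns ``Q = [[a11, a12], [a21, a22]]^{-1}``.
    """
    X, U, g, m = work.X, work.U, work.region_index, work.n_regions
    w, D = work.weights, work.D
    p, q = X.shape[1], U.shape[1]

    ZtWX = _group_matrix(g, m, w[:, None] * X)           # M x p
    XtWX = X.T @ (w[:, None] * X)
    w_c = np.bincount(g, weights=w, minlength=m)         # diag of Z'WZ
    K = np.eye(m) + w_c[:, None] * D                     # I + Z'WZ D
    lu = lu_factor(K)
    ZtWZU = w_c[:, None] * U                             # M x q

    a11 = XtWX - ZtWX.T @ (D @ lu_solve(lu, ZtWX))
    if q:
        DKi_ZtWZU = D @ lu_solve(lu, ZtWZU)
        a12 = ZtWX.T @ U - ZtWX.T @ DKi_ZtWZU
        a22 = U.T @ ZtWZU - ZtWZU.T @ DKi_ZtWZU
        A = np.block([[a11, a12], [a12.T, a22]])
    else:
        A = a11
    cf = cho_factor(0.5 * (A + A.T), lower=True)
    Q = cho_solve(cf, np.eye(p + q))
    return 0.5 * (Q + Q.T)


def joint_fixed_covariance(fit, data: IndividualTable, regions: RegionTable,
                           adj_or_R) -> np.ndarray:
    """Joint covariance of the fixed effects at a converged backfit.

    ``fit`` must expose ``beta``, ``gamma``, ``b`` and ``theta``;
    ``adj_or_R`` is either an adjacency structure or the matrix ``R``.
    """
    R = adj_or_R if isinstance(adj_or_R, np.ndarray) else None
    if R is None:
        from .spatial import build_structure_matrix
        R = build_structure_matrix(adj_or_R)
    work = build_working_model(data, regions, fit.beta, fit.gamma, fit.b,
                               fit.theta, R)
    return fixed_covariance_from_working(work)


def blup_and_fixed_solutions(work: WorkingModel):
    """One-shot mixed-model solution of the working LMM.

    Returns ``(beta, gamma, b)`` with
    ``(beta, gamma) = (C'V^{-1}C)^{-1} C'V^{-1} y_pseudo`` and
    ``b = D Z' V^{-1} (y_pseudo - X beta - ZU gamma)``, all evaluated via
    the Woodbury identity (``V`` is never formed).  At a converged backfit
    this reproduces the backfit estimates.
    """
    X, U, g, m = work.X, work.U, work.region_index, work.n_regions
    w, D, yp = work.weights, work.D, work.y_pseudo
    p, q = X.shape[1], U.shape[1]
    w_c = np.bincount(g, weights=w, minlength=m)
    K = np.eye(m) + w_c[:, None] * D
    lu = lu_factor(K)

    def vinv(mat):
        mat2 = mat if mat.ndim == 2 else mat[:, None]
        s = _group_matrix(g, m, w[:, None] * mat2)       # Z'W mat
        t = D @ lu_solve(lu, s)
        out = w[:, None] * mat2 - w[:, None] * t[g]
        return out if mat.ndim == 2 else out[:, 0]

    C = np.hstack([X, U[g]]) if q else X
    ViC = vinv(C)
    A = C.T @ ViC
    rhs = ViC.T @ yp
    coef = np.linalg.solve(0.5 * (A + A.T), rhs)
    resid = yp - C @ coef
    s = np.bincount(g, weights=vinv(resid), minlength=m)
    b = D @ s
    return coef[:p], coef[p:], b


def blup_covariance(groupfit_or_weights, R: np.ndarray,
                    theta: LerouxParams | None = None) -> np.ndarray:
    """Covariance of the BLUP ``b_hat`` from the group-level Fisher information.

    With the fixed effects held at their estimates, the penalized information
    for ``b`` in the group-level model is ``W_c + D^{-1}`` where ``W_c`` are
    the region-level working weights; the covariance is its inverse.  As
    ``sigma2 -> 0`` the penalty dominates and the covariance shrinks to zero.
    """
    if hasattr(groupfit_or_weights, "working_weights"):
        w_c = groupfit_or_weights.working_weights
        theta = groupfit_or_weights.theta if theta is None else theta
    else:
        w_c = np.asarray(groupfit_or_weights, dtype=float)
    P = leroux_precision(theta, R)
    cf = cho_factor(P + np.diag(w_c), lower=True)
    cov = cho_solve(cf, np.eye(len(w_c)))
    return 0.5 * (cov + cov.T)


def effective_df_random(w_c, R, theta) -> float:
    """Effective degrees of freedom of ``b``: ``trace[(W_c + D^-)^{-1} W_c]``.

    Lies in ``(0, M)`` and increases with ``sigma2`` (less shrinkage, more
    effective parameters).
    """
    w_c = np.asarray(w_c, dtype=float)
    P = leroux_precision(theta, R)
    cf = cho_factor(P + np.diag(w_c), lower=True)
    return float(np.trace(cho_solve(cf, np.diag(w_c))))


def conditional_aic(fit, data: IndividualTable, R: np.ndarray) -> float:
    """Approximate conditional AIC of a converged fit.

    ``-2 * loglik_c + 2 * rho`` where ``loglik_c = sum(y log mu - mu)`` is
    the conditional Poisson log-likelihood given ``b_hat`` (the ``log y!``
    constant is dropped), and ``rho = p + q + df_b`` with ``df_b`` the
    effective degrees of freedom of the random effect.  In the
    ``sigma2 -> 0`` limit ``rho -> p + q`` and this reduces to the GLM AIC
    without its constant.
    """
    mu = fit.mu
    y = np.asarray(data.y, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = float(np.sum(np.where(y > 0, y * np.log(mu), 0.0)) - mu.sum())
    w_c = np.bincount(data.region_index, weights=mu, minlength=data.n_regions)
    df_b = effective_df_random(w_c, R, fit.theta)
    p = fit.beta.size
    q = fit.gamma.size
    return -2.0 * ll + 2.0 * (p + q + df_b)
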