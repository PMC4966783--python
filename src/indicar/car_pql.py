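"""Group-level Poisson mixed model with a Leroux CAR random effect, by PQL.

The model for the aggregated counts ``Y_c`` (one per region) is

.. math::

    Y_{c,j} \\sim \\mathrm{Poisson}\\{\\exp(o_j + u_j^T \\gamma + b_j)\\},
    \\qquad b \\sim N(0, D),

with ``D^{-1} = sigma^-2 {(1 - lambda) I + lambda R}``.  Fitting alternates
two steps until joint convergence (penalized quasi-likelihood):

1. at fixed ``theta = (sigma2, lam)``, maximize the penalized log-likelihood
   over ``(gamma, b)`` by IRLS on the working linear mixed model, with
   step-halving so the penalized objective never decreases;
2. update ``theta`` by maximizing the restricted (REML) log-likelihood of
   the working pseudo-response ``z = U gamma + b + W^{-1}(Y_c - mu)`` under
   ``z ~ N(U gamma, D + W^{-1})``, profiled over ``gamma``, with ``sigma2``
   optimized on the log scale and ``lambda`` on a logit scale bounded by
   ``LAMBDA_MAX``.

This is the standard Breslow–Clayton PQL scheme specialized to the Leroux
precision family; the same routine serves both as the group-level step of
the individual-covariate backfit and as the standalone areal model used for
the age–sex standardized comparison method.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve, LinAlgError
from scipy.optimize import minimize
from scipy.special import expit, logit

from .errors import ConvergenceError, SingularityError
from .spatial import LAMBDA_MAX, LerouxParams, leroux_precision

_DEFAULT_THETA = LerouxParams(sigma2=0.1, lam=0.5)


@dataclass
class GroupModelFit:
    """Converged group-level CAR mixed-model fit.

    ``cov_gamma_naive`` is ``(U^T V^{-1} U)^{-1}`` from the working mixed
    model; "naive" because the group offset is treated as known.
    ``working_weights`` are the converged region-level Poisson means.
    """

    gamma: np.ndarray
    b: np.ndarray
    theta: LerouxParams
    cov_gamma_naive: np.ndarray
    working_weights: np.ndarray
    n_iter: int
    converged: bool
    reml: float = np.nan


def penalized_loglik(y_c, offset, U, gamma, b, P) -> float:
    """Penalized Poisson log-likelihood kernel ``sum(y eta - mu) - b'Pb/2``."""
    eta = offset + (U @ gamma if U.shape[1] else 0.0) + b
    return float(y_c @ eta - np.exp(eta).sum() - 0.5 * b @ P @ b)


def pql_inner_solve(y_c, U, offset, R, theta, gamma0=None, b0=None,
                    tol=1e-11, max_iter=100):
    """Maximize the penalized objective over ``(gamma, b)`` at fixed theta.

    Returns ``(gamma, b, working_weights)`` where the working weights are
    the fitted region means ``mu``.  The returned pair satisfies the two
    score equations ``(Y_c - mu)^T U = 0`` and ``Y_c - mu = D^{-1} b``.
    """
    y_c = np.asarray(y_c, dtype=float)
    offset = np.asarray(offset, dtype=float)
    U = np.asarray(U, dtype=float)
    if U.ndim == 1:
        U = U[:, None]
    m = len(y_c)
    q = U.shape[1]
    P = leroux_precision(theta, R)

    gamma = np.zeros(q) if gamma0 is None else np.asarray(gamma0, dtype=float).copy()
    b = np.zeros(m) if b0 is None else np.asarray(b0, dtype=float).copy()
    obj = penalized_loglik(y_c, offset, U, gamma, b, P)

    for it in range(1, max_iter + 1):
        eta = offset + (U @ gamma if q else 0.0) + b
        mu = np.exp(eta)
        w = mu
        z = (eta - offset) + (y_c - mu) / mu
        A = P + np.diag(w)
        try:
            cf = cho_factor(A, lower=True)
        except LinAlgError:
            raise SingularityError("singular penalized system W + D^-")
        if q:
            WU = w[:, None] * U
            AiWU = cho_solve(cf, WU)
            SU = WU - w[:, None] * AiWU          # S U with S = W - W A^{-1} W
            wz = w * z
            Sz = wz - w * cho_solve(cf, wz)
            G = U.T @ SU
            gamma_new = np.linalg.solve(G, U.T @ Sz)
        else:
            gamma_new = gamma
        b_new = cho_solve(cf, w * (z - (U @ gamma_new if q else 0.0)))

        d_gamma = gamma_new - gamma
        d_b = b_new - b
        scale = 1.0
        for _ in range(40):
            g_c = gamma + scale * d_gamma
            b_c = b + scale * d_b
            obj_c = penalized_loglik(y_c, offset, U, g_c, b_c, P)
            if np.isfinite(obj_c) and obj_c >= obj - 1e-10 * (abs(obj) + 1.0):
                break
            scale *= 0.5
        else:
            raise ConvergenceError(
                f"inner PQL step-halving failed at iteration {it}",
                last_iterate=(gamma, b),
            )
        change = max(
            np.max(np.abs(scale * d_b)) / (np.max(np.abs(b)) + 1.0),
            (np.max(np.abs(scale * d_gamma)) / (np.max(np.abs(gamma)) + 1.0))
            if q else 0.0,
        )
        gamma, b, obj = g_c, b_c, obj_c
        if change < tol:
            break
    else:
        raise ConvergenceError(
            f"inner PQL did not converge in {max_iter} iterations",
            last_iterate=(gamma, b),
        )

    mu = np.exp(offset + (U @ gamma if q else 0.0) + b)
    return gamma, b, mu


def _theta_to_x(theta: LerouxParams) -> np.ndarray:
    lam = np.clip(theta.lam / LAMBDA_MAX, 1e-12, 1 - 1e-12)
    return np.array([np.log(theta.sigma2), logit(lam)])


def _x_to_theta(x) -> LerouxParams:
    return LerouxParams(
        sigma2=float(np.exp(np.clip(x[0], -30, 30))),
        lam=float(LAMBDA_MAX * expit(np.clip(x[1], -35, 35))),
    )


def reml_neg_loglik(x, z, w, U, R, eig_R) -> float:
    """Negative REML log-likelihood of ``z ~ N(U gamma, D + W^{-1})``.

    Evaluated without forming ``V = D + W^{-1}`` directly: with
    ``A = D^{-1} + W``,

    * ``V^{-1} r = W r - W A^{-1} W r``  (Woodbury),
    * ``log|V| = log|A| - log|D^{-1}| - sum log w``,

    and ``log|D^{-1}|`` comes from the precomputed eigenvalues of ``R``.
    """
    theta = _x_to_theta(x)
    m = len(z)
    q = U.shape[1]
    P = leroux_precision(theta, R)
    A = P + np.diag(w)
    try:
        cf = cho_factor(A, lower=True)
    except LinAlgError:
        return np.inf
    logdet_A = 2.0 * np.sum(np.log(np.diag(cf[0])))
    lam, s2 = theta.lam, theta.sigma2
    logdet_P = np.sum(np.log((1 - lam) + lam * eig_R)) - m * np.log(s2)
    logdet_V = logdet_A - logdet_P - np.sum(np.log(w))

    def vinv(v):
        wv = w * v
        return wv - w * cho_solve(cf, wv)

    if q:
        ViU = np.column_stack([vinv(U[:, k]) for k in range(q)])
        G = U.T @ ViU
        sign, logdet_G = np.linalg.slogdet(G)
        if sign <= 0:
            return np.inf
        gamma = np.linalg.solve(G, ViU.T @ z)
        r = z - U @ gamma
    else:
        logdet_G = 0.0
        r = z
    quad = float(r @ vinv(r))
    return 0.5 * (logdet_V + logdet_G + quad)


def _maximize_reml(z, w, U, R, eig_R, theta0) -> tuple[LerouxParams, float]:
    x0 = _theta_to_x(theta0)
    res = minimize(
        reml_neg_loglik, x0, args=(z, w, U, R, eig_R), method="L-BFGS-B",
        options={"maxiter": 100, "ftol": 1e-12, "gtol": 1e-6},
    )
    # keep the better of start and end points (L-BFGS-B can stall on flat spots)
    if res.fun <= reml_neg_loglik(x0, z, w, U, R, eig_R):
        return _x_to_theta(res.x), float(res.fun)
    return theta0, float(reml_neg_loglik(x0, z, w, U, R, eig_R))


def fit_group_car(y_c, U, offset, R, theta_init=None, tol=1e-6,
                  max_alternations=200, estimate_theta=True, eig_R=None,
                  gamma0=None, b0=None,
                  require_convergence=True) -> GroupModelFit:
    """Fit the group-level CAR mixed model by alternating PQL/REML.

    Parameters
    ----------
    y_c, U, offset, R
        Aggregated counts (length M), group covariates (M x q, possibly
        q = 0, no intercept unless explicitly included as a column), known
        offset, and the intrinsic autoregression matrix.
    theta_init
        Starting ``(sigma2, lam)``; defaults to ``(0.1, 0.5)``.
    estimate_theta
        When False, ``theta`` stays fixed at ``theta_init`` and only one
        inner solve is performed.
    eig_R
        Optional precomputed eigenvalues of ``R`` (saves repeated
        decompositions when called inside the backfit loop).
    require_convergence
        When False, hitting ``max_alternations`` returns the last iterate
        (flagged ``converged=False``) instead of raising — used by the
        backfit driver, which interleaves single PQL/REML alternations with
        its own outer loop and applies its own joint convergence test.
    """
    y_c = np.asarray(y_c, dtype=float)
    U = np.asarray(U, dtype=float)
    if U.ndim == 1:
        U = U[:, None]
    offset = np.asarray(offset, dtype=float)
    R = np.asarray(R, dtype=float)
    m = len(y_c)
    if m < 1:
        raise ValueError("need at least one region")
    theta = theta_init if theta_init is not None else _DEFAULT_THETA
    if eig_R is None:
        eig_R = np.linalg.eigvalsh(R)

    gamma, b = gamma0, b0
    reml = np.nan
    if not estimate_theta:
        gamma, b, w = pql_inner_solve(y_c, U, offset, R, theta, gamma, b)
        return GroupModelFit(
            gamma=gamma, b=b, theta=theta,
            cov_gamma_naive=_gamma_covariance(w, U, R, theta),
            working_weights=w, n_iter=1, converged=True,
        )

    converged = False
    it = 0
    for it in range(1, max_alternations + 1):
        gamma_new, b_new, w = pql_inner_solve(y_c, U, offset, R, theta, gamma, b)
        eta = offset + (U @ gamma_new if U.shape[1] else 0.0) + b_new
        z = (eta - offset) + (y_c - w) / w
        theta_new, neg = _maximize_reml(z, w, U, R, eig_R, theta)
        reml = -neg
        changes = [
            abs(theta_new.sigma2 - theta.sigma2) / (abs(theta.sigma2) + 1e-8),
            abs(theta_new.lam - theta.lam) / (abs(theta.lam) + 1e-8),
            np.max(np.abs(b_new - b)) / (np.max(np.abs(b)) + 1e-8)
            if b is not None else np.inf,
        ]
        if U.shape[1] and gamma is not None:
            changes.append(
                np.max(np.abs(gamma_new - gamma)) / (np.max(np.abs(gamma)) + 1e-8)
            )
        gamma, b, theta = gamma_new, b_new, theta_new
        if max(changes) < tol:
            converged = True
            break
    if not converged and require_convergence:
        raise ConvergenceError(
            f"group-level PQL did not converge in {max_alternations} "
            "alternations", last_iterate=(gamma, b, theta),
        )
    # final inner solve so (gamma, b) correspond exactly to the returned theta
    gamma, b, w = pql_inner_solve(y_c, U, offset, R, theta, gamma, b)
    return GroupModelFit(
        gamma=gamma, b=b, theta=theta,
        cov_gamma_naive=_gamma_covariance(w, U, R, theta),
        working_weights=w, n_iter=it, converged=converged, reml=reml,
    )


def estimate_theta(y_c, U, offset, R, theta_init=None, **kwargs) -> LerouxParams:
    """REML estimate of ``(sigma2, lam)`` for the group-level working LMM.

    Convenience wrapper around :func:`fit_group_car` returning only the
    variance components.
    """
    return fit_group_car(y_c, U, offset, R, theta_init=theta_init, **kwargs).theta


def _gamma_covariance(w, U, R, theta) -> np.ndarray:
    """Working-model GLS covariance ``(U^T V^{-1} U)^{-1}`` of gamma."""
    q = U.shape[1]
    if q == 0:
        return np.zeros((0, 0))
    P = leroux_precision(theta, R)
    cf = cho_factor(P + np.diag(w), lower=True)
    WU = w[:, None] * U
    ViU = WU - w[:, None] * cho_solve(cf, WU)
    G = U.T @ ViU
    cov = np.linalg.inv(G)
    return 0.5 * (cov + cov.T)
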