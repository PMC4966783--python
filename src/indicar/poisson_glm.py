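"""Poisson log-link GLM fitting by IRLS with an offset.

This is the engine for the initialization and individual-level steps of the
backfit: maximize the Poisson log-likelihood with linear predictor
``X beta + offset`` by iteratively re-weighted least squares (Fisher scoring)
with step-halving on deviance increase.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve, LinAlgError

from .errors import ConvergenceError, SingularityError


@dataclass
class GlmFit:
    """Converged Poisson GLM fit.

    ``cov_naive`` is ``(X^T W X)^{-1}`` at convergence with ``W = diag(mu)``;
    it treats the offset as known and is therefore naive within the larger
    mixed model.
    """

    coef: np.ndarray
    cov_naive: np.ndarray
    fitted_mu: np.ndarray
    deviance: float
    n_iter: int
    converged: bool


def poisson_deviance(y, mu) -> float:
    """Poisson deviance ``2 sum[y log(y/mu) - (y - mu)]``.

    The ``y = 0`` terms reduce to ``2 mu``.  Nonnegative; zero iff ``y = mu``
    elementwise.
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if np.any(mu <= 0):
        raise ValueError("mu must be strictly positive")
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / mu), 0.0)
    return float(2.0 * np.sum(term - (y - mu)))


def fit_poisson_glm(y, X, offset=None, tol=1e-10, max_iter=50,
                    beta0=None) -> GlmFit:
    """Maximize the Poisson log-likelihood with predictor ``X beta + offset``.

    Parameters
    ----------
    y
        Non-negative count vector, length ``n``.
    X
        Full-column-rank ``n x p`` design matrix.
    offset
        Known additive term in the log-mean (``None`` means zero).
    tol
        Convergence: relative deviance change below ``tol``.
    max_iter
        Iteration cap; exceeded caps raise :class:`ConvergenceError`.
    beta0
        Optional warm-start coefficients (overrides the default
        initialization below).

    Notes
    -----
    Initialization sets every coefficient to zero except the intercept-like
    first column, started at ``log(mean(y) + 0.5) - mean(offset)``, which is
    robust for sparse counts.  Each Fisher-scoring step is halved until the
    deviance does not increase.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    offset = np.zeros(n) if offset is None else np.asarray(offset, dtype=float)
    if offset.shape != (n,):
        raise ValueError("offset length must match y")

    if beta0 is not None:
        beta = np.asarray(beta0, dtype=float).copy()
    else:
        beta = np.zeros(p)
        if np.allclose(X[:, 0], X[0, 0]) and X[0, 0] != 0:
            beta[0] = (np.log(y.mean() + 0.5) - offset.mean()) / X[0, 0]
    eta = X @ beta + offset
    mu = np.exp(eta)
    dev = poisson_deviance(y, mu)

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        w = mu
        z = (eta - offset) + (y - mu) / mu
        XtW = X.T * w
        try:
            c, low = cho_factor(XtW @ X)
        except LinAlgError:
            raise SingularityError(
                "singular weighted design X^T W X: X is rank deficient "
                "on the observed data"
            )
        beta_new = cho_solve((c, low), XtW @ z)
        if not np.all(np.isfinite(beta_new)):
            raise ConvergenceError(
                f"non-finite IRLS update at iteration {it}", last_iterate=beta
            )
        step = beta_new - beta
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            eta_c = X @ cand + offset
            if np.max(eta_c) < 500:  # guard exp overflow
                mu_c = np.exp(eta_c)
                dev_c = poisson_deviance(y, mu_c)
                if dev_c <= dev * (1 + 1e-12) + 1e-12:
                    break
            scale *= 0.5
        else:
            raise ConvergenceError(
                f"step-halving failed at iteration {it}", last_iterate=beta
            )
        beta, eta, mu = cand, eta_c, mu_c
        if abs(dev - dev_c) <= tol * (abs(dev) + 0.1):
            dev = dev_c
            converged = True
            break
        dev = dev_c
    if not converged:
        raise ConvergenceError(
            f"Poisson IRLS did not converge in {max_iter} iterations",
            last_iterate=beta,
        )

    XtWX = (X.T * mu) @ X
    c, low = cho_factor(XtWX)
    cov = cho_solve((c, low), np.eye(p))
    return GlmFit(
        coef=beta, cov_naive=0.5 * (cov + cov.T), fitted_mu=mu,
        deviance=dev, n_iter=it, converged=converged,
    )
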