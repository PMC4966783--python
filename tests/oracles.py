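"""Independent reference implementations used only by the test suite.

These deliberately take the direct (dense, memory-hungry) route that the
package itself avoids: stacked joint IRLS over ``[X | ZU | Z]``, explicit
``n x n`` marginal covariance ``V``, and Henderson's mixed-model equations.
They share no code with the implementations they check.
"""

import numpy as np

from indicar.spatial import leroux_precision


def dense_Z(region_index, n_regions):
    n = len(region_index)
    Z = np.zeros((n, n_regions))
    Z[np.arange(n), region_index] = 1.0
    return Z


def joint_pql_dense(y, X, U, region_index, n_regions, R, theta,
                    tol=1e-13, max_iter=500):
    """Joint penalized IRLS over the stacked design ``[X | ZU | Z]``.

    Solves the penalized score equations for (beta, gamma, b) at fixed
    theta in one big system, the way a standard mixed-model IRLS would.
    """
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    q = U.shape[1]
    Z = dense_Z(region_index, n_regions)
    C = np.hstack([X, Z @ U, Z])
    P = leroux_precision(theta, R)
    pen = np.zeros((p + q + n_regions,) * 2)
    pen[p + q:, p + q:] = P
    delta = np.zeros(p + q + n_regions)
    delta[0] = np.log(y.mean() + 0.5)
    for _ in range(max_iter):
        eta = C @ delta
        mu = np.exp(eta)
        z = eta + (y - mu) / mu
        new = np.linalg.solve((C.T * mu) @ C + pen, (C.T * mu) @ z)
        step = np.max(np.abs(new - delta))
        delta = new
        if step < tol:
            break
    return delta[:p], delta[p:p + q], delta[p + q:]


def dense_fixed_covariance(X, U, region_index, n_regions, weights, D):
    """``(C^T V^{-1} C)^{-1}`` with ``V = Z D Z^T + W^{-1}`` formed explicitly."""
    Z = dense_Z(region_index, n_regions)
    C = np.hstack([X, Z @ U]) if U.shape[1] else X
    V = Z @ D @ Z.T + np.diag(1.0 / weights)
    return np.linalg.inv(C.T @ np.linalg.solve(V, C))


def henderson_solve(X, U, region_index, n_regions, weights, D, y_pseudo):
    """Henderson mixed-model equations for the working LMM."""
    Z = dense_Z(region_index, n_regions)
    C = np.hstack([X, Z @ U]) if U.shape[1] else X
    k = C.shape[1]
    Dinv = np.linalg.inv(D)
    W = np.diag(weights)
    A = np.block([[C.T @ W @ C, C.T @ W @ Z],
                  [Z.T @ W @ C, Z.T @ W @ Z + Dinv]])
    rhs = np.concatenate([C.T @ W @ y_pseudo, Z.T @ W @ y_pseudo])
    sol = np.linalg.solve(A, rhs)
    return sol[:X.shape[1]], sol[X.shape[1]:k], sol[k:]


def dense_reml_neg_loglik(theta, z, w, U, R):
    """REML criterion with ``V = D + W^{-1}`` formed and inverted densely."""
    P = leroux_precision(theta, R)
    V = np.linalg.inv(P) + np.diag(1.0 / w)
    Vi = np.linalg.inv(V)
    sign, logdet_V = np.linalg.slogdet(V)
    out = logdet_V
    if U.shape[1]:
        G = U.T @ Vi @ U
        gamma = np.linalg.solve(G, U.T @ Vi @ z)
        r = z - U @ gamma
        out += np.linalg.slogdet(G)[1]
    else:
        r = z
    out += r @ Vi @ r
    return 0.5 * out
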