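"""Block coordinate-descent solver for the graphical lasso.

Maximizes log|Theta| - tr(K Theta) - lambda * sum_{i != j} |Theta_ij| by the
standard column-wise strategy: each column update is an l1-penalized
regression solved by coordinate descent on the current covariance estimate W.
The diagonal is unpenalized, so W_ii = K_ii throughout. Warm starts in (W, B)
make descending-lambda paths cheap, which StARS relies on.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _cd_solve(K, lam, W, B, tol, max_iter):  # pragma: no cover - jitted
    p = K.shape[0]
    converged = False
    n_sweeps = 0
    inner_tol = tol * 0.1
    for it in range(max_iter):
        max_delta = 0.0
        for j in range(p):
            # lasso: minimize 0.5 b'W11 b - b'k12 + lam |b|_1  (b = B[:, j])
            for _ in range(200):
                inner_delta = 0.0
                for i in range(p):
                    if i == j:
                        continue
                    r = K[i, j]
                    for t in range(p):
                        if t != j and t != i:
                            r -= W[i, t] * B[t, j]
                    old = B[i, j]
                    if r > lam:
                        b = (r - lam) / W[i, i]
                    elif r < -lam:
                        b = (r + lam) / W[i, i]
                    else:
                        b = 0.0
                    B[i, j] = b
                    d = abs(b - old)
                    if d > inner_delta:
                        inner_delta = d
                if inner_delta < inner_tol:
                    break
            for i in range(p):
                if i == j:
                    continue
                w = 0.0
                for t in range(p):
                    if t != j:
                        w += W[i, t] * B[t, j]
                d = abs(w - W[i, j])
                if d > max_delta:
                    max_delta = d
                W[i, j] = w
                W[j, i] = w
        n_sweeps = it + 1
        if max_delta < tol:
            converged = True
            break
    theta = np.zeros((p, p))
    for j in range(p):
        s = W[j, j]
        for t in range(p):
            if t != j:
                s -= W[j, t] * B[t, j]
        tjj = 1.0 / s
        theta[j, j] = tjj
        for i in range(p):
            if i != j:
                theta[i, j] = -B[i, j] * tjj
    for i in range(p):
        for j in range(i + 1, p):
            v = 0.5 * (theta[i, j] + theta[j, i])
            theta[i, j] = v
            theta[j, i] = v
    return theta, n_sweeps, converged


def glasso_cd(K, lam, W=None, B=None, tol=1e-7, max_iter=200):
    """Solve the graphical lasso at penalty ``lam``.

    Returns (Theta, W, B, n_sweeps, converged); pass (W, B) back in for a
    warm start at the next (smaller) lambda.
    """
    K = np.ascontiguousarray(K, dtype=np.float64)
    p = K.shape[0]
    if W is None:
        W = K.copy()
        np.fill_diagonal(W, np.diag(K))
    if B is None:
        B = np.zeros((p, p))
    theta, n_sweeps, converged = _cd_solve(K, float(lam), W, B, tol, max_iter)
    return theta, W, B, n_sweeps, converged
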