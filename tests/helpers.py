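"""Independent numerical oracles used by the test suite.

These deliberately avoid the code paths they check: a fixed-step RK4
integrator (vs adaptive RK45 forecasting), a proximal-gradient elastic
net solver (vs coordinate descent), and closed-form linear-algebra
solutions.
"""

from __future__ import annotations

import numpy as np


def rk4(rhs, y0, times, step=1e-3):
    """Fixed-step classical Runge-Kutta, reporting states at ``times``."""
    y = np.asarray(y0, dtype=float).copy()
    out = [y.copy()]
    for t0, t1 in zip(times[:-1], times[1:]):
        n = max(1, int(np.ceil((t1 - t0) / step)))
        h = (t1 - t0) / n
        t = t0
        for _ in range(n):
            k1 = rhs(t, y)
            k2 = rhs(t + h / 2, y + h / 2 * k1)
            k3 = rhs(t + h / 2, y + h / 2 * k2)
            k4 = rhs(t + h, y + h * k3)
            y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            t += h
        out.append(y.copy())
    return np.array(out)


def proximal_elastic_net(X, Y, l1, l2, n_iter=200_000, tol=1e-12):
    """ISTA on 0.5-free objective ||Y - XB||_F^2 + sum_j l1_j|B_j| + l2_j B_j^2.

    Per-column penalty weights ``l1``, ``l2``.  Slow but simple; run to
    tight tolerance so it can serve as ground truth for small problems.
    """
    X = np.asarray(X, float)
    Y = np.atleast_2d(np.asarray(Y, float))
    l1 = np.asarray(l1, float)[:, None]
    l2 = np.asarray(l2, float)[:, None]
    n, p = X.shape
    L = 2 * np.linalg.eigvalsh(X.T @ X).max() + 2 * l2.max() + 1e-12
    B = np.zeros((p, Y.shape[1]))
    for _ in range(n_iter):
        grad = -2 * X.T @ (Y - X @ B) + 2 * l2 * B
        Z = B - grad / L
        B_new = np.sign(Z) * np.maximum(np.abs(Z) - l1 / L, 0.0)
        if np.max(np.abs(B_new - B)) < tol:
            B = B_new
            break
        B = B_new
    return B


def ridge_closed_form(X, Y, penalty_diag):
    """(X'X + diag(penalty))^{-1} X'Y."""
    X = np.asarray(X, float)
    return np.linalg.solve(X.T @ X + np.diag(penalty_diag), X.T @ np.atleast_2d(Y))


def matrix_exponential_affine(A, g, y0, times):
    """Closed-form solution of dy/dt = g + A y via the augmented exponential.

    Uses the block trick exp([[A, g],[0, 0]] t) so singular A is fine.
    """
    from scipy.linalg import expm

    d = len(y0)
    M = np.zeros((d + 1, d + 1))
    M[:d, :d] = A
    M[:d, d] = g
    z0 = np.concatenate([y0, [1.0]])
    return np.array([(expm(M * (t - times[0])) @ z0)[:d] for t in times])
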