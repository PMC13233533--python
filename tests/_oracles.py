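"""Independent reference solvers used only to cross-check the implementation."""

import numpy as np


def pg_slim_column(B: np.ndarray, y: np.ndarray, beta: float, lam: float,
                   n_iter: int = 100_000) -> np.ndarray:
    """Projected-gradient solver for one SLIM column.

    Minimizes 1/2 ||y - B w||^2 + beta/2 ||w||^2 + lam * sum(w) over w >= 0
    with a fixed small step (inverse Lipschitz constant).  Deliberately
    simple and slow; serves as the optimization oracle.
    """
    G = B.T @ B
    b = B.T @ y
    L = float(np.linalg.eigvalsh(G)[-1]) + beta
    if L <= 0:
        return np.zeros(B.shape[1])
    eta = 1.0 / L
    w = np.zeros(B.shape[1])
    for _ in range(n_iter):
        grad = G @ w - b + beta * w + lam
        w = np.maximum(w - eta * grad, 0.0)
    return w


def pg_slim_matrix(A: np.ndarray, beta: float, lam: float,
                   n_iter: int = 100_000) -> np.ndarray:
    """Joint projected-gradient solve of the full SLIM problem.

    Column-separable and therefore equivalent to per-column solves; iterates
    W <- proj(W - eta * (A^T A (W - I) + beta W + lam)) with proj enforcing
    W >= 0 and diag(W) = 0.
    """
    n = A.shape[1]
    G = A.T @ A
    L = float(np.linalg.eigvalsh(G)[-1]) + beta
    if L <= 0:
        return np.zeros((n, n))
    eta = 1.0 / L
    W = np.zeros((n, n))
    for _ in range(n_iter):
        grad = G @ W - G + beta * W + lam
        W = np.maximum(W - eta * grad, 0.0)
        np.fill_diagonal(W, 0.0)
    return W


def column_objective(B: np.ndarray, y: np.ndarray, w: np.ndarray,
                     beta: float, lam: float) -> float:
    r = y - B @ w
    return float(0.5 * r @ r + 0.5 * beta * w @ w + lam * np.sum(np.abs(w)))


def kkt_residual(B: np.ndarray, y: np.ndarray, w: np.ndarray,
                 beta: float, lam: float) -> float:
    """Worst first-order violation: |grad| on the support, max(-grad, 0) off it."""
    g = B.T @ (B @ w - y) + beta * w + lam
    on = np.abs(g[w > 0]).max(initial=0.0)
    off = np.maximum(-g[w == 0], 0.0).max(initial=0.0)
    return float(max(on, off))


def explicit_ridge_loocv(X: np.ndarray, y: np.ndarray, alpha: float) -> np.ndarray:
    """Leave-one-out ridge predictions by m explicit refits.

    Mirrors the conventions of the closed-form path: features standardized
    and response centered with full-data statistics, no intercept.
    """
    m, k = X.shape
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Xs = (X - mu) / sd
    ybar = y.mean()
    yc = y - ybar
    preds = np.empty(m)
    for i in range(m):
        keep = np.arange(m) != i
        A = Xs[keep]
        w = np.linalg.solve(A.T @ A + alpha * np.eye(k), A.T @ yc[keep])
        preds[i] = ybar + Xs[i] @ w
    return preds
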