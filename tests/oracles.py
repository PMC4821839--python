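"""Independent reference implementations used only to check the package.

These deliberately avoid the package's solver code paths: the group-lasso
oracle is a plain (full-vector) proximal-gradient iteration, FST is the
Hudson ratio-of-averages estimator written directly from its formula, and
the hypergeometric tail is an explicit finite sum of binomial ratios.
"""

from __future__ import annotations

from math import comb

import numpy as np


def prox_group(v: np.ndarray, groups: list[np.ndarray], thresholds: np.ndarray):
    out = v.copy()
    for gi, idx in enumerate(groups):
        nv = np.linalg.norm(v[idx])
        if nv <= thresholds[gi]:
            out[idx] = 0.0
        else:
            out[idx] = (1.0 - thresholds[gi] / nv) * v[idx]
    return out


def group_lasso_pg(
    X: np.ndarray,
    y: np.ndarray,
    groups: list[np.ndarray],
    weights: np.ndarray,
    lam: float,
    max_iter: int = 200000,
    tol: float = 1e-12,
) -> np.ndarray:
    """Full proximal-gradient (ISTA) solver for the group lasso."""
    L = np.linalg.norm(X, 2) ** 2
    b = np.zeros(X.shape[1])
    step = 1.0 / L
    for _ in range(max_iter):
        grad = X.T @ (X @ b - y)
        b_new = prox_group(b - step * grad, groups, step * lam * weights)
        if np.abs(b_new - b).max() <= tol * (1.0 + np.abs(b).max(initial=0.0)):
            b = b_new
            break
        b = b_new
    return b


def gggl1_pg(
    X: np.ndarray,
    y: np.ndarray,
    groups: list[np.ndarray],
    weights: np.ndarray,
    lam: float,
    A: np.ndarray,
    mu: float,
    max_iter: int = 400000,
    tol: float = 1e-13,
) -> np.ndarray:
    """Proximal gradient for the smooth-network variant: the quadratic
    network term on per-gene mean coefficients joins the smooth part."""
    m = len(groups)
    sizes = np.array([g.size for g in groups], dtype=float)
    deg = A.sum(axis=1)
    # Lipschitz bound: data term + network quadratic (graph Laplacian on means)
    lap_norm = 2.0 * mu * (deg / sizes).max() if mu > 0 else 0.0
    L = np.linalg.norm(X, 2) ** 2 + lap_norm + 1e-9
    b = np.zeros(X.shape[1])
    step = 1.0 / L
    for _ in range(max_iter):
        grad = X.T @ (X @ b - y)
        if mu > 0:
            s = np.array([b[g].mean() for g in groups])
            pull = 2.0 * mu * (deg * s - A @ s)
            for gi, g in enumerate(groups):
                grad[g] += pull[gi] / sizes[gi]
        b_new = prox_group(b - step * grad, groups, step * lam * weights)
        if np.abs(b_new - b).max() <= tol * (1.0 + np.abs(b).max(initial=0.0)):
            b = b_new
            break
        b = b_new
    return b


def hudson_fst(g1: np.ndarray, g2: np.ndarray) -> float:
    """Hudson FST (ratio of averages) from two subpopulation dosage blocks."""
    n1 = 2 * g1.shape[0]
    n2 = 2 * g2.shape[0]
    p1 = g1.mean(axis=0) / 2.0
    p2 = g2.mean(axis=0) / 2.0
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    keep = den > 0
    return float(num[keep].sum() / den[keep].sum())


def hypergeom_tail_enum(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) by direct summation of hypergeometric point masses."""
    total = comb(N, n)
    acc = 0
    for i in range(max(k, 0, n + K - N), min(K, n) + 1):
        acc += comb(K, i) * comb(N - K, n - i)
    return acc / total


def elbow_by_distances(eigenvalues) -> int:
    """Scree elbow by evaluating the point-to-chord distance at every index."""
    lam = np.asarray(eigenvalues, dtype=float)
    m = lam.size
    x1, y1, x2, y2 = 1.0, lam[0], float(m), lam[-1]
    best, best_d = 1, -1.0
    for i in range(m):
        x0, y0 = i + 1.0, lam[i]
        d = abs((y2 - y1) * x0 - (x2 - x1) * y0 + x2 * y1 - y2 * x1) / np.hypot(
            x2 - x1, y2 - y1
        )
        if d > best_d + 1e-15:
            best_d = d
            best = i + 1
    return best
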