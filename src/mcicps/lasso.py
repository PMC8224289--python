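"""Exact Lasso solver with EDPP safe screening.

The penalized least-squares problem

    F(x) = 1/2 ||A x - y||^2 + lambda ||x||_1

is solved by cyclic coordinate descent with soft-thresholding, using
covariance ("Gram") updates so repeated solves on small balanced
subsamples are cheap.  The inner sweep is numba-jitted.

EDPP (enhanced dual polytope projection) screening discards features that
are *guaranteed* to have zero coefficients at a smaller penalty lambda_1,
given the exact solution at lambda_0: the dual optimum at lambda_1 lies in
a ball constructed by projecting along the path from the dual optimum at
lambda_0, and any feature whose column stays strictly inside the dual
feasible slab over that ball can be dropped before solving.  Rejection is
safe — the screened and unscreened solutions are identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit


class ConvergenceError(RuntimeError):
    """Solver failed to reach the KKT tolerance; carries the residual."""


@dataclass
class LassoProblem:
    A: np.ndarray      # (m, n) design, columns standardized by convention
    y: np.ndarray      # (m,) response, centered by convention
    lam: float

    def __post_init__(self) -> None:
        self.A = np.ascontiguousarray(self.A, dtype=float)
        self.y = np.ascontiguousarray(self.y, dtype=float)
        if self.A.ndim != 2 or self.y.shape != (self.A.shape[0],):
            raise ValueError("A must be (m, n) and y (m,)")
        if not self.lam > 0:
            raise ValueError("lambda must be positive")


@dataclass
class LassoSolution:
    x: np.ndarray
    objective: float
    kkt_residual: float
    lam: float
    n_iter: int

    @property
    def active_set(self) -> np.ndarray:
        return np.flatnonzero(self.x != 0.0)


def objective_value(A: np.ndarray, y: np.ndarray, x: np.ndarray,
                    lam: float) -> float:
    r = A @ x - y
    return 0.5 * float(r @ r) + lam * float(np.abs(x).sum())


def lambda_max(A: np.ndarray, y: np.ndarray) -> float:
    """Smallest penalty at which the solution is identically zero."""
    y = np.asarray(y, dtype=float)
    if not np.any(y):
        raise ValueError("y is identically zero; lambda_max undefined")
    return float(np.abs(A.T @ y).max())


@njit(cache=False)
def _cd_sweeps(G, c, lam, x, max_iter, tol):  # pragma: no cover - jitted
    n = G.shape[0]
    g = c - G @ x
    kkt = np.inf
    for it in range(max_iter):
        for j in range(n):
            gjj = G[j, j]
            if gjj <= 0.0:
                continue
            rho = g[j] + gjj * x[j]
            if rho > lam:
                xj = (rho - lam) / gjj
            elif rho < -lam:
                xj = (rho + lam) / gjj
            else:
                xj = 0.0
            d = xj - x[j]
            if d != 0.0:
                x[j] = xj
                for i in range(n):
                    g[i] -= d * G[i, j]
        kkt = 0.0
        for j in range(n):
            if x[j] > 0.0:
                v = abs(g[j] - lam)
            elif x[j] < 0.0:
                v = abs(g[j] + lam)
            else:
                v = abs(g[j]) - lam
                if v < 0.0:
                    v = 0.0
            if v > kkt:
                kkt = v
        if kkt <= tol:
            return it + 1, kkt
    return max_iter, kkt


def solve_lasso(p: LassoProblem, tol: float = 1e-10, max_iter: int = 100_000,
                keep: np.ndarray | None = None,
                x0: np.ndarray | None = None) -> LassoSolution:
    """Cyclic coordinate descent to KKT residual <= tol.

    ``keep`` restricts the solve to a feature subset (e.g. EDPP survivors);
    coefficients outside it are fixed at zero.  ``x0`` warm-starts.
    """
    n = p.A.shape[1]
    if keep is None:
        keep = np.arange(n)
    keep = np.asarray(keep, dtype=int)
    x_full = np.zeros(n)
    if p.lam >= lambda_max(p.A, p.y) - 1e-12:
        return LassoSolution(x_full, objective_value(p.A, p.y, x_full, p.lam),
                             0.0, p.lam, 0)
    Ak = p.A[:, keep]
    G = Ak.T @ Ak
    c = Ak.T @ p.y
    x = np.zeros(len(keep)) if x0 is None else np.asarray(x0, dtype=float)[keep]
    n_iter, kkt = _cd_sweeps(np.ascontiguousarray(G), np.ascontiguousarray(c),
                             p.lam, x, max_iter, tol)
    if kkt > tol:
        raise ConvergenceError(
            f"coordinate descent stalled at KKT residual {kkt:.3e} "
            f"after {n_iter} sweeps (tol {tol:.1e})"
        )
    x_full[keep] = x
    return LassoSolution(x_full, objective_value(p.A, p.y, x_full, p.lam),
                         float(kkt), p.lam, int(n_iter))


def edpp_screen(prev: LassoSolution, lam1: float, A: np.ndarray,
                y: np.ndarray) -> np.ndarray:
    """Safe feature rejection at lam1 < prev.lam; returns a boolean mask.

    Every True entry is guaranteed zero in the exact solution at ``lam1``.
    ``prev`` must be the exact solution at its own penalty (which may be
    lambda_max with x = 0).
    """
    lam0 = prev.lam
    if lam1 >= lam0:
        raise ValueError("lam1 must be smaller than the previous lambda")
    A = np.asarray(A, dtype=float)
    y = np.asarray(y, dtype=float)
    theta0 = (y - A @ prev.x) / lam0
    lmax = lambda_max(A, y)
    if lam0 >= lmax - 1e-12:
        corr = A.T @ y
        jstar = int(np.argmax(np.abs(corr)))
        v1 = np.sign(corr[jstar]) * A[:, jstar]
    else:
        v1 = y / lam0 - theta0
    v2 = y / lam1 - theta0
    v1sq = float(v1 @ v1)
    v2perp = v2 - (float(v1 @ v2) / v1sq) * v1 if v1sq > 1e-30 else v2
    center = theta0 + 0.5 * v2perp
    radius = 0.5 * float(np.linalg.norm(v2perp))
    col_norms = np.linalg.norm(A, axis=0)
    return np.abs(A.T @ center) < 1.0 - radius * col_norms


def solve_lasso_path(A: np.ndarray, y: np.ndarray, lams: np.ndarray,
                     tol: float = 1e-10, max_iter: int = 100_000,
                     screen: bool = True) -> list[LassoSolution]:
    """Solve along a decreasing lambda path with sequential EDPP screening."""
    lams = np.asarray(lams, dtype=float)
    if np.any(np.diff(lams) >= 0):
        raise ValueError("lambda path must be strictly decreasing")
    lmax = lambda_max(A, y)
    n = A.shape[1]
    prev = LassoSolution(np.zeros(n), objective_value(A, y, np.zeros(n), lmax),
                         0.0, lmax, 0)
    out = []
    for lam in lams:
        if lam >= lmax:
            sol = LassoSolution(np.zeros(n),
                                objective_value(A, y, np.zeros(n), lam),
                                0.0, float(lam), 0)
        else:
            if screen:
                rejected = edpp_screen(prev, float(lam), A, y)
                keep = np.flatnonzero(~rejected)
            else:
                keep = np.arange(n)
            sol = solve_lasso(LassoProblem(A, y, float(lam)), tol=tol,
                              max_iter=max_iter, keep=keep, x0=prev.x)
        out.append(sol)
        prev = sol
    return out
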