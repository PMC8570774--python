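"""One-step solvers for the ill-posed linear system A x = B.

Four textbook algorithms are provided, spanning L2 regularization
(Tikhonov, damped SVD), L1 regularization (soft-thresholded LSQR), and
greedy sparse pursuit (OMP).  They are deterministic given (A, B, params)
and return solutions as-is (no nonnegativity clamp — that is a modelling
choice of the reconstruction framework, not of the solvers).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.sparse.linalg as spla

__all__ = [
    "SolverSpec",
    "solve_tikhonov",
    "solve_dsvd",
    "solve_lassolsqr",
    "solve_omp",
    "solve",
    "default_lambda",
]

SOLVER_NAMES = ("tikhonov", "dsvd", "lassolsqr", "omp")


@dataclass
class SolverSpec:
    """Choice of algorithm plus its scalar parameters.

    ``lam`` (regularization weight) defaults to a scale-free value of
    1e-3 * sigma_max(A)^2 when None; ``k`` is the OMP sparsity budget.
    """

    method: str = "tikhonov"
    lam: float | None = None
    k: int = 10
    max_iter: int = 200

    def __post_init__(self) -> None:
        if self.method not in SOLVER_NAMES:
            raise ValueError(f"method must be one of {SOLVER_NAMES}")
        if self.lam is not None and self.lam < 0:
            raise ValueError("lam must be >= 0")
        if self.k < 1:
            raise ValueError("k must be >= 1")


def default_lambda(A: np.ndarray) -> float:
    """Scale-free default regularization weight 1e-3 * sigma_max(A)^2."""
    smax = scipy.linalg.svdvals(A)[0] if min(A.shape) else 0.0
    return 1e-3 * smax**2


def solve_tikhonov(A: np.ndarray, B: np.ndarray, lam: float) -> np.ndarray:
    """x = argmin ||Ax - B||^2 + lam ||x||^2 = (A'A + lam I)^-1 A'B.

    Uses the dual identity A'(AA' + lam I)^-1 B when M < N so the dense
    solve is always on the smaller Gram matrix.
    """
    if lam <= 0:
        raise ValueError("lam must be > 0 for Tikhonov")
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    m, n = A.shape
    if m < n:
        G = A @ A.T + lam * np.eye(m)
        return A.T @ scipy.linalg.solve(G, B, assume_a="pos")
    G = A.T @ A + lam * np.eye(n)
    return scipy.linalg.solve(G, A.T @ B, assume_a="pos")


def solve_dsvd(A: np.ndarray, B: np.ndarray, lam: float) -> np.ndarray:
    """Damped SVD: filter factors sigma_i / (sigma_i + lam) on the thin SVD.

    x = sum_i [sigma_i/(sigma_i+lam)] (u_i'B / sigma_i) v_i
      = sum_i (u_i'B) / (sigma_i + lam) v_i.
    """
    if lam <= 0:
        raise ValueError("lam must be > 0 for DSVD")
    A = np.asarray(A, dtype=float)
    if not np.any(A):
        warnings.warn("zero system matrix; returning x = 0", stacklevel=2)
        return np.zeros(A.shape[1])
    U, s, Vt = scipy.linalg.svd(A, full_matrices=False)
    coeff = (U.T @ np.asarray(B, dtype=float)) / (s + lam)
    return Vt.T @ coeff


def _soft(x: np.ndarray, t: float) -> np.ndarray:
    return np.sign(x) * np.maximum(np.abs(x) - t, 0.0)


def solve_lassolsqr(
    A: np.ndarray,
    B: np.ndarray,
    lam: float,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> np.ndarray:
    """Approximate argmin ||Ax - B||^2 + lam ||x||_1.

    lam = 0 falls back to plain LSQR least squares.  For lam > 0 the
    solver runs accelerated proximal-gradient steps (least-squares
    gradient + soft threshold), the iterative-shrinkage companion of
    LSQR for L1 problems; on an orthonormal design one step reproduces
    the closed form soft(A'B, lam/2).
    """
    if lam < 0:
        raise ValueError("lam must be >= 0")
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if lam == 0:
        return spla.lsqr(A, B, atol=1e-12, btol=1e-12)[0]
    L = scipy.linalg.svdvals(A)[0] ** 2  # Lipschitz constant of the LS gradient
    if L == 0:
        return np.zeros(A.shape[1])
    step = 1.0 / (2.0 * L)
    x = np.zeros(A.shape[1])
    y = x.copy()
    t = 1.0
    converged = False
    for _ in range(max_iter):
        grad = 2.0 * (A.T @ (A @ y - B))
        x_new = _soft(y - step * grad, step * lam)
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
        y = x_new + ((t - 1.0) / t_new) * (x_new - x)
        if np.linalg.norm(x_new - x) <= tol * max(1.0, np.linalg.norm(x)):
            x = x_new
            converged = True
            break
        x, t = x_new, t_new
    if not converged:
        warnings.warn("lassolsqr reached max_iter; returning best iterate", stacklevel=2)
    return x


def solve_omp(
    A: np.ndarray, B: np.ndarray, k: int, tol: float | None = None
) -> np.ndarray:
    """Orthogonal matching pursuit with k greedy steps.

    Columns are L2-normalized for atom selection (maximal |correlation|
    with the residual); the solution is a least-squares refit on the
    selected support at every step, zero off-support.  Stops early when
    the residual drops below ``tol`` (default 1e-6 ||B||).
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    m, n = A.shape
    if not 1 <= k <= n:
        raise ValueError("k must be in [1, n_columns]")
    if tol is None:
        tol = 1e-6 * np.linalg.norm(B)
    norms = np.linalg.norm(A, axis=0)
    norms[norms == 0] = 1.0
    support: list[int] = []
    x = np.zeros(n)
    residual = B.copy()
    for _ in range(k):
        if np.linalg.norm(residual) <= tol:
            break
        corr = np.abs(A.T @ residual) / norms
        corr[support] = -np.inf
        j = int(np.argmax(corr))
        support.append(j)
        sub = A[:, support]
        coef, *_ = scipy.linalg.lstsq(sub, B)  # min-norm on rank deficiency
        residual = B - sub @ coef
    x[support] = coef if support else 0.0
    return x


def solve(A: np.ndarray, B: np.ndarray, spec: SolverSpec) -> np.ndarray:
    """Dispatch to the solver named in ``spec`` with its parameters."""
    lam = spec.lam if spec.lam is not None else default_lambda(A)
    if spec.method == "tikhonov":
        return solve_tikhonov(A, B, lam)
    if spec.method == "dsvd":
        return solve_dsvd(A, B, lam)
    if spec.method == "lassolsqr":
        return solve_lassolsqr(A, B, lam, max_iter=spec.max_iter)
    return solve_omp(A, B, min(spec.k, A.shape[1]))
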