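"""L1-penalized least squares: objective, coordinate-descent solver, mask.

The objective is J(psi) = (1/(2N)) * ||f - L psi||_2^2 + alpha * ||psi||_1.
The solver z-scores columns (population sd) and centers the response before
cyclic coordinate descent with soft-thresholding; coefficients are reported
on the standardized scale. Exact-zero-variance columns always get psi = 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

DEFAULT_TOL = 1e-6
DEFAULT_MAX_SWEEPS = 1000


@dataclass
class LassoProblem:
    """One penalized regression instance; holds L and f verbatim."""

    L: np.ndarray
    f: np.ndarray
    alpha: float
    N: int = field(init=False)

    def __post_init__(self) -> None:
        self.L = np.asarray(self.L, dtype=float)
        self.f = np.asarray(self.f, dtype=float)
        if self.L.ndim != 2:
            raise ValueError("L must be a 2-D matrix")
        if self.f.shape != (self.L.shape[0],):
            raise ValueError("f must be a vector with one entry per row of L")
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")
        self.N = self.L.shape[0]

    def standardized(self) -> "LassoProblem":
        """Copy with z-scored columns (sd over N) and centered response.

        Zero-variance columns become all-zero columns, pinning their
        coefficients to zero in any minimizer with alpha > 0.
        """
        mu = self.L.mean(axis=0)
        sd = self.L.std(axis=0, ddof=0)
        safe = np.where(sd > 0, sd, 1.0)
        Lz = (self.L - mu) / safe
        Lz[:, sd == 0] = 0.0
        return LassoProblem(Lz, self.f - self.f.mean(), self.alpha)


@dataclass
class LassoFit:
    psi: np.ndarray
    objective: float
    n_nonzero: int
    sweeps_used: int
    converged: bool
    problem: LassoProblem  # the (standardized) problem the fit minimizes


def lasso_objective(problem: LassoProblem, psi: np.ndarray) -> float:
    """(1/(2N)) * ||f - L psi||^2 + alpha * ||psi||_1, on L and f as given."""
    psi = np.asarray(psi, dtype=float)
    if psi.shape != (problem.L.shape[1],):
        raise ValueError("psi length must equal the number of columns of L")
    resid = problem.f - problem.L @ psi
    return float(resid @ resid / (2.0 * problem.N) + problem.alpha * np.abs(psi).sum())


def soft_threshold(z: np.ndarray, gamma: float) -> np.ndarray:
    """sign(z) * max(|z| - gamma, 0)."""
    return np.sign(z) * np.maximum(np.abs(z) - gamma, 0.0)


def _cd_kernel(
    X: np.ndarray,
    Y: np.ndarray,
    alpha: float,
    tol: float,
    max_sweeps: int,
) -> tuple[np.ndarray, int, bool]:
    """Cyclic coordinate descent on standardized X against responses Y (n x k).

    Assumes each active column of X has mean 0 and (1/N)*||x_j||^2 == 1;
    all-zero columns are skipped. Returns (psi (t x k), sweeps, converged).
    """
    n, t = X.shape
    k = Y.shape[1]
    norms = (X * X).sum(axis=0) / n
    active = np.flatnonzero(norms > 0)
    psi = np.zeros((t, k))
    R = Y.copy()  # residual f - X psi, maintained incrementally
    sweeps = 0
    converged = False
    for sweeps in range(1, max_sweeps + 1):
        max_delta = 0.0
        for j in active:
            xj = X[:, j]
            old = psi[j].copy()
            c = old * norms[j] + xj @ R / n
            new = soft_threshold(c, alpha) / norms[j]
            delta = new - old
            if np.any(delta):
                R -= np.outer(xj, delta)
                psi[j] = new
                max_delta = max(max_delta, float(np.abs(delta).max()))
        if max_delta < tol:
            converged = True
            break
    return psi, sweeps, converged


def fit_lasso(
    problem: LassoProblem,
    tol: float = DEFAULT_TOL,
    max_sweeps: int = DEFAULT_MAX_SWEEPS,
) -> LassoFit:
    """Minimize the penalized objective by cyclic coordinate descent.

    The problem is standardized internally; ``fit.problem`` holds that
    standardized instance, and ``fit.objective`` is the objective recomputed
    on it at ``fit.psi``.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    std = problem.standardized()
    zero_var = np.flatnonzero(std.L.std(axis=0, ddof=0) == 0)
    if zero_var.size and problem.alpha == 0:
        warnings.warn(
            f"{zero_var.size} constant column(s) have degenerate variance; "
            "their coefficients are pinned to 0",
            RuntimeWarning,
            stacklevel=2,
        )
    psi, sweeps, converged = _cd_kernel(
        std.L, std.f[:, None], problem.alpha, tol, max_sweeps
    )
    psi = psi[:, 0]
    return LassoFit(
        psi=psi,
        objective=lasso_objective(std, psi),
        n_nonzero=int(np.count_nonzero(psi)),
        sweeps_used=sweeps,
        converged=converged,
        problem=std,
    )


def select_nonzero(fit: LassoFit) -> np.ndarray:
    """Boolean mask: feature j kept iff |psi_j| > 0."""
    return np.abs(fit.psi) > 0


def one_hot(labels: np.ndarray, classes: np.ndarray | None = None) -> np.ndarray:
    labels = np.asarray(labels)
    if classes is None:
        classes = np.unique(labels)
    return (labels[:, None] == classes[None, :]).astype(float)


def fit_lasso_multiclass(
    features: np.ndarray,
    labels: np.ndarray,
    alpha: float,
    tol: float = DEFAULT_TOL,
    max_sweeps: int = DEFAULT_MAX_SWEEPS,
) -> tuple[np.ndarray, float, np.ndarray]:
    """One-vs-rest LASSO over one-hot targets, solved jointly.

    Returns (mask, mean objective over classes, psi matrix t x k). A feature
    is selected if its coefficient is nonzero in ANY class fit.
    """
    X = np.asarray(features, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    safe = np.where(sd > 0, sd, 1.0)
    Xz = (X - mu) / safe
    Xz[:, sd == 0] = 0.0
    Y = one_hot(labels)
    Y = Y - Y.mean(axis=0)
    psi, _, _ = _cd_kernel(Xz, Y, alpha, tol, max_sweeps)
    n = X.shape[0]
    R = Y - Xz @ psi
    per_class = (R * R).sum(axis=0) / (2.0 * n) + alpha * np.abs(psi).sum(axis=0)
    mask = np.any(np.abs(psi) > 0, axis=1)
    return mask, float(per_class.mean()), psi
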