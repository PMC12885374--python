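"""Gram-matrix coordinate-descent kernel for the LASSO objective.

Solves min_psi 0.5*psi^T G psi - B^T psi + alpha*||psi||_1 per response
column, where G = X^T X / N and B = X^T Y / N. Mathematically equivalent to
the residual-based kernel in :mod:`fleaselect.lasso`; this formulation never
touches the sample dimension inside the loop, so it is the one used in the
flea-fitness hot path. JIT-compiled with numba when available.
"""

from __future__ import annotations

import numpy as np


def _cd_gram_py(
    G: np.ndarray, B: np.ndarray, alpha: float, tol: float, max_sweeps: int
) -> tuple[np.ndarray, int, bool]:
    m, k = B.shape
    psi = np.zeros((m, k))
    Gpsi = np.zeros((m, k))  # G @ psi, maintained incrementally
    sweeps = 0
    for sweeps in range(1, max_sweeps + 1):
        max_delta = 0.0
        for j in range(m):
            gjj = G[j, j]
            if gjj <= 0.0:
                continue
            for c in range(k):
                cj = B[j, c] - Gpsi[j, c] + gjj * psi[j, c]
                if cj > alpha:
                    new = (cj - alpha) / gjj
                elif cj < -alpha:
                    new = (cj + alpha) / gjj
                else:
                    new = 0.0
                d = new - psi[j, c]
                if d != 0.0:
                    for i in range(m):
                        Gpsi[i, c] += G[i, j] * d
                    psi[j, c] = new
                    if abs(d) > max_delta:
                        max_delta = abs(d)
        if max_delta < tol:
            return psi, sweeps, True
    return psi, sweeps, False


try:  # pragma: no cover - exercised indirectly
    from numba import njit

    cd_gram = njit(cache=False)(_cd_gram_py)
except ImportError:  # pragma: no cover
    cd_gram = _cd_gram_py


def gram_objective(
    G: np.ndarray, B: np.ndarray, yty_over_n: np.ndarray, psi: np.ndarray, alpha: float
) -> np.ndarray:
    """Per-class objective values from the Gram-space quantities."""
    quad = 0.5 * np.einsum("jc,jk,kc->c", psi, G, psi)
    lin = (B * psi).sum(axis=0)
    return 0.5 * yty_over_n - lin + quad + alpha * np.abs(psi).sum(axis=0)
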