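"""Small shared linear-algebra utilities for correlation matrices."""

from __future__ import annotations

import numpy as np

EIG_FLOOR = 1e-4


def smooth_correlation(R: np.ndarray, eig_floor: float = EIG_FLOOR) -> tuple[np.ndarray, bool]:
    """Force a symmetric matrix to be a positive-definite correlation matrix.

    Eigenvalues below ``eig_floor`` are clipped to the floor and the matrix is
    re-standardized to unit diagonal. Returns ``(matrix, smoothed)`` where
    ``smoothed`` records whether any repair was applied.
    """
    R = np.asarray(R, dtype=float)
    R = 0.5 * (R + R.T)
    vals, vecs = np.linalg.eigh(R)
    if vals.min() >= eig_floor:
        out = R.copy()
        np.fill_diagonal(out, 1.0)
        return out, False
    out = R
    for _ in range(100):  # re-standardizing can push an eigenvalue back down
        vals, vecs = np.linalg.eigh(out)
        if vals.min() >= eig_floor * (1 - 1e-9):
            break
        vals = np.clip(vals, eig_floor * 1.1, None)
        out = (vecs * vals) @ vecs.T
        d = np.sqrt(np.diag(out))
        out = out / np.outer(d, d)
        out = 0.5 * (out + out.T)
    np.fill_diagonal(out, 1.0)
    return out, True


def is_positive_definite(M: np.ndarray, tol: float = 0.0) -> bool:
    return bool(np.linalg.eigvalsh(0.5 * (M + M.T)).min() > tol)
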