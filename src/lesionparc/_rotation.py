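"""Varimax rotation with Kaiser row-normalisation.

Implemented as the classical pairwise (Jacobi-style) algorithm: sweeps
over all column pairs, each rotated in-plane by the closed-form optimal
angle ``phi = atan2(num, den) / 4`` of the varimax criterion, iterated to
convergence.  Each sweep is O(n_rows * k^2), which stays fast for
voxel-scale loading matrices where general gradient-projection rotation
routines become impractically slow.

With Kaiser normalisation the optimal rotation is found on row-normalised
loadings; because the normalisation acts row-wise, applying the same
orthogonal matrix to the raw loadings yields the de-normalised solution.
"""
from __future__ import annotations

import numpy as np


def varimax_criterion(loadings: np.ndarray) -> float:
    """Raw varimax objective: sum over columns of the variance of the
    squared loadings, sum_j [ mean(a_j^4) - mean(a_j^2)^2 ]."""
    A2 = np.asarray(loadings, dtype=float) ** 2
    return float(np.sum((A2 ** 2).mean(axis=0) - A2.mean(axis=0) ** 2))


def kaiser_normalize(A: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    h = np.linalg.norm(A, axis=1)
    h_safe = np.where(h > 0, h, 1.0)
    return A / h_safe[:, None], h_safe


def _pairwise_sweeps(B: np.ndarray, tol: float, max_sweeps: int) -> np.ndarray:
    """Kaiser's planar-rotation iteration; returns the accumulated k x k
    orthogonal rotation."""
    p, k = B.shape
    R = np.eye(k)
    B = B.copy()
    for _ in range(max_sweeps):
        max_angle = 0.0
        for i in range(k - 1):
            for j in range(i + 1, k):
                a, b = B[:, i], B[:, j]
                u = a * a - b * b
                v = 2.0 * a * b
                su, sv = u.sum(), v.sum()
                num = 2.0 * (u @ v - su * sv / p)
                den = (u @ u - v @ v) - (su * su - sv * sv) / p
                phi = 0.25 * np.arctan2(num, den)
                if abs(phi) < 1e-15:
                    continue
                max_angle = max(max_angle, abs(phi))
                c, s = np.cos(phi), np.sin(phi)
                G = np.array([[c, -s], [s, c]])
                B[:, [i, j]] = B[:, [i, j]] @ G
                R[:, [i, j]] = R[:, [i, j]] @ G
        if max_angle < tol:
            break
    return R


def varimax_rotation(
    A: np.ndarray, kaiser: bool = True, tol: float = 1e-12, max_sweeps: int = 200
) -> np.ndarray:
    """Orthogonal k x k matrix T maximising the varimax criterion of
    ``A @ T`` (criterion evaluated on Kaiser row-normalised loadings when
    ``kaiser`` is set, the convention of classical factor software)."""
    A = np.asarray(A, dtype=float)
    if A.ndim != 2:
        raise ValueError("loadings must be a 2-D array")
    k = A.shape[1]
    if k == 1:
        return np.eye(1)
    target = kaiser_normalize(A)[0] if kaiser else A
    return _pairwise_sweeps(target, tol, max_sweeps)
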