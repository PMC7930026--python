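"""Shared numerical linear-algebra primitives.

Every pseudoinverse, numerical rank, and kernel basis in this package uses one
consistent convention: singular values below an *absolute* threshold (default
``1e-8``) are treated as zero.  Using a single notion of numerical rank
throughout keeps the control expressions, the reachability tests, and the
rank-based controllability test mutually consistent.
"""

from __future__ import annotations

import numpy as np

#: Absolute singular-value truncation threshold used by default everywhere.
DEFAULT_PINV_TOL = 1e-8


def pinv(X: np.ndarray, tol: float = DEFAULT_PINV_TOL) -> np.ndarray:
    """Moore-Penrose pseudoinverse via SVD with absolute truncation.

    Singular values ``s <= tol`` are zeroed rather than inverted.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.size == 0:
        return np.zeros((X.shape[1], X.shape[0]))
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    inv = np.where(s > tol, 1.0 / np.where(s > tol, s, 1.0), 0.0)
    return (Vt.T * inv) @ U.T


def numerical_rank(X: np.ndarray, tol: float = DEFAULT_PINV_TOL) -> int:
    """Number of singular values strictly above the absolute threshold."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.size == 0:
        return 0
    s = np.linalg.svd(X, compute_uv=False)
    return int(np.sum(s > tol))


def kernel_basis(X: np.ndarray, tol: float = DEFAULT_PINV_TOL) -> np.ndarray:
    """Orthonormal basis of the numerical kernel of ``X``.

    Returns an array of shape ``(X.shape[1], k)`` whose columns are the right
    singular vectors associated with singular values at or below ``tol``
    (including the trivial ones beyond ``min(X.shape)``).  ``k = 0`` yields an
    empty ``(n, 0)`` array.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[1]
    if X.size == 0:
        return np.eye(n)
    _, s, Vt = np.linalg.svd(X, full_matrices=True)
    rank = int(np.sum(s > tol))
    return Vt[rank:].T.copy()


def psd_sqrt(G: np.ndarray, rel_clip: float = 1e-12) -> np.ndarray:
    """A matrix ``M`` with ``M.T @ M == G`` for symmetric PSD ``G``.

    Computed from the symmetric eigendecomposition, clipping eigenvalues
    below ``rel_clip * lambda_max`` to zero.  A Cholesky factor would fail on
    PSD matrices with a nontrivial nullspace, which arise routinely here
    (e.g. rank-deficient data Gram matrices).
    """
    G = np.asarray(G, dtype=float)
    if G.size == 0:
        return G.copy()
    w, V = np.linalg.eigh(0.5 * (G + G.T))
    wmax = max(float(w[-1]), 0.0)
    w = np.where(w > rel_clip * wmax, w, 0.0)
    return np.sqrt(w)[:, None] * V.T


def range_residual(X: np.ndarray, y: np.ndarray,
                   tol: float = DEFAULT_PINV_TOL) -> float:
    """Norm of the component of ``y`` outside the numerical range of ``X``."""
    y = np.asarray(y, dtype=float).ravel()
    return float(np.linalg.norm(y - X @ (pinv(X, tol) @ y)))
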