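"""Generalized singular value decomposition (GSVD) of two column-matched matrices.

The GSVD factors two real matrices ``D1`` (K1 x N) and ``D2`` (K2 x N) that
share a column dimension as::

    D1 = U1 @ diag(sigma1) @ V.T
    D2 = U2 @ diag(sigma2) @ V.T

with a *common* invertible right factor ``V``, orthonormal column bases
``U1``/``U2`` and strictly positive generalized singular values.  The ratio
``sigma1[a] / sigma2[a]`` measures the significance of the shared right basis
vector ``V[:, a]`` in ``D1`` relative to ``D2``; it is re-expressed as an
angular distance ``theta = arctan(sigma1/sigma2) - pi/4`` in ``[-pi/4, pi/4]``
so that ``+pi/4`` means "exclusive to dataset 1", ``-pi/4`` "exclusive to
dataset 2" and ``0`` "equally present in both".

Factors are ordered by decreasing ``sigma1/sigma2`` ratio, so the most
dataset-1-exclusive direction comes first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

__all__ = [
    "MatrixGSVD",
    "matrix_gsvd",
    "angular_distances",
    "gsvd_eigen_oracle",
    "RankDeficiencyError",
]

_QUARTER_PI = np.pi / 4.0


class RankDeficiencyError(np.linalg.LinAlgError):
    """An input matrix is numerically rank-deficient (full column rank required)."""


@dataclass(frozen=True)
class MatrixGSVD:
    """Result container for the two-matrix GSVD.

    Attributes
    ----------
    U1, U2 : ndarray
        Orthonormal column bases (K1 x N and K2 x N).
    sigma1, sigma2 : ndarray
        Strictly positive generalized singular values, length N, ordered so
        that ``sigma1/sigma2`` is non-increasing.
    V : ndarray
        Shared invertible right factor (N x N); rows of ``V.T`` are the shared
        basis vectors, scaled to unit Euclidean norm.
    theta : ndarray
        Angular distances ``arctan(sigma1/sigma2) - pi/4``, length N.
    """

    U1: np.ndarray
    U2: np.ndarray
    sigma1: np.ndarray
    sigma2: np.ndarray
    V: np.ndarray
    theta: np.ndarray

    @property
    def ratios(self) -> np.ndarray:
        """Generalized singular value ratios ``sigma1 / sigma2``."""
        return self.sigma1 / self.sigma2

    def reconstruct(self, which: int) -> np.ndarray:
        """Rebuild input ``which`` (1 or 2) as ``U_i @ diag(sigma_i) @ V.T``."""
        if which == 1:
            return (self.U1 * self.sigma1) @ self.V.T
        if which == 2:
            return (self.U2 * self.sigma2) @ self.V.T
        raise ValueError("which must be 1 or 2")


def _check_full_column_rank(D: np.ndarray, name: str) -> None:
    s = linalg.svdvals(D)
    tol = max(D.shape) * np.finfo(D.dtype).eps * (s[0] if s.size else 0.0)
    rank = int(np.sum(s > tol))
    if rank < D.shape[1]:
        raise RankDeficiencyError(
            f"{name} is numerically rank-deficient: numerical rank {rank} < "
            f"{D.shape[1]} columns (tolerance {tol:.3e})"
        )


def matrix_gsvd(D1: np.ndarray, D2: np.ndarray) -> MatrixGSVD:
    """GSVD of two full-column-rank matrices sharing their column dimension.

    Implemented via a thin QR of the stacked matrix ``[D1; D2]`` followed by a
    cosine-sine decomposition of the partitioned orthonormal factor (the SVD of
    the top block supplies the cosines; the sines come from the column norms of
    the rotated bottom block), so that internally ``sigma1**2 + sigma2**2 = 1``
    before the rows of ``V.T`` are rescaled to unit norm.  This avoids forming
    the normal matrices ``D_i.T @ D_i``.

    Raises
    ------
    ValueError
        If the column dimensions differ or inputs are not 2-D.
    RankDeficiencyError
        If either input is numerically rank-deficient, naming the input.
    """
    D1 = np.asarray(D1, dtype=float)
    D2 = np.asarray(D2, dtype=float)
    if D1.ndim != 2 or D2.ndim != 2:
        raise ValueError("inputs must be 2-D matrices")
    if D1.shape[1] != D2.shape[1]:
        raise ValueError(
            f"column dimension mismatch: D1 has {D1.shape[1]} columns, "
            f"D2 has {D2.shape[1]}"
        )
    n = D1.shape[1]
    if D1.shape[0] < n or D2.shape[0] < n:
        raise ValueError("each input needs at least as many rows as columns")
    if not (np.isfinite(D1).all() and np.isfinite(D2).all()):
        raise ValueError("inputs must be finite")
    _check_full_column_rank(D1, "D1")
    _check_full_column_rank(D2, "D2")

    k1 = D1.shape[0]
    Q, Rz = linalg.qr(np.vstack([D1, D2]), mode="economic")
    Q1, Q2 = Q[:k1], Q[k1:]

    # CS step: Q1 = U1 diag(c) Wt with c descending; then Q2 @ Wt.T has
    # orthogonal columns of norm s, s**2 = 1 - c**2.
    U1, c, Wt = linalg.svd(Q1, full_matrices=False)
    c = np.clip(c, 0.0, 1.0)
    B = Q2 @ Wt.T
    s = np.linalg.norm(B, axis=0)
    if np.any(s <= 0):
        raise RankDeficiencyError(
            "D2 has numerically zero generalized singular values "
            "(rank-deficient on the shared subspace)"
        )
    U2 = B / s

    Vt = Wt @ Rz
    # Unit-norm rows of V.T, scale absorbed equally into both sigmas.
    rho = np.linalg.norm(Vt, axis=1)
    Vt = Vt / rho[:, None]
    sigma1 = c * rho
    sigma2 = s * rho
    if np.any(sigma1 <= 0) or np.any(sigma2 <= 0):
        raise RankDeficiencyError(
            "an input is rank-deficient: a generalized singular value "
            "vanished numerically"
        )

    # Order by decreasing sigma1/sigma2; stable so tied (degenerate) blocks
    # keep their pre-sort order.
    order = np.argsort(-sigma1 / sigma2, kind="stable")
    U1, U2 = U1[:, order], U2[:, order]
    sigma1, sigma2 = sigma1[order], sigma2[order]
    Vt = Vt[order]

    # Sign convention: the largest-magnitude entry of each row of V.T is
    # positive; compensating flips go into the U columns.
    for a in range(n):
        j = int(np.argmax(np.abs(Vt[a])))
        if Vt[a, j] < 0:
            Vt[a] = -Vt[a]
            U1[:, a] = -U1[:, a]
            U2[:, a] = -U2[:, a]

    theta = angular_distances(sigma1, sigma2)
    return MatrixGSVD(U1=U1, U2=U2, sigma1=sigma1, sigma2=sigma2, V=Vt.T, theta=theta)


def angular_distances(sigma1: np.ndarray, sigma2: np.ndarray) -> np.ndarray:
    """Angular distances ``arctan(sigma1/sigma2) - pi/4`` in ``[-pi/4, pi/4]``.

    Antisymmetric in the two datasets: swapping the arguments negates the
    result.  Requires strictly positive entries of equal length.
    """
    s1 = np.asarray(sigma1, dtype=float)
    s2 = np.asarray(sigma2, dtype=float)
    if s1.shape != s2.shape:
        raise ValueError("sigma vectors must have equal length")
    if np.any(s1 <= 0) or np.any(s2 <= 0):
        raise ValueError("generalized singular values must be strictly positive")
    return np.arctan2(s1, s2) - _QUARTER_PI


def gsvd_eigen_oracle(D1: np.ndarray, D2: np.ndarray) -> np.ndarray:
    """Generalized singular value ratios from the normal-equations pencil.

    Solves ``D1.T D1 v = lambda D2.T D2 v``; the sorted ``sqrt(lambda)`` equal
    the ``sigma1/sigma2`` ratios of :func:`matrix_gsvd` (descending).  This is
    a numerically cruder but independent route, intended as a test oracle.
    """
    D1 = np.asarray(D1, dtype=float)
    D2 = np.asarray(D2, dtype=float)
    if D1.shape[1] != D2.shape[1]:
        raise ValueError("column dimension mismatch")
    _check_full_column_rank(D1, "D1")
    _check_full_column_rank(D2, "D2")
    lam = linalg.eigh(D1.T @ D1, D2.T @ D2, eigvals_only=True)
    lam = np.clip(lam, 0.0, None)
    return np.sqrt(lam)[::-1]
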