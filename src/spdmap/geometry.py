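"""Affine-invariant Riemannian geometry of symmetric positive definite matrices.

Full-rank functional connectivity (correlation) matrices are symmetric
positive definite (SPD) and live on a smooth manifold -- a convex half-cone
inside the vector space of symmetric matrices.  The affine-invariant metric
endows this cone with the geodesic distance

    d(A, B) = || log(A^{-1/2} B A^{-1/2}) ||_F
            = sqrt( sum_i log^2 sigma_i ),   sigma_i = eigvals(A^{-1} B),

which is invariant under congruence A -> X A X^T by any invertible X, and
under joint inversion.  Matrices with non-positive eigenvalues are infinitely
far from every SPD matrix, which matches the intuition that they are not
valid full-rank correlation matrices.

This module provides the distance, the matrix-function primitives it needs
(all through symmetric eigendecomposition), and the Frechet (Karcher) mean
under both the Euclidean and the Riemannian metric.
"""

from __future__ import annotations

import numpy as np
import scipy.linalg

from .exceptions import ConvergenceError, DimensionError, NotSPDError, SymmetryError

__all__ = [
    "sym_eig",
    "spd_power",
    "spd_log",
    "sym_exp",
    "riemannian_distance",
    "euclidean_distance",
    "frechet_mean_riemannian",
    "frechet_mean_euclidean",
    "assert_spd",
    "spd_floor",
]

#: relative symmetry tolerance: max |A - A.T| <= SYM_RTOL * max |A|
SYM_RTOL = 1e-10


def spd_floor(A: np.ndarray) -> float:
    """Relative positivity floor for ``A``: ``1e-10 * trace(A) / M``.

    Scale-free, hence tolerant of badly conditioned correlation matrices.
    Guarded from below so that matrices with non-positive trace still get a
    strictly positive floor.
    """
    A = np.asarray(A, dtype=float)
    m = A.shape[0]
    rel = 1e-10 * float(np.trace(A)) / m
    guard = 1e-12 * max(float(np.max(np.abs(A))), 1.0) if A.size else 1e-12
    return max(rel, guard * 1e-2, 1e-300)


def _as_square(A, name="matrix") -> np.ndarray:
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise DimensionError(f"{name} must be square, got shape {A.shape}")
    return A


def check_symmetric(A, name="matrix") -> np.ndarray:
    """Validate symmetry within ``SYM_RTOL`` and return ``A`` as float array."""
    A = _as_square(A, name)
    scale = float(np.max(np.abs(A))) if A.size else 0.0
    asym = float(np.max(np.abs(A - A.T))) if A.size else 0.0
    if asym > SYM_RTOL * max(scale, 1e-300):
        raise SymmetryError(
            f"{name} is not symmetric: max |A_ij - A_ji| = {asym:.3e} "
            f"(tolerance {SYM_RTOL * scale:.3e})"
        )
    return A


def _fix_signs(U: np.ndarray) -> np.ndarray:
    """Fix each eigenvector's sign so its largest-magnitude entry is positive.

    Ties in magnitude resolve to the first such entry (argmax convention).
    Makes the eigenbasis -- and hence every fitted rotation -- reproducible.
    """
    idx = np.argmax(np.abs(U), axis=0)
    signs = np.sign(U[idx, np.arange(U.shape[1])])
    signs[signs == 0] = 1.0
    return U * signs


def sym_eig(A):
    """Eigendecomposition of a symmetric matrix.

    Returns ``(w, U)`` with eigenvalues ``w`` ascending and columns of ``U``
    orthonormal, sign-fixed so ``A = U diag(w) U.T``.
    """
    A = check_symmetric(A)
    w, U = scipy.linalg.eigh(A)
    return w, _fix_signs(U)


def _eig_spd(A, name="matrix"):
    """Eigendecomposition that additionally enforces positive definiteness."""
    w, U = sym_eig(A)
    floor = spd_floor(A)
    if w[0] <= floor:
        raise NotSPDError(
            f"{name} is not SPD: smallest eigenvalue {w[0]:.3e} <= floor {floor:.3e}"
        )
    return w, U


def spd_power(A, p: float) -> np.ndarray:
    """Matrix power ``A^p`` of an SPD matrix via eigendecomposition."""
    w, U = _eig_spd(A)
    return (U * w**p) @ U.T


def spd_log(A) -> np.ndarray:
    """Matrix logarithm of an SPD matrix (a symmetric matrix)."""
    w, U = _eig_spd(A)
    return (U * np.log(w)) @ U.T


def sym_exp(X) -> np.ndarray:
    """Matrix exponential of a symmetric matrix (an SPD matrix)."""
    w, U = sym_eig(X)
    return (U * np.exp(w)) @ U.T


def euclidean_distance(A, B) -> float:
    """Frobenius distance ``||A - B||_F`` between symmetric matrices."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape:
        raise DimensionError(f"shape mismatch: {A.shape} vs {B.shape}")
    return float(np.linalg.norm(A - B))


def riemannian_distance(A, B) -> float:
    """Affine-invariant geodesic distance between SPD matrices.

    ``d = sqrt(Tr log^2 (A^{-1/2} B A^{-1/2}))``, computed from the
    generalized eigenvalues of the pencil (B, A) which equal the eigenvalues
    of ``A^{-1} B``.
    """
    A = check_symmetric(A, "A")
    B = check_symmetric(B, "B")
    if A.shape != B.shape:
        raise DimensionError(f"shape mismatch: {A.shape} vs {B.shape}")
    try:
        sigma = scipy.linalg.eigh(B, A, eigvals_only=True)
    except scipy.linalg.LinAlgError as exc:  # Cholesky of A failed
        raise NotSPDError(f"first argument is not SPD: {exc}") from exc
    if sigma[0] <= 0.0:
        raise NotSPDError(
            f"second argument is not SPD: smallest generalized eigenvalue {sigma[0]:.3e}"
        )
    return float(np.sqrt(np.sum(np.log(sigma) ** 2)))


def frechet_mean_euclidean(Fs) -> np.ndarray:
    """Arithmetic mean of a nonempty list of symmetric matrices.

    Minimizes the summed squared Frobenius distance to the set.
    """
    Fs = [np.asarray(F, dtype=float) for F in Fs]
    if not Fs:
        raise ValueError("cannot average an empty list of matrices")
    return np.mean(np.stack(Fs), axis=0)


def frechet_mean_riemannian(Fs, tol: float = 1e-8, max_iter: int = 200,
                            return_info: bool = False):
    """Frechet (Karcher) mean of SPD matrices under the affine-invariant metric.

    Iterates the fixed-point scheme

        Fbar <- Fbar^{1/2} exp( (1/K) sum_k log(Fbar^{-1/2} F_k Fbar^{-1/2}) ) Fbar^{1/2}

    from the arithmetic mean (always SPD for SPD inputs) until the Frobenius
    norm of the averaged tangent term -- the Riemannian gradient up to scale
    -- drops below ``tol``.  The fixed point is the unique minimizer of
    ``sum_k d^2(Fbar, F_k)``.

    With ``return_info=True`` also returns a dict with per-iteration gradient
    norms and objective values (sum of squared distances).
    """
    Fs = [check_symmetric(F, f"F[{i}]") for i, F in enumerate(Fs)]
    if not Fs:
        raise ValueError("cannot average an empty list of matrices")
    K = len(Fs)
    Fbar = frechet_mean_euclidean(Fs)
    info = {"grad_norms": [], "objective": []} if return_info else None
    gnorm = np.inf
    for _ in range(max_iter):
        w, U = _eig_spd(Fbar, "current mean iterate")
        P = (U * w**-0.5) @ U.T    # Fbar^{-1/2}
        Ph = (U * w**0.5) @ U.T    # Fbar^{+1/2}
        logs = [spd_log(P @ F @ P) for F in Fs]
        T = sum(logs) / K
        T = 0.5 * (T + T.T)  # exact symmetry despite matmul roundoff
        gnorm = float(np.linalg.norm(T))
        if return_info:
            info["grad_norms"].append(gnorm)
            info["objective"].append(float(sum(np.sum(L**2) for L in logs)))
        if gnorm <= tol:
            return (Fbar, info) if return_info else Fbar
        Fbar = Ph @ sym_exp(T) @ Ph
        Fbar = 0.5 * (Fbar + Fbar.T)  # kill roundoff drift
    raise ConvergenceError(
        f"Frechet mean did not converge in {max_iter} iterations "
        f"(last gradient norm {gnorm:.3e})",
        gradient_norm=gnorm,
    )


def assert_spd(A, repair: bool = False):
    """Validate (or repair) positive definiteness of a symmetric matrix.

    Returns ``(A_spd, clipped_mass)``.  Without ``repair`` a matrix with an
    eigenvalue at or below the relative floor raises :class:`NotSPDError`
    and ``clipped_mass`` is 0 for matrices that pass.  With ``repair``,
    eigenvalues are clipped up to the floor, the matrix reconstructed, and
    ``clipped_mass`` reports the total eigenvalue mass moved.
    """
    A = check_symmetric(A)
    w, U = sym_eig(A)
    floor = spd_floor(A)
    if w[0] > floor:
        return A, 0.0
    if not repair:
        raise NotSPDError(
            f"matrix is not SPD: smallest eigenvalue {w[0]:.3e} <= floor {floor:.3e}"
        )
    clipped = np.maximum(floor - w, 0.0)
    w_rep = np.maximum(w, floor)
    return (U * w_rep) @ U.T, float(np.sum(clipped))
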