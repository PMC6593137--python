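"""Primitives on the manifold of symmetric positive definite matrices.

Trial covariance matrices live on the SPD manifold; the affine-invariant
metric ``d(A, B) = ||log(A^{-1/2} B A^{-1/2})||_F`` makes classifiers built
on it immune to invertible linear channel mixings.  This module provides the
metric, the Fréchet (geometric) mean via the standard fixed-point iteration,
and the tangent-space chart used to feed SPD features to linear classifiers.
"""

from __future__ import annotations

import numpy as np
from scipy import linalg


def check_spd(A: np.ndarray, name: str = "matrix", tol: float = 1e-10
              ) -> np.ndarray:
    """Validate symmetry and positive definiteness; returns ``A`` as float."""
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError(f"{name} must be square")
    if np.max(np.abs(A - A.T)) > tol * max(1.0, np.max(np.abs(A))):
        raise ValueError(f"{name} is not symmetric")
    w = np.linalg.eigvalsh(A)
    if w.min() <= 0:
        raise ValueError(
            f"{name} is not positive definite (min eigenvalue {w.min():.3g})")
    return A


def _eig_fun(A: np.ndarray, fun) -> np.ndarray:
    """Apply a scalar function to the eigenvalues of a symmetric matrix."""
    w, v = np.linalg.eigh(A)
    return (v * fun(w)) @ v.T


def sqrtm(A: np.ndarray) -> np.ndarray:
    return _eig_fun(A, np.sqrt)


def invsqrtm(A: np.ndarray) -> np.ndarray:
    return _eig_fun(A, lambda w: 1.0 / np.sqrt(w))


def logm(A: np.ndarray) -> np.ndarray:
    return _eig_fun(A, np.log)


def expm(A: np.ndarray) -> np.ndarray:
    return _eig_fun(A, np.exp)


def riemann_distance(A: np.ndarray, B: np.ndarray) -> float:
    """Affine-invariant geodesic distance between two SPD matrices."""
    A = check_spd(A, "A")
    B = check_spd(B, "B")
    isa = invsqrtm(A)
    # eigenvalues of A^-1/2 B A^-1/2; distance is the norm of their logs
    w = np.linalg.eigvalsh(isa @ B @ isa)
    return float(np.sqrt(np.sum(np.log(w) ** 2)))


def riemann_mean(matrices, tol: float = 1e-8, max_iter: int = 200,
                 validate: bool = True) -> np.ndarray:
    """Fréchet mean under the affine-invariant metric.

    Fixed-point iteration ``M <- M^{1/2} exp(mean_i log(M^{-1/2} C_i
    M^{-1/2})) M^{1/2}`` initialized at the arithmetic mean; converged when
    the Frobenius norm of the tangent-space mean drops below ``tol``.
    """
    mats = np.asarray(matrices, dtype=float)
    if mats.ndim == 2:
        mats = mats[None]
    if mats.shape[0] == 0:
        raise ValueError("cannot average an empty set of matrices")
    if validate:
        for i, C in enumerate(mats):
            check_spd(C, f"matrix {i}")
    if mats.shape[0] == 1:
        return mats[0].copy()
    M = mats.mean(axis=0)
    for _ in range(max_iter):
        ms = sqrtm(M)
        ims = invsqrtm(M)
        T = np.mean([logm(ims @ C @ ims) for C in mats], axis=0)
        T = (T + T.T) / 2.0
        norm = np.linalg.norm(T, "fro")
        M = ms @ expm(T) @ ms
        M = (M + M.T) / 2.0
        if norm < tol:
            return M
    raise RuntimeError(
        f"Riemannian mean did not converge in {max_iter} iterations "
        f"(last tangent norm {norm:.3g}); consider raising max_iter or "
        f"regularizing the matrices")


_SQRT2 = np.sqrt(2.0)


def tangent_project(matrices, reference: np.ndarray) -> np.ndarray:
    """Project SPD matrices to the tangent space at ``reference``.

    Each matrix maps to the vectorized upper triangle of
    ``log(M^{-1/2} C M^{-1/2})`` with off-diagonal entries weighted by
    sqrt(2), so the Euclidean norm of a vector equals the geodesic distance
    from the reference; dimension is n(n+1)/2.
    """
    ref = check_spd(reference, "reference")
    mats = np.asarray(matrices, dtype=float)
    single = mats.ndim == 2
    if single:
        mats = mats[None]
    ims = invsqrtm(ref)
    n = ref.shape[0]
    iu = np.triu_indices(n)
    weights = np.where(iu[0] == iu[1], 1.0, _SQRT2)
    out = np.empty((mats.shape[0], n * (n + 1) // 2))
    for i, C in enumerate(mats):
        S = logm(ims @ C @ ims)
        out[i] = S[iu] * weights
    return out[0] if single else out


def untangent_project(vectors, reference: np.ndarray) -> np.ndarray:
    """Inverse of :func:`tangent_project` (maps vectors back to SPD)."""
    ref = check_spd(reference, "reference")
    vecs = np.asarray(vectors, dtype=float)
    single = vecs.ndim == 1
    if single:
        vecs = vecs[None]
    ms = sqrtm(ref)
    n = ref.shape[0]
    iu = np.triu_indices(n)
    weights = np.where(iu[0] == iu[1], 1.0, 1.0 / _SQRT2)
    out = np.empty((vecs.shape[0], n, n))
    for i, v in enumerate(vecs):
        S = np.zeros((n, n))
        S[iu] = v * weights
        S = S + S.T - np.diag(np.diag(S))
        out[i] = ms @ expm(S) @ ms
    return out[0] if single else out


def geometric_mean_two(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Geodesic midpoint A #_{1/2} B = A^{1/2} (A^{-1/2} B A^{-1/2})^{1/2} A^{1/2}."""
    sa, isa = sqrtm(A), invsqrtm(A)
    return sa @ sqrtm(isa @ B @ isa) @ sa
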