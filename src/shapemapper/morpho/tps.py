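"""Thin-plate splines and bending energy.

The interpolating spline maps a set of control points exactly onto their
targets while minimising a quadratic roughness functional. Kernels:
U(r) = r^2 log r in 2D and U(r) = -r in 3D. The 3D sign is chosen so the
kernel is conditionally positive definite on the subspace orthogonal to
affine maps, which makes the bending energy (and the bending-energy matrix)
nonnegative without any post-hoc correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["TpsModel", "tps_fit", "bending_energy_matrix"]


def _kernel(r: np.ndarray, d: int) -> np.ndarray:
    if d == 2:
        out = np.zeros_like(r)
        mask = r > 0
        rm = r[mask]
        out[mask] = rm * rm * np.log(rm)
        return out
    return -r


def _kernel_matrix(a: np.ndarray, b: np.ndarray, d: int) -> np.ndarray:
    r = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)
    return _kernel(r, d)


@dataclass
class TpsModel:
    """Fitted interpolating spline from ``source`` to ``target`` control points.

    ``weights`` (k x d) are the kernel coefficients, ``affine`` ((d+1) x d)
    the affine part (row 0 = translation). The kernel weights satisfy
    Q^t w = 0 with Q = [1 | source], i.e. they are orthogonal to the affine
    subspace, and ``bending_energy = sum_dim w_dim^t K w_dim >= 0``.
    """

    source: np.ndarray
    target: np.ndarray
    weights: np.ndarray
    affine: np.ndarray
    bending_energy: float

    def __call__(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        d = self.source.shape[1]
        U = _kernel_matrix(pts, self.source, d)
        q = np.hstack([np.ones((len(pts), 1)), pts])
        return U @ self.weights + q @ self.affine


def tps_fit(source: np.ndarray, target: np.ndarray) -> TpsModel:
    """Fit the interpolating thin-plate spline source -> target.

    Requires at least d+1 control points in general position (non-collinear
    in 2D, non-coplanar in 3D); a singular system raises ``ValueError``.
    """
    src = np.asarray(source, dtype=float)
    tgt = np.asarray(target, dtype=float)
    if src.ndim != 2 or src.shape != tgt.shape:
        raise ValueError("source and target must be matching k x d matrices")
    k, d = src.shape
    if d not in (2, 3):
        raise ValueError("d must be 2 or 3")
    if k < d + 1:
        raise ValueError(f"need at least {d + 1} control points")

    K = _kernel_matrix(src, src, d)
    Q = np.hstack([np.ones((k, 1)), src])
    L = np.zeros((k + d + 1, k + d + 1))
    L[:k, :k] = K
    L[:k, k:] = Q
    L[k:, :k] = Q.T
    rhs = np.zeros((k + d + 1, d))
    rhs[:k] = tgt

    # guard against degenerate control points (collinear / coplanar)
    if np.linalg.matrix_rank(Q, tol=1e-10 * max(1.0, np.abs(src).max())) < d + 1:
        raise ValueError("control points are degenerate (collinear or coplanar)")
    try:
        sol = np.linalg.solve(L, rhs)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - rank check above
        raise ValueError("singular TPS system") from exc

    w = sol[:k]
    a = sol[k:]
    be = float(np.einsum("id,ij,jd->", w, K, w))
    be = max(be, 0.0)
    return TpsModel(source=src, target=tgt, weights=w, affine=a, bending_energy=be)


def bending_energy_matrix(reference: np.ndarray) -> np.ndarray:
    """Bending-energy matrix L_b of a reference configuration.

    The upper-left k x k block of the inverse TPS system. For a displacement
    field with per-coordinate columns y, the bending energy is
    ``sum_dim y_dim^t L_b y_dim``. L_b is symmetric PSD, its rows sum to
    zero, and it annihilates every affine displacement of the reference.
    """
    src = np.asarray(reference, dtype=float)
    k, d = src.shape
    K = _kernel_matrix(src, src, d)
    Q = np.hstack([np.ones((k, 1)), src])
    if np.linalg.matrix_rank(Q, tol=1e-10 * max(1.0, np.abs(src).max())) < d + 1:
        raise ValueError("degenerate reference configuration")
    L = np.zeros((k + d + 1, k + d + 1))
    L[:k, :k] = K
    L[:k, k:] = Q
    L[k:, :k] = Q.T
    Lb = np.linalg.inv(L)[:k, :k]
    return 0.5 * (Lb + Lb.T)
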