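"""Generalized Procrustes analysis and shape-space principal components.

Superimposition removes translation, scale and rotation (no reflection) from
a sample of landmark configurations, leaving Procrustes shape coordinates.
The analysis is the iterative scheme of Gower: align every configuration to
the current consensus by orthogonal Procrustes rotation, update the
consensus, repeat until it stabilises.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .base import LandmarkConfig, LandmarkSample

__all__ = [
    "GPAResult",
    "centroid_size",
    "gpa",
    "procrustes_distance",
    "pca_reduce",
    "PcaResult",
]


def centroid_size(coords) -> float:
    """Square root of summed squared distances of landmarks to their centroid."""
    if isinstance(coords, LandmarkConfig):
        coords = coords.coords
    x = np.asarray(coords, dtype=float)
    c = x - x.mean(axis=0)
    return float(np.sqrt((c**2).sum()))


def _optimal_rotation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Proper rotation R minimising ||a R - b||_F (reflections excluded)."""
    u, _, vt = np.linalg.svd(a.T @ b)
    r = u @ vt
    if np.linalg.det(r) < 0:
        u[:, -1] = -u[:, -1]
        r = u @ vt
    return r


@dataclass
class GPAResult:
    aligned: LandmarkSample
    mean_shape: np.ndarray
    centroid_sizes: np.ndarray
    converged: bool
    iterations: int


def gpa(
    sample: LandmarkSample,
    scale: bool = True,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> GPAResult:
    """Full generalized Procrustes superimposition of a landmark sample.

    Each configuration is centered, scaled to unit centroid size (when
    ``scale``), and rotated to the consensus; the consensus is the
    renormalised average of the aligned configurations. Iteration stops when
    the consensus moves by less than ``tol`` (RMS) or after ``max_iter``
    rounds (the best alignment so far is returned with ``converged=False``).
    """
    x = sample.coords.copy()
    n, k, d = x.shape
    if n < 2:
        raise ValueError("GPA needs at least two configurations")

    sizes = np.empty(n)
    for i in range(n):
        x[i] -= x[i].mean(axis=0)
        cs = np.sqrt((x[i] ** 2).sum())
        if cs == 0:
            raise ValueError(f"degenerate configuration at index {i}")
        sizes[i] = cs
        if scale:
            x[i] /= cs

    mean = x[0].copy()
    mean /= np.sqrt((mean**2).sum())
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        for i in range(n):
            x[i] = x[i] @ _optimal_rotation(x[i], mean)
        new_mean = x.mean(axis=0)
        new_mean -= new_mean.mean(axis=0)
        new_mean /= np.sqrt((new_mean**2).sum())
        # align new consensus to old so the convergence test is rotation-free
        new_mean = new_mean @ _optimal_rotation(new_mean, mean)
        delta = np.sqrt(((new_mean - mean) ** 2).mean())
        mean = new_mean
        if delta < tol:
            converged = True
            break

    aligned = LandmarkSample(
        coords=x, ids=sample.ids, labels=sample.labels, fixed_mask=sample.fixed_mask
    )
    return GPAResult(
        aligned=aligned,
        mean_shape=mean,
        centroid_sizes=sizes,
        converged=converged,
        iterations=it,
    )


def procrustes_distance(a, b) -> float:
    """Partial Procrustes distance between two configurations.

    Both are centered and scaled to unit centroid size, the second is rotated
    onto the first, and the root summed squared coordinate difference is
    returned. Symmetric; zero iff the two have the same shape.
    """
    xa = a.coords if isinstance(a, LandmarkConfig) else np.asarray(a, dtype=float)
    xb = b.coords if isinstance(b, LandmarkConfig) else np.asarray(b, dtype=float)
    if xa.shape != xb.shape:
        raise ValueError("configurations must share (k, d)")
    xa = xa - xa.mean(axis=0)
    xb = xb - xb.mean(axis=0)
    na, nb = np.sqrt((xa**2).sum()), np.sqrt((xb**2).sum())
    if na == 0 or nb == 0:
        raise ValueError("degenerate configuration")
    xa /= na
    xb /= nb
    xb = xb @ _optimal_rotation(xb, xa)
    return float(np.sqrt(((xa - xb) ** 2).sum()))


@dataclass
class PcaResult:
    scores: np.ndarray  # n x r
    basis: np.ndarray  # q x r, orthonormal columns
    eigenvalues: np.ndarray  # all nonzero eigenvalues, descending
    mean: np.ndarray  # q
    retained: int


def pca_reduce(gpa_result: GPAResult, variance_fraction: float = 0.95) -> PcaResult:
    """Principal components of the aligned coordinates.

    Eigendecomposition of the covariance of the vectorized Procrustes
    coordinates; the smallest leading set of components whose cumulative
    variance reaches ``variance_fraction`` is retained. The basis is
    orthonormal, so reconstruction error equals the discarded eigenvalue sum.
    """
    if not 0 < variance_fraction <= 1:
        raise ValueError("variance_fraction must be in (0, 1]")
    y = gpa_result.aligned.vectorized()
    n, q = y.shape
    mean = y.mean(axis=0)
    yc = y - mean
    u, s, vt = np.linalg.svd(yc, full_matrices=False)
    eig = s**2 / (n - 1)
    nonzero = eig > max(eig[0], 1.0) * 1e-12 if eig.size else np.zeros(0, bool)
    eig = eig[nonzero]
    vt = vt[nonzero]
    u = u[:, nonzero]
    s = s[nonzero]
    cum = np.cumsum(eig) / eig.sum()
    r = int(np.searchsorted(cum, variance_fraction - 1e-12) + 1)
    r = min(r, len(eig))
    basis = vt[:r].T
    scores = u[:, :r] * s[:r]
    return PcaResult(scores=scores, basis=basis, eigenvalues=eig, mean=mean, retained=r)
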