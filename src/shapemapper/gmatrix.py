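"""QTL-based genetic covariance matrices and their comparison.

The additive genetic covariance implied by a fitted multiple-QTL model is
G = B' C B, with B the QTL-by-trait effect matrix and C the covariance of
the QTL dosages (I/4 for unlinked backcross loci; estimated empirically from
the expected dosages to capture linkage). Matrices are compared by the root
Euclidean distance between their symmetric square roots, the angle between
leading eigenvectors against a random-vector null, the Krzanowski common
subspace, and the spectrum of G P^- (multivariate heritability).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .qtl import QtlModelFit
from .genoprob import GenoProb, dosage as _dosage

__all__ = [
    "CovMatrix",
    "SubspaceResult",
    "qtl_G",
    "phenotypic_P",
    "matrix_sqrt_psd",
    "root_euclidean_distance",
    "gmax_angle_test",
    "krzanowski_subspace",
    "multivariate_heritability",
]


@dataclass
class CovMatrix:
    """A symmetric PSD genetic (G) or phenotypic (P) covariance of coordinates."""

    matrix: np.ndarray
    labels: list[str]
    kind: str = "G"

    def __post_init__(self):
        A = np.asarray(self.matrix, dtype=float)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("matrix must be square")
        if not np.allclose(A, A.T, atol=1e-10 * max(1.0, np.abs(A).max())):
            raise ValueError("matrix must be symmetric")
        if len(self.labels) != A.shape[0]:
            raise ValueError("labels do not match matrix dimension")
        self.matrix = 0.5 * (A + A.T)

    @property
    def m(self) -> int:
        return self.matrix.shape[0]

    def subset(self, labels: list[str]) -> "CovMatrix":
        idx = [self.labels.index(l) for l in labels]
        return CovMatrix(self.matrix[np.ix_(idx, idx)], labels=list(labels), kind=self.kind)


def qtl_G(
    fit: QtlModelFit,
    probs: GenoProb,
    labels: list[str],
    subset: list[str] | None = None,
    dosage_cov: str = "empirical",
) -> CovMatrix:
    """Additive genetic covariance implied by the fitted QTL model.

    G = B' C B with C the covariance of expected dosages at the fitted
    positions -- estimated from the genotype probabilities
    (``dosage_cov='empirical'``, capturing linkage between same-chromosome
    QTL) or the unlinked backcross closed form I/4. Subsetting to a label
    subset commutes with construction.
    """
    if fit.n_qtl == 0:
        raise ValueError("model has no QTL")
    B = fit.B
    if dosage_cov == "empirical":
        D = np.column_stack([_dosage(probs, c, p) for c, p in fit.positions()])
        C = np.cov(D, rowvar=False)
        C = np.atleast_2d(C)
    elif dosage_cov == "unlinked":
        C = np.eye(fit.n_qtl) / 4.0
    else:
        raise ValueError("dosage_cov must be 'empirical' or 'unlinked'")
    G = B.T @ C @ B
    out = CovMatrix(0.5 * (G + G.T), labels=list(labels), kind="G")
    if subset is not None:
        out = out.subset(subset)
    return out


def phenotypic_P(
    Y: np.ndarray,
    labels: list[str],
    covariates=None,
    covariate_columns=None,
) -> CovMatrix:
    """Phenotypic covariance of shape coordinates.

    When covariates are given the covariance is taken over the residuals of
    the covariate fit (consistent with the mapping model); otherwise the raw
    centered covariance.
    """
    from .qtl import COVARIATE_COLUMNS, build_design, _residualize

    Y = np.asarray(Y, dtype=float)
    if covariates is not None:
        X = build_design(covariates, covariate_columns or COVARIATE_COLUMNS)
        R = _residualize(Y, X)
        P = R.T @ R / (len(Y) - X.shape[1])
    else:
        Yc = Y - Y.mean(axis=0)
        P = Yc.T @ Yc / (len(Y) - 1)
    return CovMatrix(P, labels=list(labels), kind="P")


def _as_matrix(A) -> np.ndarray:
    return A.matrix if isinstance(A, CovMatrix) else np.asarray(A, dtype=float)


def matrix_sqrt_psd(A) -> np.ndarray:
    """Symmetric PSD square root via the spectral decomposition.

    Negative eigenvalues within noise of zero are clipped at 0.
    """
    M = _as_matrix(A)
    if not np.allclose(M, M.T, atol=1e-8 * max(1.0, np.abs(M).max())):
        raise ValueError("matrix must be symmetric")
    w, v = np.linalg.eigh(0.5 * (M + M.T))
    w = np.clip(w, 0.0, None)
    return (v * np.sqrt(w)) @ v.T


def root_euclidean_distance(G1, G2) -> float:
    """d_H(G1, G2) = Frobenius norm of the difference of matrix square roots."""
    A, B = _as_matrix(G1), _as_matrix(G2)
    if A.shape != B.shape:
        raise ValueError("dimension mismatch")
    if isinstance(G1, CovMatrix) and isinstance(G2, CovMatrix) and G1.labels != G2.labels:
        raise ValueError("coordinate labels differ")
    return float(np.linalg.norm(matrix_sqrt_psd(A) - matrix_sqrt_psd(B)))


def _folded_angle(u: np.ndarray, v: np.ndarray) -> float:
    c = abs(float(u @ v) / (np.linalg.norm(u) * np.linalg.norm(v)))
    return float(np.degrees(np.arccos(min(c, 1.0))))


def gmax_angle_test(G1, G2, n_random: int = 100_000, seed: int = 0):
    """Angle between leading eigenvectors, against a random-vector null.

    Axes are sign-free, so the angle is folded to [0, 90] degrees. The
    p-value is the fraction of ``n_random`` pairs of independent uniformly
    distributed directions (Gaussian normalized) whose folded angle is at
    most the observed one -- small p means the two gmax are more aligned
    than random directions. Ties in the leading eigenvalue are reported via
    the returned multiplicity (angle computed with the first eigenvector,
    flagged for interpretation within the leading eigenspace).
    """
    A, B = _as_matrix(G1), _as_matrix(G2)
    if not (np.any(A) and np.any(B)):
        raise ValueError("zero matrix")
    m = A.shape[0]
    wa, va = np.linalg.eigh(A)
    wb, vb = np.linalg.eigh(B)
    g1, g2 = va[:, -1], vb[:, -1]
    angle = _folded_angle(g1, g2)

    def multiplicity(w):
        return int(np.sum(w >= w[-1] * (1 - 1e-8)))

    rng = np.random.default_rng(seed)
    u = rng.standard_normal((n_random, m))
    v = rng.standard_normal((n_random, m))
    cosang = np.abs(np.einsum("ij,ij->i", u, v)) / (
        np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1)
    )
    null = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
    p = float((np.sum(null <= angle) + 1) / (n_random + 1))
    return angle, p, {"multiplicity": (multiplicity(wa), multiplicity(wb))}


@dataclass
class SubspaceResult:
    H: np.ndarray
    eigenvalues: np.ndarray  # Delta per H-axis, descending
    eigenvectors: np.ndarray  # columns
    angles: np.ndarray  # (#axes) x (#matrices), degrees
    q_used: list[int]


def krzanowski_subspace(matrices, var_fraction: float = 0.90) -> SubspaceResult:
    """Krzanowski common subspace of several covariance matrices.

    A_i holds the first q_i eigenvectors of matrix i (smallest count whose
    cumulative variance reaches ``var_fraction``); H = sum_i A_i A_i'. Each
    eigenvalue of H equals sum_i cos^2(delta_i), where delta_i is the angle
    between the H-eigenvector and the subspace spanned by A_i; the upper
    bound is the number of matrices.
    """
    if not 0 < var_fraction <= 1:
        raise ValueError("var_fraction must be in (0, 1]")
    mats = [_as_matrix(M) for M in matrices]
    if len(mats) < 2:
        raise ValueError("need at least two matrices")
    m = mats[0].shape[0]
    if any(M.shape != (m, m) for M in mats):
        raise ValueError("dimension mismatch")

    As, qs = [], []
    for M in mats:
        w, v = np.linalg.eigh(M)
        w = np.clip(w[::-1], 0.0, None)
        v = v[:, ::-1]
        cum = np.cumsum(w) / w.sum()
        q_i = int(np.searchsorted(cum, var_fraction - 1e-12) + 1)
        As.append(v[:, :q_i])
        qs.append(q_i)

    H = sum(A @ A.T for A in As)
    w, v = np.linalg.eigh(H)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]

    angles = np.empty((m, len(As)))
    for j in range(m):
        h = v[:, j]
        for i, A in enumerate(As):
            c = min(np.linalg.norm(A.T @ h), 1.0)
            angles[j, i] = np.degrees(np.arccos(c))
    return SubspaceResult(H=H, eigenvalues=w, eigenvectors=v, angles=angles, q_used=qs)


def multivariate_heritability(G, P, rank_tol: float = 1e-10):
    """Spectral decomposition of G P^- (multivariate heritability).

    P^- is the Moore-Penrose pseudoinverse with eigenvalues below
    ``rank_tol`` times the largest treated as null space. Eigenvalues of
    G P^- are heritabilities of shape directions: they are returned sorted
    descending, with imaginary parts within numerical noise discarded and
    values clipped to [0, 1] (clipping reported). Eigenvectors are the
    corresponding shape directions.
    """
    Gm, Pm = _as_matrix(G), _as_matrix(P)
    if Gm.shape != Pm.shape:
        raise ValueError("dimension mismatch")
    if not np.any(Pm):
        raise ValueError("zero P matrix")
    wp, vp = np.linalg.eigh(Pm)
    keep = wp > rank_tol * wp.max()
    Pinv = (vp[:, keep] / wp[keep]) @ vp[:, keep].T
    M = Gm @ Pinv
    w, v = np.linalg.eig(M)
    order = np.argsort(-w.real)
    w, v = w[order], v[:, order]
    clipped = int(np.sum((w.real < -1e-8) | (w.real > 1 + 1e-8)))
    vals = np.clip(w.real, 0.0, 1.0)
    return vals, v.real, {"clipped": clipped}
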