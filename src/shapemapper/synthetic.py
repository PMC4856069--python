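"""Synthetic backcross populations with planted shape QTL.

Emulates the study design this package targets: an N2 backcross genotyped at
on the order of a hundred SNPs on a cM map, phenotyped by a 3D landmark
configuration whose shape carries additive QTL effects (in Procrustes units),
covariate effects (log centroid size, sex, direction of cross) and individual
error with a configurable covariance. Everything downstream -- GPA, genotype
probabilities, the scan, the model search, G-matrix construction -- can be
exercised on these populations without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import trimesh

from .genoprob import AA, AB, MISSING, CrossData, GeneticMap, haldane

__all__ = [
    "MapSpec",
    "QtlSpec",
    "SimTruth",
    "simulate_backcross",
    "simulate_shapes",
    "make_mesh",
    "default_mean_shape",
    "isotropic_error_cov",
    "diagonal_error_cov",
    "factor_error_cov",
    "beta_norm_for_h2",
    "shape_tangent_projector",
]


@dataclass
class MapSpec:
    """Genome layout: chromosome lengths (cM) and marker spacing.

    ``chromosomes`` is a list of (name, length-cM); markers are placed every
    ``marker_spacing`` cM from 0 through the chromosome end, or at
    ``marker_positions[chrom]`` when given explicitly.
    """

    chromosomes: list[tuple[str, float]]
    marker_spacing: float = 10.0
    marker_positions: dict[str, np.ndarray] | None = None

    def __post_init__(self):
        if not self.chromosomes:
            raise ValueError("empty map")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name}: length must be > 0")
        if self.marker_positions is None and self.marker_spacing <= 0:
            raise ValueError("marker_spacing must be > 0")

    def build_map(self) -> GeneticMap:
        chroms: dict[str, tuple[list[str], np.ndarray]] = {}
        for name, length in self.chromosomes:
            if self.marker_positions is not None and name in self.marker_positions:
                pos = np.asarray(self.marker_positions[name], dtype=float)
                if np.any(pos < 0) or np.any(pos > length):
                    raise ValueError(f"chromosome {name}: marker positions off-map")
                if np.any(np.diff(pos) < 0):
                    raise ValueError(f"chromosome {name}: positions must be sorted")
            else:
                pos = np.arange(0.0, length + 1e-9, self.marker_spacing)
            names = [f"m{name}_{i + 1}" for i in range(len(pos))]
            chroms[name] = (names, pos)
        return GeneticMap(chroms)


@dataclass
class QtlSpec:
    """One planted QTL: chromosome, cM position, and additive effect vector.

    ``beta`` has length k*d and is the difference between the heterozygote and
    homozygote mean shapes in Procrustes units.
    """

    chrom: str
    pos: float
    beta: np.ndarray

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=float).ravel()
        if not np.linalg.norm(self.beta) > 0:
            raise ValueError("QTL effect must be nonzero")


@dataclass
class SimTruth:
    """Ground truth for one simulation: QTL, covariate effects, error model."""

    mean_shape: np.ndarray  # k x d
    qtls: list[QtlSpec] = field(default_factory=list)
    size_effect: np.ndarray | None = None  # per unit log centroid size
    sex_effect: np.ndarray | None = None
    direction_effect: np.ndarray | None = None
    error_cov: np.ndarray | None = None  # (k*d) x (k*d) PSD

    def __post_init__(self):
        self.mean_shape = np.asarray(self.mean_shape, dtype=float)
        k, d = self.mean_shape.shape
        q = k * d
        for name in ("size_effect", "sex_effect", "direction_effect"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float).ravel()
                if v.size != q:
                    raise ValueError(f"{name} must have length k*d={q}")
                setattr(self, name, v)
        for qtl in self.qtls:
            if qtl.beta.size != q:
                raise ValueError("QTL effect must have length k*d")
        if self.error_cov is not None:
            S = np.asarray(self.error_cov, dtype=float)
            if S.shape != (q, q):
                raise ValueError("error_cov must be (k*d) x (k*d)")
            if not np.allclose(S, S.T, atol=1e-10):
                raise ValueError("error_cov must be symmetric")
            w = np.linalg.eigvalsh(S)
            if w.min() < -1e-10 * max(w.max(), 1.0):
                raise ValueError("error_cov must be positive semidefinite")
            self.error_cov = S

    @property
    def shape_dim(self) -> tuple[int, int]:
        return self.mean_shape.shape


def isotropic_error_cov(k: int, d: int, sigma: float) -> np.ndarray:
    """Sigma_e = sigma^2 I: equal independent noise on every coordinate."""
    return sigma**2 * np.eye(k * d)


def diagonal_error_cov(variances: np.ndarray) -> np.ndarray:
    """Independent but landmark/axis-specific noise."""
    v = np.asarray(variances, dtype=float).ravel()
    if np.any(v < 0):
        raise ValueError("variances must be nonnegative")
    return np.diag(v)


def factor_error_cov(loadings: np.ndarray, unique: float) -> np.ndarray:
    """Low-rank-plus-diagonal Sigma_e = L L' + unique * I (correlated error)."""
    L = np.atleast_2d(np.asarray(loadings, dtype=float))
    if L.shape[0] < L.shape[1]:
        L = L.T
    return L @ L.T + unique * np.eye(L.shape[0])


def shape_tangent_projector(mean_shape: np.ndarray) -> np.ndarray:
    """Projector onto the shape tangent space at ``mean_shape``.

    Removes the similarity directions that superimposition absorbs --
    translations (d), uniform scaling of the mean (1) and infinitesimal
    rotations of the mean (d(d-1)/2) -- so effect vectors planted through it
    survive GPA at full magnitude. Returns a (k*d) x (k*d) symmetric
    idempotent matrix.
    """
    m = np.asarray(mean_shape, dtype=float)
    k, d = m.shape
    q = k * d
    cols = []
    for ax in range(d):  # translations
        e = np.zeros((k, d))
        e[:, ax] = 1.0
        cols.append(e.ravel())
    cols.append(m.ravel())  # scale
    for a in range(d):  # rotations
        for b in range(a + 1, d):
            A = np.zeros((d, d))
            A[a, b], A[b, a] = 1.0, -1.0
            cols.append((m @ A.T).ravel())
    Nmat = np.column_stack(cols)
    Q, _ = np.linalg.qr(Nmat)
    return np.eye(q) - Q @ Q.T


def beta_norm_for_h2(h2: float, sigma: float) -> float:
    """Effect norm giving directional heritability ``h2`` under isotropic noise.

    In a backcross the dosage variance is 1/4, so the genetic variance along
    the effect direction is ||beta||^2/4 against residual sigma^2, giving
    h2 = ||beta||^2 / (||beta||^2 + 4 sigma^2); invert for ||beta||.
    """
    if not 0 < h2 < 1:
        raise ValueError("h2 must be in (0, 1)")
    return float(2.0 * sigma * np.sqrt(h2 / (1.0 - h2)))


def simulate_backcross(
    map_spec: MapSpec,
    n: int,
    seed: int,
    geno_error: float = 0.0,
    missing_rate: float = 0.0,
) -> CrossData:
    """Simulate N2 backcross genotypes along a cM map.

    Genotypes follow a two-state Markov chain per chromosome with
    recombination fractions from the Haldane map function between adjacent
    markers (no interference) and marginal P(AB) = 1/2. Observed genotypes are
    then flipped with probability ``geno_error`` and masked with probability
    ``missing_rate``. The error-free chain is kept in the ``true_genotypes``
    attribute so phenotype simulation can condition on the truth.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    for name, rate in (("geno_error", geno_error), ("missing_rate", missing_rate)):
        if not 0 <= rate < 1:
            raise ValueError(f"{name} must be in [0, 1)")
    rng = np.random.default_rng(seed)
    gmap = map_spec.build_map()

    blocks = []
    for chrom, (names, pos) in gmap.chromosomes.items():
        m = len(pos)
        g = np.empty((n, m), dtype=np.int8)
        g[:, 0] = rng.random(n) < 0.5
        rs = haldane(np.diff(pos))
        for j in range(1, m):
            flip = rng.random(n) < rs[j - 1]
            g[:, j] = np.where(flip, 1 - g[:, j - 1], g[:, j - 1])
        blocks.append(g)
    true_geno = np.concatenate(blocks, axis=1)

    observed = true_geno.copy()
    if geno_error > 0:
        flip = rng.random(observed.shape) < geno_error
        observed = np.where(flip, 1 - observed, observed).astype(np.int8)
    if missing_rate > 0:
        mask = rng.random(observed.shape) < missing_rate
        observed[mask] = MISSING

    ids = [f"ind{i + 1:04d}" for i in range(n)]
    cross = CrossData(genetic_map=gmap, genotypes=observed, ids=ids)
    cross.true_genotypes = true_geno
    return cross


def _random_rotation(d: int, rng: np.random.Generator) -> np.ndarray:
    A = rng.standard_normal((d, d))
    Q, R = np.linalg.qr(A)
    Q *= np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


def simulate_shapes(
    cross: CrossData,
    truth: SimTruth,
    seed: int,
    desuperimpose: bool = True,
):
    """Generate landmark phenotypes for simulated genotypes.

    Each specimen's vectorized configuration is
    ``mean + logCS*beta_size + sex*beta_sex + dir*beta_dir + sum_j g_j beta_j
    + e``, ``e ~ N(0, Sigma_e)``, with ``g_j`` the true genotype (0/1) at the
    marker nearest each QTL. When ``desuperimpose`` is true, each
    configuration is then rotated by a random proper rotation, scaled by
    ``exp(logCS)`` (logCS ~ N(0, 0.08), so scales span roughly 0.85-1.18) and
    translated, so a GPA is required -- and sufficient -- to recover shape.

    Returns ``(coords, covariates)``: an n x k x d array and a DataFrame with
    ``logCS`` (log centroid size of the emitted configuration), ``sex`` and
    ``cross_direction``.
    """
    from .morpho.gpa import centroid_size

    k, d = truth.shape_dim
    q = k * d
    n = cross.n
    rng = np.random.default_rng(seed)

    true_geno = getattr(cross, "true_genotypes", None)
    if true_geno is None:
        true_geno = cross.genotypes
    gmap = cross.genetic_map

    # dosage columns at the marker nearest each QTL
    qtl_cols = []
    for qtl in truth.qtls:
        if qtl.chrom not in gmap.chromosomes:
            raise ValueError(f"QTL chromosome {qtl.chrom!r} not on the map")
        names, pos = gmap.chromosomes[qtl.chrom]
        if not pos[0] - 1e-9 <= qtl.pos <= pos[-1] + 1e-9:
            raise ValueError(f"QTL position {qtl.pos} off chromosome {qtl.chrom}")
        j = int(np.argmin(np.abs(pos - qtl.pos)))
        col = true_geno[:, cross.marker_slice(qtl.chrom)][:, j].astype(float)
        qtl_cols.append(np.where(col == MISSING, 0.5, col))

    log_cs = rng.normal(0.0, 0.08, n)
    sex = (rng.random(n) < 0.5).astype(int)
    direction = (rng.random(n) < 0.5).astype(int) + 1  # coded 1/2

    Y = np.tile(truth.mean_shape.ravel(), (n, 1))
    if truth.size_effect is not None:
        Y += np.outer(log_cs, truth.size_effect)
    if truth.sex_effect is not None:
        Y += np.outer(sex, truth.sex_effect)
    if truth.direction_effect is not None:
        Y += np.outer(direction - 1, truth.direction_effect)
    for qtl, g in zip(truth.qtls, qtl_cols):
        Y += np.outer(g, qtl.beta)
    if truth.error_cov is not None and np.any(truth.error_cov):
        L = np.linalg.cholesky(
            truth.error_cov + 1e-12 * np.trace(truth.error_cov) / q * np.eye(q)
        )
        Y += rng.standard_normal((n, q)) @ L.T

    coords = Y.reshape(n, k, d)
    if desuperimpose:
        for i in range(n):
            R = _random_rotation(d, rng)
            t = rng.uniform(-1.0, 1.0, d)
            coords[i] = np.exp(log_cs[i]) * coords[i] @ R.T + t

    measured_log_cs = np.log([centroid_size(c) for c in coords])
    covariates = pd.DataFrame(
        {
            "logCS": measured_log_cs,
            "sex": sex,
            "cross_direction": direction,
        },
        index=cross.ids,
    )
    return coords, covariates


def make_mesh(
    kind: str = "ellipsoid",
    semi_axes: tuple[float, float, float] = (1.0, 1.0, 1.0),
    subdivisions: int = 3,
    exponent: float = 1.0,
) -> trimesh.Trimesh:
    """Watertight fixture mesh: an (super)ellipsoid from a subdivided icosphere.

    ``kind='superellipsoid'`` maps each unit-sphere vertex u componentwise to
    sign(u)|u|^exponent before scaling by the semi-axes; ``exponent < 1``
    gives boxier shapes, ``> 1`` pinched ones.
    """
    ax = np.asarray(semi_axes, dtype=float)
    if ax.shape != (3,) or np.any(ax <= 0):
        raise ValueError("semi_axes must be three positive numbers")
    sphere = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    v = sphere.vertices.copy()
    if kind == "superellipsoid":
        v = np.sign(v) * np.abs(v) ** exponent
        norm = np.linalg.norm(v, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        # keep points on a star-shaped surface (radial renormalisation)
        v = v / norm * np.linalg.norm(sphere.vertices, axis=1, keepdims=True)
    elif kind != "ellipsoid":
        raise ValueError(f"unknown mesh kind {kind!r}")
    v = v * ax
    mesh = trimesh.Trimesh(vertices=v, faces=sphere.faces, process=False)
    return mesh


def default_mean_shape(k: int = 13, d: int = 3, seed: int = 5834, scale: float = 1.0):
    """A fixed, well-spread k x d reference configuration.

    Points are drawn once (fixed seed) on a flattened ellipsoid so the
    configuration is non-degenerate in every axis, then centered and
    normalised to unit centroid size before optional rescaling. Mimics the
    hemi-mandible situation: most spread in-plane, modest relief out of plane.
    """
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((k, d))
    x /= np.linalg.norm(x, axis=1, keepdims=True)
    squash = np.ones(d)
    if d == 3:
        squash[2] = 0.3  # flattish, like a mandible on its natural plane
    x = x * squash
    x -= x.mean(0)
    x /= np.sqrt((x**2).sum())
    return x * scale
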