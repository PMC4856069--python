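"""Surface operations for semilandmarks.

Covers the dense-phenotyping workflow: build a template of uniformly spread
surface points on a reference mesh (poisson-disk sampling), transfer it to
new specimens by a thin-plate spline anchored on the expert landmarks,
relax the transferred points by bending-energy sliding in their local
tangent planes, and keep everything glued to the actual triangulated surface
by exact nearest-point projection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

from .base import LandmarkConfig
from .tps import bending_energy_matrix, tps_fit

__all__ = [
    "Template",
    "SlideResult",
    "project_to_mesh",
    "signed_surface_distance",
    "poisson_disk_template",
    "transfer_template",
    "slide_semilandmarks",
]


def _closest_on_triangles(p: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Closest point to ``p`` on every triangle in ``tri`` (F x 3 x 3).

    Vectorised region classification (vertex / edge / interior cases).
    """
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    out = np.empty_like(a)
    done = np.zeros(len(a), dtype=bool)

    m = (d1 <= 0) & (d2 <= 0)
    out[m] = a[m]
    done |= m
    m = (~done) & (d3 >= 0) & (d4 <= d3)
    out[m] = b[m]
    done |= m
    vc = d1 * d4 - d3 * d2
    m = (~done) & (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0)
    out[m] = a[m] + v[m, None] * ab[m]
    done |= m
    m = (~done) & (d6 >= 0) & (d5 <= d6)
    out[m] = c[m]
    done |= m
    vb = d5 * d2 - d1 * d6
    m = (~done) & (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0)
    out[m] = a[m] + w[m, None] * ac[m]
    done |= m
    va = d3 * d6 - d5 * d4
    m = (~done) & (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    denom = (d4 - d3) + (d5 - d6)
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(denom != 0, (d4 - d3) / denom, 0.0)
    out[m] = b[m] + w[m, None] * (c[m] - b[m])
    done |= m
    m = ~done
    denom = va + vb + vc
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.where(denom != 0, vb / denom, 1 / 3)
        w = np.where(denom != 0, vc / denom, 1 / 3)
    out[m] = a[m] + v[m, None] * ab[m] + w[m, None] * ac[m]
    return out


def project_to_mesh(points: np.ndarray, mesh: trimesh.Trimesh):
    """Exact nearest point on the triangle set for each query point.

    Returns ``(nearest, distances, face_index)``. All vertex, edge and
    interior cases are handled; for small-to-moderate meshes the search is an
    exhaustive vectorised sweep over triangles, which is exact by
    construction.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if len(mesh.faces) == 0:
        raise ValueError("empty mesh")
    tri = mesh.triangles.view(np.ndarray)
    nearest = np.empty_like(pts)
    dists = np.empty(len(pts))
    fidx = np.empty(len(pts), dtype=int)
    for i, p in enumerate(pts):
        cand = _closest_on_triangles(p, tri)
        d2 = ((cand - p) ** 2).sum(axis=1)
        j = int(np.argmin(d2))
        nearest[i] = cand[j]
        dists[i] = np.sqrt(d2[j])
        fidx[i] = j
    return nearest, dists, fidx


def signed_surface_distance(mesh_a: trimesh.Trimesh, mesh_b: trimesh.Trimesh) -> np.ndarray:
    """Signed distance from each vertex of ``mesh_a`` to ``mesh_b``.

    The magnitude is the Euclidean distance to the nearest point of
    ``mesh_b``; the sign is positive when that point lies along the outward
    vertex normal of ``mesh_a`` (i.e. ``mesh_b`` is outside ``mesh_a``
    locally) and negative when it lies against it. Vertex normals are
    computed from the faces when absent.
    """
    nearest, dists, _ = project_to_mesh(mesh_a.vertices.view(np.ndarray), mesh_b)
    normals = mesh_a.vertex_normals.view(np.ndarray)
    offset = nearest - mesh_a.vertices.view(np.ndarray)
    sign = np.sign(np.einsum("ij,ij->i", normals, offset))
    sign[dists < 1e-14] = 0.0
    return sign * dists


@dataclass
class Template:
    """Reference configuration (fixed landmarks + semilandmarks) on a mesh."""

    reference_config: LandmarkConfig
    reference_mesh: trimesh.Trimesh
    radius: float


def _sample_surface(mesh: trimesh.Trimesh, count: int, rng: np.random.Generator):
    """Uniform-by-area surface samples (area-weighted face + barycentric)."""
    areas = mesh.area_faces
    probs = areas / areas.sum()
    fidx = rng.choice(len(areas), size=count, p=probs)
    tri = mesh.triangles.view(np.ndarray)[fidx]
    r1 = np.sqrt(rng.random(count))
    r2 = rng.random(count)
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    return (1 - r1)[:, None] * a + (r1 * (1 - r2))[:, None] * b + (r1 * r2)[:, None] * c


def _dart_throw(candidates: np.ndarray, radius: float) -> np.ndarray:
    """Greedy poisson-disk thinning: keep points >= radius apart."""
    accepted: list[np.ndarray] = []
    acc = np.empty((0, 3))
    r2 = radius * radius
    for p in candidates:
        if len(accepted) == 0 or (((acc - p) ** 2).sum(axis=1) >= r2).all():
            accepted.append(p)
            acc = np.asarray(accepted)
    return acc


def poisson_disk_template(
    mesh: trimesh.Trimesh,
    target_count: int | None = None,
    radius: float | None = None,
    exclusion_regions: list[tuple[np.ndarray, float]] | None = None,
    seed: int = 0,
    fixed_landmarks: np.ndarray | None = None,
    fixed_labels: list[str] | None = None,
) -> Template:
    """Uniformly spread semilandmarks on a reference mesh.

    Dart-throwing with a minimum pairwise distance: candidates are sampled
    uniformly by area and kept greedily when at least ``radius`` from every
    accepted point. When ``target_count`` is given instead of a radius, the
    radius is tuned by a few multiplicative corrections until the count is
    within 15% of the target. ``exclusion_regions`` are (center, radius)
    spheres whose interior points are discarded (e.g. teeth). Optional
    ``fixed_landmarks`` are back-projected onto the mesh and prepended as the
    fixed part of the template.
    """
    if (target_count is None) == (radius is None):
        raise ValueError("give exactly one of target_count or radius")
    rng = np.random.default_rng(seed)
    n_cand = max(5000, 40 * (target_count or 100))
    candidates = _sample_surface(mesh, n_cand, rng)
    if exclusion_regions:
        keep = np.ones(len(candidates), dtype=bool)
        for center, rad in exclusion_regions:
            keep &= np.linalg.norm(candidates - np.asarray(center), axis=1) >= rad
        candidates = candidates[keep]

    if radius is not None:
        points = _dart_throw(candidates, radius)
        if target_count is not None and not points.size:
            raise ValueError("radius too large for the surface")
        r_used = radius
    else:
        # RSA saturation density ~0.55 of disks of diameter radius
        area = mesh.area
        r_used = float(np.sqrt(4 * 0.55 * area / (np.pi * target_count)))
        points = _dart_throw(candidates, r_used)
        for _ in range(8):
            if abs(len(points) - target_count) <= 0.15 * target_count:
                break
            r_used *= np.sqrt(len(points) / target_count)
            points = _dart_throw(candidates, r_used)
        if abs(len(points) - target_count) > 0.15 * target_count:
            raise ValueError(
                f"could not reach target_count={target_count} (got {len(points)})"
            )

    semi = points
    if fixed_landmarks is not None:
        fixed = np.asarray(fixed_landmarks, dtype=float)
        fixed_proj, _, _ = project_to_mesh(fixed, mesh)
        coords = np.vstack([fixed_proj, semi])
        k0 = len(fixed)
        labels = list(fixed_labels) if fixed_labels else [f"F{i + 1}" for i in range(k0)]
        labels += [f"S{i + 1}" for i in range(len(semi))]
        mask = np.array([True] * k0 + [False] * len(semi))
    else:
        coords = semi
        labels = [f"S{i + 1}" for i in range(len(semi))]
        mask = np.zeros(len(semi), dtype=bool)

    config = LandmarkConfig(coords=coords, labels=labels, fixed_mask=mask)
    return Template(reference_config=config, reference_mesh=mesh, radius=r_used)


def transfer_template(
    template: Template,
    target_fixed: np.ndarray,
    target_mesh: trimesh.Trimesh,
) -> LandmarkConfig:
    """Carry the template onto a new specimen.

    A thin-plate spline from the template's fixed landmarks to
    ``target_fixed`` warps the semilandmarks; each warped point is then
    projected to its nearest point on ``target_mesh``. The fixed landmarks
    themselves are back-projected onto the mesh by shortest Euclidean
    distance so the whole configuration lives on the specimen's surface.
    """
    ref = template.reference_config
    mask = ref.fixed_mask
    ref_fixed = ref.coords[mask]
    tgt_fixed = np.asarray(target_fixed, dtype=float)
    if tgt_fixed.shape != ref_fixed.shape:
        raise ValueError("target fixed landmarks do not match the template")
    warp = tps_fit(ref_fixed, tgt_fixed)
    semi_warp = warp(ref.coords[~mask])
    semi_proj, _, _ = project_to_mesh(semi_warp, target_mesh)
    fixed_proj, _, _ = project_to_mesh(tgt_fixed, target_mesh)
    coords = np.empty_like(ref.coords)
    coords[mask] = fixed_proj
    coords[~mask] = semi_proj
    return LandmarkConfig(coords=coords, labels=ref.labels, fixed_mask=mask.copy())


@dataclass
class SlideResult:
    config: LandmarkConfig
    bending_energies: list = field(default_factory=list)  # pre-projection path
    converged: bool = True


def _tangent_bases(points: np.ndarray, mesh: trimesh.Trimesh):
    """Orthonormal tangent pairs from the nearest face normal of each point.

    Falls back to a local PCA plane over the 8 nearest neighbours when the
    face normal is degenerate.
    """
    _, _, fidx = project_to_mesh(points, mesh)
    normals = mesh.face_normals.view(np.ndarray)[fidx]
    u = np.empty_like(points)
    v = np.empty_like(points)
    for i, nrm in enumerate(normals):
        nn = np.linalg.norm(nrm)
        if nn < 1e-12:
            diffs = points - points[i]
            order = np.argsort((diffs**2).sum(axis=1))[1:9]
            local = points[order] - points[order].mean(axis=0)
            _, _, vt = np.linalg.svd(local, full_matrices=False)
            nrm = vt[-1]
        else:
            nrm = nrm / nn
        helper = np.array([1.0, 0.0, 0.0])
        if abs(nrm[0]) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        t1 = np.cross(nrm, helper)
        t1 /= np.linalg.norm(t1)
        t2 = np.cross(nrm, t1)
        u[i], v[i] = t1, t2
    return u, v


def _config_energy(Lb: np.ndarray, target: np.ndarray) -> float:
    return float(np.einsum("im,ij,jm->", target, Lb, target))


def slide_semilandmarks(
    reference: LandmarkConfig,
    target: LandmarkConfig,
    target_mesh: trimesh.Trimesh,
    iters: int = 3,
) -> SlideResult:
    """Relax semilandmarks by bending-energy sliding on the target surface.

    Each iteration solves the closed-form generalized least squares for the
    tangent-plane displacements of the semilandmarks that minimise the
    bending energy of the reference-to-target thin-plate spline (fixed
    landmarks immobile), then re-projects the slid points onto
    ``target_mesh``. The pre-projection energy is non-increasing across
    iterations; re-projection can perturb it slightly.
    """
    if reference.coords.shape != target.coords.shape:
        raise ValueError("reference and target must share (k, d)")
    mask = reference.fixed_mask
    semi_idx = np.flatnonzero(~mask)
    Lb = bending_energy_matrix(reference.coords)
    k, d = reference.coords.shape
    Y = target.coords.copy()
    energies = [_config_energy(Lb, Y)]
    if semi_idx.size == 0:
        return SlideResult(
            config=LandmarkConfig(Y, labels=target.labels, fixed_mask=mask.copy()),
            bending_energies=energies,
        )

    converged = True
    for _ in range(iters):
        u, v = _tangent_bases(Y[semi_idx], target_mesh)
        s = len(semi_idx)
        # column-stacked displacement basis: y[m*k + i] = Y[i, m]
        U = np.zeros((k * d, 2 * s))
        for j, i in enumerate(semi_idx):
            for m in range(d):
                U[m * k + i, 2 * j] = u[j, m]
                U[m * k + i, 2 * j + 1] = v[j, m]
        Bblk = np.kron(np.eye(d), Lb)
        y = Y.T.ravel()
        A = U.T @ Bblk @ U
        b = -U.T @ Bblk @ y
        t, *_ = np.linalg.lstsq(A, b, rcond=1e-10)
        y_new = y + U @ t
        Y_slid = y_new.reshape(d, k).T
        e_slid = _config_energy(Lb, Y_slid)
        if e_slid > energies[-1] + 1e-10 * max(1.0, energies[-1]):
            converged = False
            break
        energies.append(e_slid)
        proj, _, _ = project_to_mesh(Y_slid[semi_idx], target_mesh)
        Y = Y_slid
        Y[semi_idx] = proj

    return SlideResult(
        config=LandmarkConfig(Y, labels=target.labels, fixed_mask=mask.copy()),
        bending_energies=energies,
        converged=converged,
    )
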