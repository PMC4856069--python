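"""Simulated 2D phenotyping: orthogonal flattening of 3D configurations.

Emulates photographing a fairly flat bone: the specimen is laid on its
natural plane (defined by three anchor landmarks) and every landmark is
orthogonally projected along the plane normal, producing a 2D configuration
comparable to classical 2D imaging studies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh

from .base import LandmarkConfig

__all__ = ["FlattenResult", "flatten_to_2d"]


def _principal_axis_align(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center and rotate a configuration to its principal axes.

    Axes ordered by decreasing variance; each eigenvector's sign is fixed so
    its largest-magnitude component is positive (deterministic output).
    """
    c = coords - coords.mean(axis=0)
    cov = c.T @ c
    w, v = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    v = v[:, order]
    for j in range(v.shape[1]):
        i = np.argmax(np.abs(v[:, j]))
        if v[i, j] < 0:
            v[:, j] = -v[:, j]
    if v.shape[1] == 3 and np.linalg.det(v) < 0:
        v[:, 2] = -v[:, 2]
    return c @ v, v


@dataclass
class FlattenResult:
    config2d: LandmarkConfig
    out_of_plane: np.ndarray  # signed residual along the plane normal, per landmark
    plane_normal: np.ndarray  # in the principal-axis frame
    iterations: int
    converged: bool


def flatten_to_2d(
    config: LandmarkConfig,
    anchors: tuple[int, int, int],
    mesh: trimesh.Trimesh | None = None,
    max_iter: int = 10,
    tol: float = 1e-8,
) -> FlattenResult:
    """Project a 3D configuration onto the plane of three anchor landmarks.

    The configuration is first aligned to its principal axes. When a mesh is
    given (in the same coordinate frame as ``config``), the first two anchor
    positions are refined iteratively to the innermost mesh vertex along the
    current plane normal -- the vertex, among those nearby, with the smallest
    signed height above the plane -- until the anchors stop moving. All
    landmarks are then orthogonally projected onto the plane and expressed in
    a deterministic in-plane basis (principal axes of the projected
    configuration, largest component positive).
    """
    if config.d != 3:
        raise ValueError("flattening applies to 3D configurations")
    a0, a1, a2 = anchors
    if len({a0, a1, a2}) != 3:
        raise ValueError("anchors must be three distinct landmarks")

    aligned, rot = _principal_axis_align(config.coords)
    center = config.coords.mean(axis=0)
    verts = None
    if mesh is not None:
        verts = (mesh.vertices.view(np.ndarray) - center) @ rot

    p0, p1, p2 = aligned[a0].copy(), aligned[a1].copy(), aligned[a2].copy()

    def plane_normal(q0, q1, q2):
        nrm = np.cross(q1 - q0, q2 - q0)
        n = np.linalg.norm(nrm)
        if n < 1e-12:
            raise ValueError("collinear anchors")
        nrm = nrm / n
        # orient toward +z of the principal-axis frame (the natural plane's
        # normal is close to the smallest-variance axis), so similar
        # specimens always flatten with the same handedness
        if nrm[2] < 0:
            nrm = -nrm
        return nrm

    it = 0
    converged = True
    if verts is not None:
        converged = False
        for it in range(1, max_iter + 1):
            nrm = plane_normal(p0, p1, p2)
            origin = p0.copy()
            moved = 0.0
            for which, p in enumerate((p0, p1)):
                # candidate vertices near the anchor's normal line
                lateral = (verts - p) - np.outer((verts - p) @ nrm, nrm)
                near = np.linalg.norm(lateral, axis=1) < 0.15 * np.ptp(aligned, axis=0).max()
                if not near.any():
                    continue
                heights = (verts[near] - origin) @ nrm
                new_p = verts[near][np.argmin(heights)]
                other = p1 if which == 0 else p0
                if np.linalg.norm(new_p - other) < tol:
                    continue  # refusing to collapse the two lay-flat anchors
                moved = max(moved, float(np.linalg.norm(new_p - p)))
                if which == 0:
                    p0 = new_p.copy()
                else:
                    p1 = new_p.copy()
            if moved < tol:
                converged = True
                break

    nrm = plane_normal(p0, p1, p2)
    heights = (aligned - p0) @ nrm
    projected = aligned - np.outer(heights, nrm)

    # in-plane orthonormal basis from the projected configuration
    centered = projected - projected.mean(axis=0)
    cov = centered.T @ centered
    w, v = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    basis = v[:, order[:2]]
    i = np.argmax(np.abs(basis[:, 0]))
    if basis[i, 0] < 0:
        basis[:, 0] = -basis[:, 0]
    # right-handed in-plane frame w.r.t. the plane normal: keeps the 2D
    # handedness consistent across similar specimens
    if np.linalg.det(np.column_stack([basis, nrm])) < 0:
        basis[:, 1] = -basis[:, 1]
    coords2d = centered @ basis

    cfg2d = LandmarkConfig(
        coords=coords2d, labels=config.labels, fixed_mask=config.fixed_mask.copy()
    )
    return FlattenResult(
        config2d=cfg2d,
        out_of_plane=heights,
        plane_normal=nrm,
        iterations=it,
        converged=converged,
    )
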