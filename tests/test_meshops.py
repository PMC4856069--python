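"""Surface operations: projection, poisson-disk template, transfer, sliding."""

import numpy as np
import pytest
import trimesh

from shapemapper.morpho import (
    LandmarkConfig,
    poisson_disk_template,
    project_to_mesh,
    signed_surface_distance,
    slide_semilandmarks,
    transfer_template,
)
from shapemapper.morpho.meshops import _closest_on_triangles
from shapemapper.synthetic import make_mesh


def brute_force_nearest(point, mesh):
    """Per-triangle loop with an independent closest-point computation."""
    best_d2, best_p = np.inf, None
    for tri in mesh.triangles:
        a, b, c = tri
        # solve the constrained least squares in barycentric coordinates
        E0, E1 = b - a, c - a
        M = np.array([[E0 @ E0, E0 @ E1], [E1 @ E0, E1 @ E1]])
        rhs = np.array([E0 @ (point - a), E1 @ (point - a)])
        try:
            u, v = np.linalg.solve(M, rhs)
        except np.linalg.LinAlgError:
            continue
        if u < 0 or v < 0 or u + v > 1:
            # clamp to each edge and pick the best
            cands = []
            for p0, p1 in ((a, b), (a, c), (b, c)):
                e = p1 - p0
                t = np.clip(e @ (point - p0) / (e @ e), 0, 1)
                cands.append(p0 + t * e)
            q = min(cands, key=lambda x: ((x - point) ** 2).sum())
        else:
            q = a + u * E0 + v * E1
        d2 = ((q - point) ** 2).sum()
        if d2 < best_d2:
            best_d2, best_p = d2, q
    return best_p, np.sqrt(best_d2)


class TestProjectToMesh:
    def test_point_on_face_is_fixed_point(self, ellipsoid_mesh):
        centroid = ellipsoid_mesh.triangles[10].mean(axis=0)
        near, d, f = project_to_mesh(centroid[None], ellipsoid_mesh)
        assert d[0] < 1e-12
        assert np.allclose(near[0], centroid)

    def test_point_along_face_normal(self, ellipsoid_mesh):
        fi = 42
        centroid = ellipsoid_mesh.triangles[fi].mean(axis=0)
        normal = ellipsoid_mesh.face_normals[fi]
        h = 0.01  # small enough that the face itself is nearest
        near, d, f = project_to_mesh((centroid + h * normal)[None], ellipsoid_mesh)
        assert d[0] == pytest.approx(h, abs=1e-9)
        assert np.allclose(near[0], centroid, atol=1e-9)

    def test_matches_brute_force_on_random_points(self, ellipsoid_mesh, rng):
        pts = rng.uniform(-4, 4, (25, 3))
        near, d, _ = project_to_mesh(pts, ellipsoid_mesh)
        for i, p in enumerate(pts):
            q, dd = brute_force_nearest(p, ellipsoid_mesh)
            assert d[i] == pytest.approx(dd, abs=1e-9)
            assert np.allclose(near[i], q, atol=1e-7)

    def test_empty_mesh_rejected(self):
        empty = trimesh.Trimesh(vertices=np.zeros((0, 3)), faces=np.zeros((0, 3), int))
        with pytest.raises(ValueError):
            project_to_mesh(np.zeros((1, 3)), empty)


class TestSignedSurfaceDistance:
    def test_identical_meshes_zero(self, sphere_mesh):
        assert np.allclose(signed_surface_distance(sphere_mesh, sphere_mesh), 0.0)

    def test_concentric_spheres_positive_outward(self):
        inner = make_mesh("ellipsoid", (1, 1, 1), 3)
        outer = make_mesh("ellipsoid", (1.1, 1.1, 1.1), 3)
        sd = signed_surface_distance(inner, outer)
        assert np.all(sd > 0.08)
        assert np.all(sd < 0.12)

    def test_sign_flips_with_orientation(self):
        inner = make_mesh("ellipsoid", (1, 1, 1), 2)
        outer = make_mesh("ellipsoid", (1.2, 1.2, 1.2), 2)
        sd = signed_surface_distance(inner, outer)
        flipped = trimesh.Trimesh(inner.vertices, inner.faces[:, ::-1], process=False)
        sd_f = signed_surface_distance(flipped, outer)
        assert np.allclose(sd, -sd_f, atol=1e-9)


class TestPoissonDiskTemplate:
    def test_min_distance_property(self, ellipsoid_mesh):
        tpl = poisson_disk_template(ellipsoid_mesh, radius=0.4, seed=1)
        pts = tpl.reference_config.coords
        from scipy.spatial.distance import pdist

        assert pdist(pts).min() >= 0.4

    def test_sphere_packing_bound(self, sphere_mesh):
        """Saturated set size bracketed by spherical-cap packing/covering.

        Disjoint caps of chord radius r/2 give the upper bound (with the
        hexagonal density limit); covering caps of chord radius r give the
        lower bound for a saturated sample.
        """
        r = 0.5
        tpl = poisson_disk_template(sphere_mesh, radius=r, seed=2)
        n = len(tpl.reference_config.coords)
        area = 4 * np.pi
        cap = lambda chord: 2 * np.pi * (1 - np.cos(2 * np.arcsin(chord / 2)))  # noqa: E731
        upper = area * 0.9069 / cap(r / 2)
        lower = area / cap(r)
        assert lower <= n <= upper

    def test_target_count_within_fifteen_percent(self, ellipsoid_mesh):
        tpl = poisson_disk_template(ellipsoid_mesh, target_count=80, seed=3)
        n = (~tpl.reference_config.fixed_mask).sum()
        assert abs(n - 80) <= 12

    def test_exclusion_regions_respected(self, sphere_mesh):
        center = np.array([0.0, 0.0, 1.0])
        tpl = poisson_disk_template(
            sphere_mesh, radius=0.25, exclusion_regions=[(center, 0.5)], seed=4
        )
        pts = tpl.reference_config.coords
        assert np.linalg.norm(pts - center, axis=1).min() >= 0.5

    def test_points_lie_on_mesh(self, ellipsoid_mesh):
        tpl = poisson_disk_template(ellipsoid_mesh, radius=0.5, seed=5)
        _, d, _ = project_to_mesh(tpl.reference_config.coords, ellipsoid_mesh)
        assert d.max() < 1e-9

    def test_both_or_neither_parameter_rejected(self, sphere_mesh):
        with pytest.raises(ValueError):
            poisson_disk_template(sphere_mesh, target_count=10, radius=0.3)
        with pytest.raises(ValueError):
            poisson_disk_template(sphere_mesh)


@pytest.fixture()
def template(ellipsoid_mesh, rng):
    idx = rng.choice(len(ellipsoid_mesh.vertices), 13, replace=False)
    fixed = ellipsoid_mesh.vertices.view(np.ndarray)[idx]
    return poisson_disk_template(
        ellipsoid_mesh, target_count=50, seed=6, fixed_landmarks=fixed
    )


class TestTransferTemplate:
    def test_identity_transfer_reproduces_template(self, template, ellipsoid_mesh):
        ref = template.reference_config
        out = transfer_template(template, ref.coords[ref.fixed_mask], ellipsoid_mesh)
        assert np.abs(out.coords - ref.coords).max() < 1e-8

    def test_output_lies_on_target_mesh(self, template, ellipsoid_mesh):
        tgt_mesh = trimesh.Trimesh(
            ellipsoid_mesh.vertices * [1.15, 0.9, 1.05],
            ellipsoid_mesh.faces,
            process=False,
        )
        ref = template.reference_config
        out = transfer_template(
            template, ref.coords[ref.fixed_mask] * [1.15, 0.9, 1.05], tgt_mesh
        )
        _, d, _ = project_to_mesh(out.coords, tgt_mesh)
        bbox = np.ptp(tgt_mesh.vertices, axis=0).max()
        assert d.max() < 1e-6 * bbox

    def test_affine_deformation_oracle(self, template, ellipsoid_mesh, rng):
        """An affine target is matched by affinely mapping the template."""
        A = np.diag([1.2, 0.85, 1.1]) + 0.05 * rng.standard_normal((3, 3))
        tgt_mesh = trimesh.Trimesh(
            ellipsoid_mesh.vertices @ A.T, ellipsoid_mesh.faces, process=False
        )
        ref = template.reference_config
        out = transfer_template(template, ref.coords[ref.fixed_mask] @ A.T, tgt_mesh)
        expected = ref.coords @ A.T
        err = np.linalg.norm(out.coords - expected, axis=1).max()
        assert err < 0.02 * tgt_mesh.edges_unique_length.mean()


class TestSlideSemilandmarks:
    def test_identical_target_does_not_move(self, template, ellipsoid_mesh):
        ref = template.reference_config
        res = slide_semilandmarks(ref, ref, ellipsoid_mesh, iters=2)
        assert np.abs(res.config.coords - ref.coords).max() < 1e-6

    def test_bending_energy_non_increasing(self, template, ellipsoid_mesh, rng):
        ref = template.reference_config
        tgt_mesh = trimesh.Trimesh(
            ellipsoid_mesh.vertices * [1.3, 0.8, 1.0], ellipsoid_mesh.faces, process=False
        )
        # perturbed transfer: warp + tangential jitter then re-projection
        coords = ref.coords * [1.3, 0.8, 1.0]
        jitter = 0.05 * rng.standard_normal(coords.shape)
        coords[~ref.fixed_mask] += jitter[~ref.fixed_mask]
        proj, _, _ = project_to_mesh(coords[~ref.fixed_mask], tgt_mesh)
        coords[~ref.fixed_mask] = proj
        tgt = LandmarkConfig(coords, labels=ref.labels, fixed_mask=ref.fixed_mask)
        res = slide_semilandmarks(ref, tgt, tgt_mesh, iters=3)
        e = res.bending_energies
        assert all(e[i + 1] <= e[i] + 1e-8 for i in range(len(e) - 1))
        assert e[-1] < e[0]

    def test_fixed_landmarks_never_move(self, template, ellipsoid_mesh, rng):
        ref = template.reference_config
        coords = ref.coords.copy()
        coords[~ref.fixed_mask] += 0.02 * rng.standard_normal(
            coords[~ref.fixed_mask].shape
        )
        proj, _, _ = project_to_mesh(coords[~ref.fixed_mask], ellipsoid_mesh)
        coords[~ref.fixed_mask] = proj
        tgt = LandmarkConfig(coords, labels=ref.labels, fixed_mask=ref.fixed_mask)
        res = slide_semilandmarks(ref, tgt, ellipsoid_mesh, iters=3)
        assert np.array_equal(
            res.config.coords[ref.fixed_mask], coords[ref.fixed_mask]
        )

    def test_sliding_beats_unslid_baseline(self, template, ellipsoid_mesh, rng):
        """A tangentially rotated start is strictly improved by sliding."""
        ref = template.reference_config
        theta = 0.15
        R = np.array(
            [
                [np.cos(theta), -np.sin(theta), 0],
                [np.sin(theta), np.cos(theta), 0],
                [0, 0, 1],
            ]
        )
        coords = ref.coords.copy()
        rotated = coords[~ref.fixed_mask] @ R.T
        proj, _, _ = project_to_mesh(rotated, ellipsoid_mesh)
        coords[~ref.fixed_mask] = proj
        tgt = LandmarkConfig(coords, labels=ref.labels, fixed_mask=ref.fixed_mask)
        res = slide_semilandmarks(ref, tgt, ellipsoid_mesh, iters=3)
        assert res.bending_energies[-1] < res.bending_energies[0] * 0.9
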