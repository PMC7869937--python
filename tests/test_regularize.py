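"""Meshing, hole repair, smoothing, resampling and Poisson-disk thinning."""

import numpy as np
import pytest

from rugosa.cloud import ColoredPointCloud
from rugosa.regularize import (SurfaceMesh, build_mesh, laplacian_smooth,
                               poisson_disk_thin, repair_holes, sample_surface)

from conftest import grid_cloud, random_cloud


def planar_square_mesh(side=1.0):
    """Two triangles covering a unit square at z=0."""
    cloud = ColoredPointCloud(
        [[0, 0, 0], [side, 0, 0], [side, side, 0], [0, side, 0]],
        np.full((4, 3), 100, dtype=np.uint8))
    return build_mesh(cloud)


class TestBuildMesh:
    def test_planar_square(self):
        mesh = planar_square_mesh()
        assert len(mesh.faces) == 2
        assert mesh.area == pytest.approx(1.0)

    @pytest.mark.parametrize("n", [4, 7, 10])
    def test_grid_triangle_count(self, n):
        mesh = build_mesh(grid_cloud(n, spacing=0.1))
        assert len(mesh.faces) == 2 * (n - 1) ** 2

    def test_vertex_set_equals_cloud(self):
        cloud = random_cloud(200, seed=1)
        mesh = build_mesh(cloud)
        np.testing.assert_array_equal(mesh.vertices, cloud.xyz)
        np.testing.assert_array_equal(mesh.colors, cloud.rgb)

    def test_collinear_points_rejected(self):
        xyz = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        cloud = ColoredPointCloud(xyz, np.zeros((5, 3), dtype=np.uint8))
        with pytest.raises(ValueError, match="collinear"):
            build_mesh(cloud)

    def test_max_edge_prunes_wall_triangles(self):
        # two horizontal strips 1 m apart in z: hull triangulation bridges
        # them with long edges; pruning drops exactly those bridges
        a = grid_cloud(5, spacing=0.1, z=0.0)
        b = grid_cloud(5, spacing=0.1, z=1.0).translated([1.0, 0, 0])
        cloud = ColoredPointCloud(np.vstack([a.xyz, b.xyz]),
                                  np.vstack([a.rgb, b.rgb]))
        full = build_mesh(cloud)
        pruned = build_mesh(cloud, max_edge=0.5)
        assert len(pruned.faces) < len(full.faces)
        corners = pruned.vertices[pruned.faces]
        edge_len = np.linalg.norm(corners - np.roll(corners, -1, axis=1), axis=2)
        assert edge_len.max() <= 0.5


class TestRepairHoles:
    def test_missing_interior_triangle_is_refilled(self):
        mesh = build_mesh(grid_cloud(8, spacing=0.1))
        full_area = mesh.area
        interior = len(mesh.faces) // 2  # any one triangle off the border
        centers = mesh.vertices[mesh.faces].mean(axis=1)
        interior = int(np.argmin(np.linalg.norm(
            centers[:, :2] - [0.35, 0.35], axis=1)))
        holed = SurfaceMesh(mesh.vertices,
                            np.delete(mesh.faces, interior, axis=0),
                            mesh.colors)
        repaired, log = repair_holes(holed, max_hole_perimeter=1.0)
        assert log["n_holes_filled"] == 1
        assert repaired.area == pytest.approx(full_area, abs=1e-12)

    def test_hole_free_mesh_is_identity(self):
        mesh = build_mesh(grid_cloud(6, spacing=0.1))
        repaired, log = repair_holes(mesh, max_hole_perimeter=1.0)
        np.testing.assert_array_equal(repaired.faces, mesh.faces)
        assert log["n_holes_filled"] == 0

    def test_oversized_hole_left_open(self):
        mesh = build_mesh(grid_cloud(8, spacing=0.1))
        centers = mesh.vertices[mesh.faces].mean(axis=1)
        near = np.linalg.norm(centers[:, :2] - [0.35, 0.35], axis=1) < 0.12
        holed = SurfaceMesh(mesh.vertices, mesh.faces[~near], mesh.colors)
        area_holed = holed.area
        repaired, log = repair_holes(holed, max_hole_perimeter=0.2)
        assert log["n_holes_left_open"] >= 1
        assert repaired.area == pytest.approx(area_holed)


class TestLaplacianSmooth:
    def test_symmetric_planar_grid_is_fixed_point(self):
        mesh = build_mesh(grid_cloud(9, spacing=0.05, z=1.5))
        out = laplacian_smooth(mesh, radius=0.075, iterations=2)
        np.testing.assert_allclose(out.vertices, mesh.vertices, atol=1e-12)

    def test_spike_height_strictly_reduced(self):
        cloud = grid_cloud(9, spacing=0.05)
        xyz = cloud.xyz.copy()
        center = np.argmin(np.linalg.norm(xyz[:, :2] - [0.2, 0.2], axis=1))
        xyz[center, 2] = 0.05  # spike inside the smoothing radius
        mesh = build_mesh(ColoredPointCloud(xyz, cloud.rgb))
        out = laplacian_smooth(mesh, radius=0.1, iterations=1)
        assert out.vertices[center, 2] < 0.05
        assert out.vertices[center, 2] >= 0.0

    def test_zero_iterations_is_identity(self):
        mesh = build_mesh(random_cloud(50, seed=4))
        out = laplacian_smooth(mesh, radius=0.2, iterations=0)
        np.testing.assert_array_equal(out.vertices, mesh.vertices)

    def test_boundary_vertices_never_move(self):
        mesh = build_mesh(random_cloud(100, seed=6))
        fixed = mesh.boundary_vertices()
        out = laplacian_smooth(mesh, radius=0.5, iterations=3)
        np.testing.assert_array_equal(out.vertices[fixed], mesh.vertices[fixed])

    def test_invalid_radius_rejected(self):
        with pytest.raises(ValueError):
            laplacian_smooth(planar_square_mesh(), radius=0.0)


class TestSampleSurface:
    def test_count_formula(self):
        mesh = planar_square_mesh(side=np.sqrt(2.0))  # 2 m^2
        cloud = sample_surface(mesh, density=500, seed=0)
        assert len(cloud) == 1000

    def test_samples_lie_on_triangle_planes(self):
        mesh = planar_square_mesh()
        cloud = sample_surface(mesh, density=200, seed=1)
        np.testing.assert_allclose(cloud.z, 0.0, atol=1e-12)
        assert cloud.x.min() >= 0 and cloud.x.max() <= 1

    def test_area_weighted_allocation(self):
        # two triangles with area ratio 1:3
        verts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, -3, 0]])
        faces = np.array([[0, 1, 2], [0, 3, 1]])
        mesh = SurfaceMesh(verts, faces, np.full((4, 3), 50, dtype=np.uint8))
        counts = np.zeros(2)
        for seed in range(20):
            cloud = sample_surface(mesh, density=500, seed=seed)
            counts[0] += (cloud.y >= 0).sum()
            counts[1] += (cloud.y < 0).sum()
        ratio = counts[1] / counts.sum()
        # binomial 99% band around 0.75 for n = 20 * 1000
        assert abs(ratio - 0.75) < 2.58 * np.sqrt(0.75 * 0.25 / counts.sum())

    def test_deterministic_under_seed(self):
        mesh = planar_square_mesh()
        a = sample_surface(mesh, density=300, seed=9)
        b = sample_surface(mesh, density=300, seed=9)
        np.testing.assert_array_equal(a.xyz, b.xyz)
        np.testing.assert_array_equal(a.rgb, b.rgb)

    def test_zero_area_rejected(self):
        verts = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]])
        mesh = SurfaceMesh(verts, np.array([[0, 1, 2]]),
                           np.zeros((3, 3), dtype=np.uint8))
        with pytest.raises(ValueError, match="zero"):
            sample_surface(mesh, density=100, seed=0)


class TestPoissonDisk:
    def test_two_close_points_one_survives(self):
        cloud = ColoredPointCloud([[0, 0, 0], [0.005, 0, 0]],
                                  [[0, 0, 0], [0, 0, 0]])
        out = poisson_disk_thin(cloud, min_dist=0.01, seed=0)
        assert len(out) == 1

    def test_already_spaced_cloud_unchanged(self):
        cloud = grid_cloud(10, spacing=0.02)
        out = poisson_disk_thin(cloud, min_dist=0.01, seed=0)
        assert len(out) == len(cloud)

    def test_spacing_and_maximality_brute_force(self):
        rng = np.random.default_rng(17)
        # clustered cloud: dense blobs plus background
        blobs = [rng.normal(c, 0.02, size=(600, 3)) for c in
                 ([0, 0, 0], [0.3, 0.1, 0], [0.1, 0.4, 0.1])]
        xyz = np.vstack(blobs + [rng.uniform(-0.2, 0.6, size=(200, 3))])
        cloud = ColoredPointCloud(xyz, np.zeros((len(xyz), 3), dtype=np.uint8))
        out = poisson_disk_thin(cloud, min_dist=0.01, seed=5)
        kept = out.xyz
        d = np.linalg.norm(kept[:, None] - kept[None, :], axis=2)
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 0.01
        # maximality: every rejected point is within min_dist of a kept one
        kept_set = set(map(tuple, kept))
        rejected = np.array([p for p in xyz if tuple(p) not in kept_set])
        dr = np.linalg.norm(rejected[:, None] - kept[None, :], axis=2)
        assert dr.min(axis=1).max() < 0.01

    def test_empty_input(self):
        from rugosa.cloud import empty_cloud
        assert len(poisson_disk_thin(empty_cloud(), 0.01, seed=0)) == 0


def test_regularize_chain_preserves_flat_surface():
    cloud = grid_cloud(25, spacing=0.05, z=0.8)  # uniform planar cloud
    mesh = build_mesh(cloud)
    mesh, _ = repair_holes(mesh, 0.5)
    mesh = laplacian_smooth(mesh, radius=0.075)
    sampled = sample_surface(mesh, density=500, seed=3)
    thinned = poisson_disk_thin(sampled, min_dist=0.01, seed=4)
    rms = np.sqrt(np.mean((thinned.z - 0.8) ** 2))
    assert rms < 1e-6
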