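import numpy as np
import pytest
import trimesh

from bonereg.geometry import GeometryError, ImageGrid, TriangleMesh
from bonereg.metrics import (
    MetricSettings,
    compare_models,
    contains_points,
    dice_index,
    mean_absolute_distance,
    point_to_surface_distances,
    sample_surface,
    voxelize_closed_mesh,
)
from conftest import make_cube


def oracle_point_triangle_distance(p, tri):
    """Independent 7-candidate closest-point oracle.

    Solves the unconstrained projection onto the triangle plane plus the
    three clamped edge problems and the three vertices, and takes the
    minimum - a different derivation than the Voronoi-region classifier.
    """
    a, b, c = tri
    candidates = [a, b, c]
    for p0, p1 in ((a, b), (b, c), (c, a)):
        d = p1 - p0
        t = np.clip(np.dot(p - p0, d) / np.dot(d, d), 0.0, 1.0)
        candidates.append(p0 + t * d)
    ab, ac = b - a, c - a
    g = np.array([[ab @ ab, ab @ ac], [ab @ ac, ac @ ac]])
    rhs = np.array([ab @ (p - a), ac @ (p - a)])
    try:
        u, v = np.linalg.solve(g, rhs)
        if u >= 0 and v >= 0 and u + v <= 1:
            candidates.append(a + u * ab + v * ac)
    except np.linalg.LinAlgError:
        pass
    return min(np.linalg.norm(p - q) for q in candidates)


class TestPointToSurface:
    def test_mesh_vertex_has_zero_distance(self, sphere10):
        d = point_to_surface_distances(sphere10.vertices[:5], sphere10)
        assert d.max() < 1e-12

    def test_height_above_large_triangle(self):
        tri = TriangleMesh(np.array([[0.0, 0, 0], [10, 0, 0], [0, 10, 0]]),
                           np.array([[0, 1, 2]]))
        d = point_to_surface_distances(np.array([[2.0, 2.0, 3.5]]), tri)
        assert abs(d[0] - 3.5) < 1e-12

    def test_matches_exhaustive_triangle_oracle(self, rng, coarse_femur):
        pts = rng.normal(0, 40, (100, 3))
        d = point_to_surface_distances(pts, coarse_femur)
        tris = coarse_femur.triangles
        for i in range(len(pts)):
            oracle = min(oracle_point_triangle_distance(pts[i], t) for t in tris)
            assert abs(d[i] - oracle) < 1e-9


class TestMad:
    def test_zero_for_identical_meshes(self, sphere10):
        assert mean_absolute_distance(sphere10, sphere10, 2000, 0) < 1e-9

    def test_concentric_spheres_offset(self, sphere10, sphere105):
        mad = mean_absolute_distance(sphere10, sphere105, 4000, 0)
        assert abs(mad - 0.5) < 0.02

    def test_exactly_symmetric_in_arguments(self, sphere10, sphere105):
        assert mean_absolute_distance(sphere10, sphere105, 1000, 7) \
            == mean_absolute_distance(sphere105, sphere10, 1000, 7)

    def test_monotone_in_translation_offset(self, cube10):
        mads = []
        for dx in (0.5, 1.0, 2.0, 4.0):
            other = make_cube(offset=(dx, 0, 0))
            mads.append(mean_absolute_distance(cube10, other, 2000, 0))
        assert all(np.diff(mads) > 0)

    def test_translated_cube_matches_integration_oracle(self, cube10):
        # direct numerical integration of the definition on the unit-cube
        # pair: exact distance from a face grid to the other box's surface
        def dist_to_box(p, lo, hi):
            q = np.clip(p, lo, hi)
            outside = np.linalg.norm(p - q, axis=-1)
            inside = np.minimum(np.minimum(
                np.minimum(p[..., 0] - lo[0], hi[0] - p[..., 0]),
                np.minimum(p[..., 1] - lo[1], hi[1] - p[..., 1])),
                np.minimum(p[..., 2] - lo[2], hi[2] - p[..., 2]))
            return np.where(outside > 0, outside, inside)

        def directed(lo_a, hi_a, lo_b, hi_b, n=60):
            total, area = 0.0, 0.0
            g = (np.arange(n) + 0.5) / n
            for axis in range(3):
                for side in (0, 1):
                    u, v = np.meshgrid(g, g, indexing="ij")
                    face = np.zeros((n, n, 3))
                    ax_other = [i for i in range(3) if i != axis]
                    face[..., ax_other[0]] = lo_a[ax_other[0]] + u * (
                        hi_a[ax_other[0]] - lo_a[ax_other[0]])
                    face[..., ax_other[1]] = lo_a[ax_other[1]] + v * (
                        hi_a[ax_other[1]] - lo_a[ax_other[1]])
                    face[..., axis] = (lo_a, hi_a)[side][axis]
                    total += dist_to_box(face, lo_b, hi_b).mean()
                    area += 1.0
            return total / area

        lo_a, hi_a = np.zeros(3), np.full(3, 10.0)
        lo_b, hi_b = np.array([1.0, 0, 0]), np.array([11.0, 10, 10])
        oracle = 0.5 * (directed(lo_a, hi_a, lo_b, hi_b)
                        + directed(lo_b, hi_b, lo_a, hi_a))
        other = make_cube(offset=(1.0, 0, 0))
        mad = mean_absolute_distance(cube10, other, 20000, 1)
        assert abs(mad - oracle) < 0.02


class TestVoxelize:
    def test_unit_cube_counts_exactly(self, cube10):
        grid = ImageGrid([0.5, 0.5, 0.5], [1, 1, 1], (10, 10, 10))
        occ = voxelize_closed_mesh(cube10, grid)
        assert occ.sum() == 1000

    def test_sphere_volume_within_two_percent(self, sphere10):
        lo = sphere10.vertices.min(axis=0) - 1.0
        hi = sphere10.vertices.max(axis=0) + 1.0
        dims = tuple(np.ceil((hi - lo) / 0.5).astype(int))
        grid = ImageGrid(lo + 0.25, [0.5] * 3, dims)
        vol = voxelize_closed_mesh(sphere10, grid).sum() * grid.voxel_volume
        analytic = 4 / 3 * np.pi * 1000.0
        assert abs(vol - analytic) / analytic < 0.02

    def test_voxel_volume_converges_first_order(self, sphere10):
        analytic = 4 / 3 * np.pi * 1000.0
        errs = []
        for h in (2.0, 1.0, 0.5):
            lo = sphere10.vertices.min(axis=0) - h
            hi = sphere10.vertices.max(axis=0) + h
            dims = tuple(np.ceil((hi - lo) / h).astype(int))
            grid = ImageGrid(lo + h / 2, [h] * 3, dims)
            vol = voxelize_closed_mesh(sphere10, grid).sum() * grid.voxel_volume
            errs.append(abs(vol - analytic))
        assert errs[2] < errs[0]

    def test_open_mesh_rejected_with_boundary_count(self, sphere10):
        open_mesh = TriangleMesh(sphere10.vertices, sphere10.faces[1:])
        grid = ImageGrid([0, 0, 0], [1, 1, 1], (5, 5, 5))
        with pytest.raises(GeometryError, match="3 edge"):
            voxelize_closed_mesh(open_mesh, grid)

    def test_contains_points(self, sphere10):
        inside = np.array([[0.0, 0, 0], [5, 5, 5], [9.9, 0, 0]])
        outside = np.array([[10.5, 0, 0], [20, 20, 20]])
        assert contains_points(sphere10, inside).all()
        assert not contains_points(sphere10, outside).any()


class TestDice:
    def test_identical_meshes_give_one(self, sphere10):
        assert abs(dice_index(sphere10, sphere10, 0.5) - 1.0) < 1e-12

    def test_disjoint_meshes_give_zero(self, cube10):
        far = make_cube(offset=(100, 0, 0))
        assert dice_index(cube10, far, 1.0) == 0.0

    def test_half_offset_cubes(self, cube10):
        other = make_cube(offset=(5.0, 0, 0))
        assert abs(dice_index(cube10, other, 0.25) - 0.5) < 0.005

    def test_symmetric_in_arguments(self, sphere10, sphere105):
        assert abs(dice_index(sphere10, sphere105, 0.5)
                   - dice_index(sphere105, sphere10, 0.5)) < 1e-12

    def test_grid_convergence_on_smooth_shapes(self, sphere10):
        moved = TriangleMesh(sphere10.vertices + np.array([0.7, 0.3, 0.2]),
                             sphere10.faces)
        d1 = dice_index(sphere10, moved, 1.0)
        d2 = dice_index(sphere10, moved, 0.5)
        assert abs(d1 - d2) < 0.005


class TestCompareModels:
    def test_identical_inputs(self, sphere10):
        rep = compare_models(sphere10, sphere10,
                             MetricSettings(0.5, 2000, 0))
        assert rep.mad_mm < 1e-9 and rep.dice == 1.0

    def test_translated_cube_pair(self, cube10):
        other = make_cube(offset=(1.0, 0, 0))
        rep = compare_models(cube10, other, MetricSettings(0.25, 5000, 0))
        # analytic overlap: 900 mm^3 of 1000 each -> Dice 0.9
        assert abs(rep.dice - 0.9) < 0.01
        assert 0.2 < rep.mad_mm < 0.6

    def test_report_echoes_settings(self, sphere10):
        rep = compare_models(sphere10, sphere10, MetricSettings(0.75, 1500, 3))
        assert rep.voxel_size_mm == 0.75
        assert rep.sample_count == 1500

    def test_area_weighted_sampling_lands_on_surface(self, rng, coarse_femur):
        pts, _ = sample_surface(coarse_femur, 500, rng)
        assert point_to_surface_distances(pts, coarse_femur).max() < 1e-9
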