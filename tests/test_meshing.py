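"""Surface reconstruction: isosurface, smoothing, remeshing, hulls."""

import numpy as np
import pytest
import trimesh

from spiculo.geometry import (
    as_mesh,
    euler_characteristic,
    is_watertight,
    signed_volume,
    surface_area,
)
from spiculo.masks import BinaryMask, voxelize
from spiculo.meshing import (
    concave_hull,
    convex_hull,
    mesh_isosurface,
    reconstruct,
    remesh_isotropic,
    smooth_mesh,
)

CUBE_CORNERS = np.array(
    [[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0],
     [0, 0, 1], [1, 0, 1], [0, 1, 1], [1, 1, 1]],
    dtype=float,
)


def cube_mask(n=11):
    values = np.zeros((n + 2, n + 2, n + 2), np.uint8)
    values[1:-1, 1:-1, 1:-1] = 1
    return BinaryMask(values, (1.0, 1.0, 1.0))


class TestIsosurfaceM1:
    def test_cube_against_analytic_isolevel_cuboid(self):
        # at isovalue 0.9 the surface sits 0.1 voxel outside the outermost
        # foreground centers: an 11-voxel cube meshes as a 10.2 mm cuboid
        mesh = mesh_isosurface(cube_mask(11))
        side = 10.2
        assert is_watertight(mesh)
        assert signed_volume(mesh) == pytest.approx(side**3, rel=0.05)
        assert surface_area(mesh) == pytest.approx(6 * side**2, rel=0.10)

    def test_single_voxel_mesh_is_closed_and_tiny(self):
        values = np.zeros((3, 3, 3), np.uint8)
        values[1, 1, 1] = 1
        mesh = mesh_isosurface(BinaryMask(values, (1.0, 1.0, 1.0)))
        assert is_watertight(mesh)
        assert 0 < signed_volume(mesh) < 1.0

    def test_suite_masks_genus_zero(self, small_masks):
        for mask in small_masks:
            assert euler_characteristic(mesh_isosurface(mask)) == 2

    def test_invalid_isovalue(self, small_masks):
        with pytest.raises(ValueError):
            mesh_isosurface(small_masks[0], isovalue=1.5)


class TestSmoothM2:
    def test_quantity_zero_is_identity(self, icosphere):
        out = smooth_mesh(icosphere, quantity=0.0)
        assert np.array_equal(out.vertices, icosphere.vertices)

    def test_icosphere_barely_moves(self, icosphere):
        out = smooth_mesh(icosphere)
        disp = np.linalg.norm(out.vertices - icosphere.vertices, axis=1)
        assert disp.max() < 0.005 * 10.0  # < 0.5 % of the radius

    def test_spiculated_area_strictly_decreases(self, small_masks):
        m1 = mesh_isosurface(small_masks[0])  # d = 11, most spiculated
        m2 = smooth_mesh(m1)
        assert surface_area(m2) < surface_area(m1)
        assert is_watertight(m2)

    def test_volume_within_5_percent_of_m1(self, small_masks):
        for mask in small_masks:
            m1 = mesh_isosurface(mask)
            m2 = smooth_mesh(m1)
            assert signed_volume(m2) == pytest.approx(signed_volume(m1), rel=0.05)


class TestRemeshM3:
    def test_on_target_mesh_is_near_fixed_point(self):
        ico = trimesh.creation.icosphere(subdivisions=3, radius=10.0)
        mesh = as_mesh(ico.vertices, ico.faces)
        edges = np.linalg.norm(
            mesh.vertices[mesh.edges_unique[:, 0]]
            - mesh.vertices[mesh.edges_unique[:, 1]],
            axis=1,
        )
        target = float(np.median(edges))
        out = remesh_isotropic(mesh, target_edge=target)
        assert len(out.vertices) == len(mesh.vertices)
        # vertices move by well under 1 % of the object scale
        assert np.abs(signed_volume(out) - signed_volume(mesh)) < 0.01 * signed_volume(mesh)

    def test_dense_sphere_coarsens_toward_target(self):
        dense = trimesh.creation.icosphere(subdivisions=5, radius=10.0)
        mesh = as_mesh(dense.vertices, dense.faces)
        out = remesh_isotropic(mesh, target_edge=2.0)
        assert is_watertight(out)
        assert len(out.vertices) < len(mesh.vertices)
        assert signed_volume(out) == pytest.approx(4 / 3 * np.pi * 1000, rel=0.01)
        med_in = np.median(
            np.linalg.norm(
                mesh.vertices[mesh.edges_unique[:, 0]]
                - mesh.vertices[mesh.edges_unique[:, 1]],
                axis=1,
            )
        )
        med_out = np.median(
            np.linalg.norm(
                out.vertices[out.edges_unique[:, 0]]
                - out.vertices[out.edges_unique[:, 1]],
                axis=1,
            )
        )
        assert abs(med_out - 2.0) < abs(med_in - 2.0)

    def test_volume_within_5_percent_of_m1(self, small_masks):
        for mask in small_masks:
            m1 = mesh_isosurface(mask)
            m3 = remesh_isotropic(m1)
            assert is_watertight(m3)
            assert signed_volume(m3) == pytest.approx(signed_volume(m1), rel=0.05)


class TestHulls:
    def test_cube_corners(self):
        hull = convex_hull(CUBE_CORNERS * 2.0)
        assert surface_area(hull) == pytest.approx(24.0, abs=1e-9)
        assert signed_volume(hull) == pytest.approx(8.0, abs=1e-9)

    def test_hull_of_hull_identical(self, rng):
        pts = rng.normal(size=(100, 3))
        h1 = convex_hull(pts)
        h2 = convex_hull(np.asarray(h1.vertices))
        assert surface_area(h2) == pytest.approx(surface_area(h1), rel=1e-12)
        assert signed_volume(h2) == pytest.approx(signed_volume(h1), rel=1e-12)

    def test_coplanar_points_rejected(self):
        flat = np.column_stack([np.arange(10.0), np.arange(10.0) ** 2, np.zeros(10)])
        with pytest.raises(ValueError):
            convex_hull(flat)
        with pytest.raises(ValueError):
            concave_hull(flat, 1.0)

    def test_convex_input_shrink_one_equals_hull(self):
        out = concave_hull(CUBE_CORNERS, 1.0)
        hull = convex_hull(CUBE_CORNERS)
        assert surface_area(out) == pytest.approx(surface_area(hull), rel=1e-9)
        assert signed_volume(out) == pytest.approx(signed_volume(hull), rel=1e-9)

    def test_shrink_zero_is_convex_hull_with_minimal_area(self, rng):
        a = rng.normal(size=(150, 3)) * 0.5
        b = rng.normal(size=(150, 3)) * 0.5 + [4, 0, 0]
        bar = np.column_stack(
            [rng.uniform(0, 4, 80), rng.normal(size=80) * 0.15, rng.normal(size=80) * 0.15]
        )
        pts = np.vstack([a, b, bar])
        tight = concave_hull(pts, 1.0)
        convex = concave_hull(pts, 0.0)
        hull = convex_hull(pts)
        assert surface_area(convex) == pytest.approx(surface_area(hull), rel=1e-9)
        # two-lobed cloud: the concave boundary excludes the waist region
        assert signed_volume(tight) < signed_volume(convex)
        assert is_watertight(tight)


class TestReconstructDispatch:
    def test_all_methods_watertight_on_suite_mask(self, small_masks):
        mask = small_masks[1]
        for method in ("M1", "M2", "M3", "M4"):
            mesh = reconstruct(mask, method)
            assert is_watertight(mesh), method

    def test_area_ordering_hull_concave_isosurface(self, small_masks):
        mask = small_masks[0]
        m1 = mesh_isosurface(mask)
        m4 = reconstruct(mask, "M4")
        hull = convex_hull(np.asarray(m1.vertices))
        assert surface_area(hull) <= surface_area(m4) + 1e-9
        assert surface_area(m4) <= surface_area(m1) + 1e-9

    def test_unknown_method(self, small_masks):
        with pytest.raises(ValueError):
            reconstruct(small_masks[0], "M9")
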