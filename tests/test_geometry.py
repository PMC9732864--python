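"""Geometry: lesion distances, geodesics, grid extrapolation."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ecogdist import (
    CorticalSurface,
    ElectrodeArray,
    LesionVolume,
    bipolar_midpoint,
    center_of_mass,
    construct_array_on_surface,
    euclidean_com_distance,
    euclidean_edge_distance,
    extrapolate_grid,
    geodesic_distance,
    lesion_volume_cm3,
    make_surface,
)
from conftest import ball_lesion


def random_lesion(rng, n_vox=50, shape=(12, 12, 12), voxel=1.5, origin=(-5.0, 3.0, -8.0)):
    mask = np.zeros(shape, dtype=bool)
    flat = rng.choice(np.prod(shape), size=n_vox, replace=False)
    mask.ravel()[flat] = True
    affine = np.eye(4)
    affine[:3, :3] *= voxel
    affine[:3, 3] = origin
    return LesionVolume(mask=mask, affine=affine)


class TestLesionBasics:
    def test_com_single_voxel_identity_affine(self):
        mask = np.zeros((10, 10, 10), bool)
        mask[5, 5, 5] = True
        les = LesionVolume(mask, np.eye(4))
        assert np.allclose(center_of_mass(les), [5, 5, 5])

    def test_com_two_voxel_midpoint(self):
        mask = np.zeros((12, 3, 3), bool)
        mask[0, 0, 0] = mask[10, 0, 0] = True
        les = LesionVolume(mask, np.eye(4))
        assert np.allclose(center_of_mass(les), [5, 0, 0])

    def test_com_matches_bruteforce_enumeration(self, rng):
        les = random_lesion(rng)
        # brute force: explicit list of world voxel centres
        pts = []
        for ijk in np.argwhere(les.mask):
            pts.append(les.affine[:3, :3] @ ijk + les.affine[:3, 3])
        assert np.allclose(center_of_mass(les), np.mean(pts, axis=0), atol=1e-12)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="foreground"):
            LesionVolume(np.zeros((3, 3, 3), bool), np.eye(4))

    @pytest.mark.parametrize(
        "n_vox,voxel,expected",
        [(1000, 1.0, 1.0), (1, 2.0, 0.008)],
    )
    def test_volume_conversion(self, n_vox, voxel, expected):
        mask = np.zeros((12, 12, 12), bool)
        mask.ravel()[:n_vox] = True
        affine = np.eye(4) * voxel
        affine[3, 3] = 1.0
        les = LesionVolume(mask, affine)
        assert lesion_volume_cm3(les) == pytest.approx(expected)

    def test_volume_matches_loop_count(self, rng):
        les = random_lesion(rng, n_vox=37, voxel=1.5)
        count = sum(
            1 for i in range(12) for j in range(12) for k in range(12) if les.mask[i, j, k]
        )
        assert lesion_volume_cm3(les) == pytest.approx(count * 1.5**3 / 1000.0)


class TestEdgeAndComDistance:
    def test_point_on_lesion_voxel_is_zero(self):
        mask = np.zeros((5, 5, 5), bool)
        mask[2, 2, 2] = True
        les = LesionVolume(mask, np.eye(4))
        assert euclidean_edge_distance([2.0, 2.0, 2.0], les) == 0.0

    def test_three_four_five_triangle(self, origin_lesion):
        assert euclidean_edge_distance([3.0, 4.0, 0.0], origin_lesion) == pytest.approx(5.0)

    def test_edge_distance_matches_bruteforce_min(self, rng):
        les = random_lesion(rng, n_vox=30)
        world = les.foreground_world()
        for _ in range(200):
            p = rng.uniform(-30, 40, 3)
            brute = np.min(np.linalg.norm(world - p, axis=1))
            got = euclidean_edge_distance(p, les)
            if les.contains(p):
                assert got == 0.0
            else:
                assert got == pytest.approx(brute, abs=1e-12)

    def test_com_distance_cases(self, origin_lesion, rng):
        assert euclidean_com_distance([0.0, 0.0, 0.0], origin_lesion) == 0.0
        assert euclidean_com_distance([0.0, 0.0, 7.0], origin_lesion) == pytest.approx(7.0)
        les = random_lesion(rng)
        com = center_of_mass(les)
        for _ in range(20):
            p = rng.uniform(-30, 40, 3)
            assert euclidean_com_distance(p, les) == pytest.approx(
                np.linalg.norm(p - com)
            )

    def test_edge_never_farther_than_com_outside_convex_lesion(self, rng):
        les = ball_lesion(radius_vox=4)
        for _ in range(200):
            p = rng.uniform(-40, 40, 3)
            if les.contains(p):
                continue
            assert euclidean_edge_distance(p, les) <= euclidean_com_distance(p, les) + 1e-12

    def test_nonfinite_point_rejected(self, origin_lesion):
        with pytest.raises(ValueError):
            euclidean_edge_distance([np.nan, 0, 0], origin_lesion)


class TestBipolarMidpoint:
    def test_simple_cases(self):
        assert np.allclose(bipolar_midpoint([0, 0, 0], [10, 0, 0]), [5, 0, 0])
        a = np.array([3.0, -2.0, 7.0])
        assert np.allclose(bipolar_midpoint(a, a), a)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-100, 100), min_size=6, max_size=6))
    def test_componentwise_mean(self, vals):
        a, b = np.array(vals[:3]), np.array(vals[3:])
        mid = bipolar_midpoint(a, b)
        for i in range(3):
            assert mid[i] == pytest.approx((a[i] + b[i]) / 2, abs=1e-9)


class TestGeodesic:
    def test_degenerate_path_equals_com_to_entry(self, sphere50, origin_lesion):
        p_idx = sphere50.nearest_vertex(center_of_mass(origin_lesion))
        electrode = sphere50.vertices[p_idx]
        d = geodesic_distance(electrode, origin_lesion, sphere50)
        assert d == pytest.approx(np.linalg.norm(electrode), abs=1e-9)

    def test_sphere_great_circle(self, sphere50, origin_lesion, rng):
        P = sphere50.vertices[sphere50.nearest_vertex(center_of_mass(origin_lesion))]
        for i in rng.integers(0, len(sphere50.vertices), 10):
            v = sphere50.vertices[i]
            theta = np.arccos(np.clip(v @ P / 2500.0, -1, 1))
            if theta < 0.3:
                continue
            expected = 50.0 + 50.0 * theta
            got = geodesic_distance(v, origin_lesion, sphere50)
            assert got == pytest.approx(expected, rel=0.02)

    def test_tiny_mesh_equals_exhaustive_path_enumeration(self, origin_lesion):
        # octahedron at radius 30: all simple paths enumerable by hand
        r = 30.0
        verts = np.array(
            [[r, 0, 0], [-r, 0, 0], [0, r, 0], [0, -r, 0], [0, 0, r], [0, 0, -r]]
        )
        faces = np.array(
            [[0, 2, 4], [2, 1, 4], [1, 3, 4], [3, 0, 4],
             [2, 0, 5], [1, 2, 5], [3, 1, 5], [0, 3, 5]]
        )
        surf = CorticalSurface(verts, faces)
        edges = {(a, b) for f in faces for a, b in
                 [(f[0], f[1]), (f[1], f[2]), (f[2], f[0])]}
        edges |= {(b, a) for a, b in edges}

        def all_paths_min(src, dst):
            best = [np.inf]

            def walk(node, seen, acc):
                if acc >= best[0]:
                    return
                if node == dst:
                    best[0] = acc
                    return
                for a, b in edges:
                    if a == node and b not in seen:
                        w = np.linalg.norm(verts[a] - verts[b])
                        walk(b, seen | {b}, acc + w)

            walk(src, {src}, 0.0)
            return best[0]

        p_idx = surf.nearest_vertex(center_of_mass(origin_lesion))
        for target in range(6):
            d = geodesic_distance(verts[target], origin_lesion, surf, n_ring=1)
            l1 = np.linalg.norm(verts[p_idx])
            assert d == pytest.approx(l1 + all_paths_min(p_idx, target), abs=1e-9)

    def test_geodesic_at_least_com_distance_on_sphere(self, sphere50, origin_lesion, rng):
        # straight line is shortest: geodesic >= Euclidean COM distance
        for i in rng.integers(0, len(sphere50.vertices), 20):
            v = sphere50.vertices[i]
            assert geodesic_distance(v, origin_lesion, sphere50) >= (
                euclidean_com_distance(v, origin_lesion) - 0.5
            )

    def test_far_point_raises_with_label(self, sphere50, origin_lesion):
        with pytest.raises(ValueError, match="chA"):
            geodesic_distance(
                [90.0, 0.0, 0.0], origin_lesion, sphere50, snap_tol=1.0, label="chA"
            )

    def test_disconnected_mesh_rejected(self):
        # two separate triangles cannot form a valid cortical surface
        verts = np.array(
            [[0, 0, 0], [1, 0, 0], [0, 1, 0], [10, 10, 0], [11, 10, 0], [10, 11, 0]],
            dtype=float,
        )
        faces = np.array([[0, 1, 2], [3, 4, 5]])
        with pytest.raises(ValueError, match="connected"):
            CorticalSurface(verts, faces)

    def test_rigid_motion_invariance(self, rng):
        les = ball_lesion(radius_vox=3)
        surf = make_surface("sphere", min_vertices=600, radius=40.0)
        p = surf.vertices[17]
        d_e = euclidean_edge_distance(p, les)
        d_c = euclidean_com_distance(p, les)
        d_g = geodesic_distance(p, les, surf)
        # random rotation + translation applied jointly
        q = np.linalg.qr(rng.normal(size=(3, 3)))[0]
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        t = rng.uniform(-50, 50, 3)
        aff = np.eye(4)
        aff[:3, :3] = q @ les.affine[:3, :3]
        aff[:3, 3] = q @ les.affine[:3, 3] + t
        les2 = LesionVolume(les.mask.copy(), aff)
        surf2 = CorticalSurface(surf.vertices @ q.T + t, surf.faces.copy())
        p2 = q @ p + t
        assert euclidean_edge_distance(p2, les2) == pytest.approx(d_e, rel=1e-6)
        assert euclidean_com_distance(p2, les2) == pytest.approx(d_c, rel=1e-6)
        assert geodesic_distance(p2, les2, surf2) == pytest.approx(d_g, rel=1e-6)


def strip_array(coords, visible, n=4):
    return ElectrodeArray("S", 1, n, coords, np.asarray(visible, bool))


class TestExtrapolateGrid:
    def test_planar_strip_exact_lattice(self, plane):
        coords = np.full((4, 3), np.nan)
        coords[0] = [0, 0, 0]
        coords[1] = [10, 0, 0]
        out = extrapolate_grid(strip_array(coords, [1, 1, 0, 0]), plane)
        assert np.allclose(out.coordinates[2], [20, 0, 0], atol=1e-6)
        assert np.allclose(out.coordinates[3], [30, 0, 0], atol=1e-6)

    def test_planar_grid_closed_form_lattice(self, plane):
        # full first row plus one column electrode fixes the orientation
        coords = np.full((16, 3), np.nan)
        for c in range(4):
            coords[c] = [10.0 * c, 0.0, 0.0]
        coords[4] = [0.0, 10.0, 0.0]
        vis = np.zeros(16, bool)
        vis[:5] = True
        out = extrapolate_grid(ElectrodeArray("G", 4, 4, coords, vis), plane)
        expected = np.array(
            [[10.0 * c, 10.0 * r, 0.0] for r in range(4) for c in range(4)]
        )
        assert np.abs(out.coordinates - expected).max() < 1e-6

    def test_sphere_strip_spacing_and_snap(self, sphere80):
        arr = construct_array_on_surface(
            sphere80, [0, 0, 80.0], [1.0, 0.0, 0.0], 1, 8, array_id="S8"
        )
        hidden = arr.coordinates.copy()
        hidden[2:] = np.nan
        vis = np.zeros(8, bool)
        vis[:2] = True
        out = extrapolate_grid(
            ElectrodeArray("S8", 1, 8, hidden, vis), sphere80
        )
        chords = np.linalg.norm(np.diff(out.coordinates, axis=0), axis=1)
        assert np.all(np.abs(chords - 10.0) <= 0.2)
        radii = np.linalg.norm(out.coordinates, axis=1)
        assert np.all(np.abs(radii - 80.0) <= 1.0)

    def test_idempotent(self, sphere80):
        arr = construct_array_on_surface(
            sphere80, [0, 0, 80.0], [0.0, 1.0, 0.0], 4, 4, array_id="G"
        )
        hidden = arr.coordinates.copy()
        vis = np.ones(16, bool)
        for i in (10, 11, 14, 15):
            hidden[i] = np.nan
            vis[i] = False
        filled = extrapolate_grid(
            ElectrodeArray("G", 4, 4, hidden, vis), sphere80, chord_tol=1.0
        )
        again = extrapolate_grid(filled, sphere80, chord_tol=1.0)
        assert np.array_equal(filled.coordinates, again.coordinates)

    def test_too_few_visible_rejected(self):
        coords = np.full((4, 3), np.nan)
        coords[0] = [0, 0, 0]
        with pytest.raises(ValueError, match="visible"):
            strip_array(coords, [1, 0, 0, 0])

    def test_no_adjacent_pair_rejected(self, plane):
        coords = np.full((4, 3), np.nan)
        coords[0] = [0, 0, 0]
        coords[2] = [20, 0, 0]
        with pytest.raises(ValueError, match="adjacent"):
            extrapolate_grid(strip_array(coords, [1, 0, 1, 0]), plane)

    def test_visible_electrode_off_surface_rejected(self, plane):
        coords = np.full((4, 3), np.nan)
        coords[0] = [0, 0, 30.0]  # 30 mm above the sheet
        coords[1] = [10, 0, 0]
        with pytest.raises(ValueError, match="surface"):
            extrapolate_grid(strip_array(coords, [1, 1, 0, 0]), plane)

    def test_placement_infeasible_on_tiny_surface(self):
        tiny = make_surface("plane", extent=25.0, spacing=5.0)
        coords = np.full((8, 3), np.nan)
        coords[0] = [-10, 0, 0]
        coords[1] = [0, 0, 0]
        with pytest.raises(ValueError, match="infeasible|chord"):
            extrapolate_grid(
                ElectrodeArray("S", 1, 8, coords, np.array([1, 1, 0, 0, 0, 0, 0, 0], bool)),
                tiny,
            )

    def test_visible_electrodes_never_move(self, sphere80):
        arr = construct_array_on_surface(
            sphere80, [10, 5, 79.0], [1.0, 0.5, 0.0], 4, 5, array_id="G45"
        )
        hidden = arr.coordinates.copy()
        vis = np.ones(20, bool)
        for c in (3, 4):
            for r in range(4):
                i = r * 5 + c
                hidden[i] = np.nan
                vis[i] = False
        out = extrapolate_grid(
            ElectrodeArray("G45", 4, 5, hidden, vis), sphere80, chord_tol=1.0
        )
        kept = ~np.isnan(hidden).any(axis=1)
        assert np.array_equal(out.coordinates[kept], arr.coordinates[kept])
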