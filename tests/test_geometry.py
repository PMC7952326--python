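"""Chamber geometry: boundary loops, hole filling, areas, volumes,
point status."""

import numpy as np
import pytest

from eamkit.errors import TopologyError
from eamkit.geometry import (fill_holes, get_anatomical_structures, get_area,
                             get_volume, point_status, points_inside_mesh,
                             _ray_crossings)
from eamkit.model import SurfaceMesh
from eamkit.synth import ChamberSpec, make_chamber_mesh

SPHERE_AREA_CM2 = 4 * np.pi * 30.0 ** 2 / 100.0  # = 113.097...
SPHERE_VOL_CM3 = 4 / 3 * np.pi * 30.0 ** 3 / 1000.0


class TestBoundaryLoops:
    def test_closed_surface_has_no_loops(self, closed_icosphere):
        assert get_anatomical_structures(closed_icosphere) == []

    def test_five_holes_give_five_disjoint_loops(self, planar_study):
        ud, _ = planar_study
        loops = get_anatomical_structures(ud.surface)
        assert len(loops) == 5
        all_vertices = np.concatenate([L.vertex_indices for L in loops])
        assert len(all_vertices) == len(np.unique(all_vertices))
        # every free edge belongs to exactly one loop
        n_free = len(ud.surface.free_edges())
        assert sum(len(L.vertex_indices) for L in loops) == n_free

    def test_loops_sorted_by_descending_perimeter(self, planar_study):
        ud, _ = planar_study
        perims = [L.perimeter for L in get_anatomical_structures(ud.surface)]
        assert perims == sorted(perims, reverse=True)

    def test_circular_rim_perimeter_near_circle(self):
        """A hole whose rim is a planar circle of radius 5 mm reports a
        perimeter equal to its rim polygon's edge-length sum (oracle) and
        within 5% of 2*pi*5 mm."""
        # annulus between radii 5 and 15 mm: inner rim is the circular hole
        n_seg = 64
        ang = np.linspace(0, 2 * np.pi, n_seg, endpoint=False)
        rings = [5.0, 10.0, 15.0]
        verts = np.vstack([
            np.column_stack([r * np.cos(ang), r * np.sin(ang),
                             np.zeros(n_seg)])
            for r in rings])
        tris = []
        for k in range(len(rings) - 1):
            base0, base1 = k * n_seg, (k + 1) * n_seg
            for i in range(n_seg):
                j = (i + 1) % n_seg
                tris.append([base0 + i, base1 + i, base0 + j])
                tris.append([base0 + j, base1 + i, base1 + j])
        mesh = SurfaceMesh(verts, np.asarray(tris))
        loops = get_anatomical_structures(mesh)
        inner = min(loops, key=lambda L: L.perimeter)
        pts = mesh.vertices[inner.vertex_indices]
        poly_perim = np.linalg.norm(np.roll(pts, -1, axis=0) - pts,
                                    axis=1).sum()
        assert inner.perimeter == pytest.approx(poly_perim)
        assert inner.perimeter == pytest.approx(2 * np.pi * 5.0, rel=0.05)

    def test_nonmanifold_edge_rejected(self):
        v = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1],
                      [0, -1, 0]], dtype=float)
        t = np.array([[0, 1, 2], [0, 1, 3], [0, 1, 4]])
        with pytest.raises(TopologyError):
            SurfaceMesh(v, t)


class TestFillHoles:
    def test_idempotent_on_closed_mesh(self, closed_icosphere):
        filled = fill_holes(closed_icosphere)
        assert filled.n_vertices == closed_icosphere.n_vertices
        assert filled.n_triangles == closed_icosphere.n_triangles

    def test_one_new_vertex_per_hole(self, planar_study):
        ud, _ = planar_study
        filled = fill_holes(ud.surface)
        assert filled.n_vertices == ud.surface.n_vertices + 5
        assert filled.is_closed()

    def test_planar_fan_reproduces_the_plane(self, square_with_hole):
        loops = get_anatomical_structures(square_with_hole)
        hole = min(loops, key=lambda L: L.perimeter)  # inner triangle
        filled = fill_holes(square_with_hole, loops=[hole])
        assert filled.total_area() == pytest.approx(1.0, abs=1e-12)


class TestArea:
    def test_unit_square_both_methods(self):
        sq = SurfaceMesh(np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0],
                                   [0, 1, 0]], float),
                         np.array([[0, 1, 2], [0, 2, 3]]))
        assert get_area(sq, "nofill", units="mm2") == pytest.approx(1.0)

    def test_square_with_hole_nofill(self, square_with_hole):
        assert get_area(square_with_hole, "nofill",
                        units="mm2") == pytest.approx(0.875)

    def test_icosphere_area_within_2pct_of_analytic(self, closed_icosphere):
        assert get_area(closed_icosphere, "nofill") == pytest.approx(
            SPHERE_AREA_CM2, rel=0.02)

    def test_fill_at_least_nofill_and_additive(self, planar_study):
        ud, _ = planar_study
        nofill = get_area(ud.surface, "nofill", units="mm2")
        fill = get_area(ud.surface, "fill", units="mm2")
        fan = sum(L.area * 100.0  # loop areas are cm^2
                  for L in get_anatomical_structures(ud.surface))
        assert fill >= nofill
        assert fill - nofill == pytest.approx(fan, rel=1e-12)

    def test_unknown_method_rejected(self, closed_icosphere):
        with pytest.raises(ValueError):
            get_area(closed_icosphere, "magic")


class TestVolume:
    def test_unit_cube(self, unit_cube):
        assert get_volume(unit_cube, units="mm3") == pytest.approx(1.0,
                                                                   abs=1e-12)

    def test_unit_tetrahedron(self, unit_tetrahedron):
        assert get_volume(unit_tetrahedron,
                          units="mm3") == pytest.approx(1 / 6, abs=1e-12)

    def test_volume_ignores_input_winding(self, unit_cube):
        flipped = SurfaceMesh(unit_cube.vertices,
                              unit_cube.triangles[:, ::-1])
        assert get_volume(flipped, units="mm3") == pytest.approx(1.0)

    def test_icosphere_volume_within_2pct_of_analytic(self, closed_icosphere):
        assert get_volume(closed_icosphere) == pytest.approx(SPHERE_VOL_CM3,
                                                             rel=0.02)

    def test_translation_invariance(self, closed_icosphere):
        v0 = get_volume(closed_icosphere)
        moved = SurfaceMesh(closed_icosphere.vertices + [123.0, -456.0, 789.0],
                            closed_icosphere.triangles)
        assert abs(get_volume(moved) - v0) / v0 < 1e-9

    def test_open_chamber_volume_uses_filled_mesh(self, planar_study):
        ud, _ = planar_study
        assert 0 < get_volume(ud.surface) < SPHERE_VOL_CM3 * 1.2


class TestRefinementConvergence:
    def test_error_strictly_shrinks_with_subdivision(self):
        errs_a, errs_v = [], []
        for s in (2, 3, 4):
            m = make_chamber_mesh(ChamberSpec(radius=30.0, subdivisions=s,
                                              holes=(), jitter=0.0))
            errs_a.append(abs(get_area(m, "nofill") - SPHERE_AREA_CM2))
            errs_v.append(abs(get_volume(m) - SPHERE_VOL_CM3))
        assert errs_a[0] > errs_a[1] > errs_a[2]
        assert errs_v[0] > errs_v[1] > errs_v[2]


class TestPointStatus:
    def test_centroid_inside_far_point_outside(self, planar_study):
        ud, _ = planar_study
        closed = fill_holes(ud.surface)
        centroid = ud.surface.vertices.mean(axis=0)
        far = centroid + [0.0, 0.0, 90.0]
        inside = points_inside_mesh(np.vstack([centroid, far]), closed)
        assert inside.tolist() == [True, False]

    def test_matches_bruteforce_parity_oracle(self, planar_study):
        """200 seeded random points agree with an independent exhaustive
        ray-parity vote using different seeded directions."""
        ud, _ = planar_study
        closed = fill_holes(ud.surface)
        rng = np.random.default_rng(11)
        pts = rng.uniform(-45.0, 45.0, (200, 3))
        got = points_inside_mesh(pts, closed, seed=7)
        a, b, c = closed.triangle_corners()
        votes = np.zeros(len(pts), dtype=int)
        for s in (101, 102, 103, 104, 105):
            d = np.random.default_rng(s).normal(size=3)
            votes += _ray_crossings(pts, d, a, b, c) % 2
        assert np.array_equal(got, votes * 2 > 5)

    def test_electric_points_classified_with_distances(self, planar_study):
        ud, _ = planar_study
        res = point_status(ud)
        assert res.inside.all()  # generator puts catheters inside the shell
        assert (res.distance >= 0).all()
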