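"""Voltage metrics: area-weighted mean, exact sub-threshold areas,
histograms."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eamkit.model import SurfaceMesh, UserData
from eamkit.synth import (ChamberSpec, make_chamber_mesh,
                          simulate_voltage_field)
from eamkit.voltage import (low_voltage_area, mean_voltage,
                            triangle_area_below, voltage_histogram)


def _study_with_field(values, mesh):
    mesh = mesh.copy()
    mesh.fields["bip"] = np.asarray(values, dtype=float)
    return UserData(surface=mesh)


@pytest.fixture(scope="module")
def patch_study():
    """Chamber with one triangle-aligned 0.2 mV patch on a 2.0 mV
    background (rim vertices blended to the midpoint)."""
    mesh = make_chamber_mesh(ChamberSpec(subdivisions=3, holes=(),
                                         jitter=0.0))
    values, truth = simulate_voltage_field(mesh, [(0, 10.0, 0.2)],
                                           background=2.0)
    mesh.fields["bip"] = values
    return UserData(surface=mesh), truth


class TestTriangleClipKernel:
    def test_saturation_cases(self):
        vals = np.array([[1.0, 1.0, 1.0], [0.2, 0.2, 0.2]])
        areas = np.array([2.0, 3.0])
        below = triangle_area_below(vals, areas, 0.5)
        np.testing.assert_allclose(below, [0.0, 3.0])

    def test_halfway_split_of_symmetric_triangle(self):
        # linear field 0..1 over a triangle: area below the midpoint of
        # the two extremes via the wedge formula, checked against a dense
        # barycentric Monte Carlo estimate
        vals = np.array([[0.0, 0.0, 1.0]])
        areas = np.array([1.0])
        got = triangle_area_below(vals, areas, 0.5)[0]
        rng = np.random.default_rng(0)
        u = rng.uniform(0, 1, (200000, 2))
        flip = u.sum(axis=1) > 1
        u[flip] = 1 - u[flip]
        mc = np.mean(u[:, 1] < 0.5)  # value = third barycentric coordinate
        assert got == pytest.approx(1 - 0.25)  # {v<0.5} = 1 - (0.5)^2
        assert got == pytest.approx(mc, abs=5e-3)

    @given(st.tuples(st.floats(0, 3), st.floats(0, 3), st.floats(0, 3)),
           st.floats(-0.5, 3.5))
    @settings(max_examples=200, deadline=None)
    def test_clip_is_bounded_and_complementary(self, vals, thr):
        vals = np.array([vals])
        areas = np.array([1.7])
        below = triangle_area_below(vals, areas, thr)[0]
        assert -1e-12 <= below <= areas[0] + 1e-12
        # complement computed by negating the field
        above = triangle_area_below(-vals, areas, -thr)[0]
        if not np.any(np.isclose(vals, thr)):  # strict/limit convention
            assert below + above == pytest.approx(areas[0], rel=1e-9)

    @given(st.tuples(st.floats(0, 3), st.floats(0, 3), st.floats(0, 3)))
    @settings(max_examples=100, deadline=None)
    def test_clip_monotone_in_threshold(self, vals):
        vals = np.array([vals])
        areas = np.array([1.0])
        prev = -1.0
        for thr in np.linspace(-0.1, 3.1, 33):
            cur = triangle_area_below(vals, areas, thr)[0]
            assert cur >= prev - 1e-12
            prev = cur


class TestMeanVoltage:
    def test_uniform_field_both_methods(self, planar_study):
        ud, _ = planar_study
        mesh = ud.surface.copy()
        mesh.fields["bip"] = np.ones(mesh.n_vertices)
        uniform = UserData(surface=mesh, electric=ud.electric)
        assert mean_voltage(uniform, "map") == pytest.approx(1.0)

    def test_matches_independent_triangle_loop_oracle(self, patch_study):
        ud, _ = patch_study
        got = mean_voltage(ud, "map")
        mesh = ud.surface
        vals = mesh.fields["bip"]
        num = den = 0.0
        for tri in mesh.triangles:  # plain per-triangle loop oracle
            a, b, c = mesh.vertices[tri]
            area = 0.5 * np.linalg.norm(np.cross(b - a, c - a))
            num += area * vals[tri].mean()
            den += area
        assert got == pytest.approx(num / den, rel=1e-9)

    def test_masking_high_vertices_lowers_mean(self, patch_study):
        ud, _ = patch_study
        base = mean_voltage(ud, "map")
        mesh = ud.surface.copy()
        vals = mesh.fields["bip"].copy()
        vals[vals > base] = np.nan  # mask above-mean values
        mesh.fields["bip"] = vals
        assert mean_voltage(UserData(surface=mesh), "map") < base

    def test_egm_method_interpolates_point_voltages(self, planar_study):
        ud, _ = planar_study
        v = mean_voltage(ud, "egm")
        pv = ud.electric.voltage_bip
        pv = pv[np.isfinite(pv)]
        assert pv.min() * 0.5 < v < pv.max() * 1.5


class TestLowVoltageArea:
    def test_saturation_in_both_directions(self, closed_icosphere):
        total = closed_icosphere.total_area() / 100.0
        hi = _study_with_field(np.ones(closed_icosphere.n_vertices),
                               closed_icosphere)
        res = low_voltage_area(hi, "map", 0.5)
        assert res.low_area == 0.0
        lo = _study_with_field(np.full(closed_icosphere.n_vertices, 0.2),
                               closed_icosphere)
        res = low_voltage_area(lo, "map", 0.5)
        assert res.low_area == pytest.approx(total, rel=1e-12)
        assert res.fraction_low == pytest.approx(100.0)

    def test_triangle_aligned_patch_recovered_exactly(self, patch_study):
        ud, truth = patch_study
        res = low_voltage_area(ud, "map", truth.rim_threshold[0])
        assert res.low_area * 100.0 == pytest.approx(
            truth.patch_areas_mm2[0], rel=1e-6)

    def test_monotone_and_continuous_in_threshold(self, patch_study):
        """Monotone over the full range; continuous away from the field's
        constant levels (a uniform region is an atom of the area
        distribution, so the area necessarily jumps at its exact value)."""
        ud, _ = patch_study
        thresholds = np.linspace(0.1, 2.2, 64)
        areas = [low_voltage_area(ud, "map", t).low_area
                 for t in thresholds]
        assert all(b >= a - 1e-12 for a, b in zip(areas, areas[1:]))
        smooth = np.linspace(0.25, 1.9, 56)  # strictly between the levels
        areas_s = [low_voltage_area(ud, "map", t).low_area for t in smooth]
        jumps = np.diff(areas_s)
        assert jumps.max() < ud.surface.total_area() / 100.0 * 0.05
        assert low_voltage_area(ud, "map", 0.05).low_area == 0.0
        total = ud.surface.total_area() / 100.0
        assert low_voltage_area(ud, "map", 5.0).low_area == pytest.approx(
            total, rel=1e-12)

    def test_default_threshold_is_half_millivolt(self, patch_study):
        ud, _ = patch_study
        assert low_voltage_area(ud, "map").threshold == 0.5


class TestVoltageHistogram:
    def test_bins_conserve_total_area(self, patch_study):
        ud, _ = patch_study
        h = voltage_histogram(ud, "map", np.arange(0.0, 3.01, 0.25))
        assert h.bin_areas.sum() == pytest.approx(h.total_area, rel=1e-9)
        assert h.total_area == pytest.approx(
            ud.surface.total_area() / 100.0, rel=1e-12)

    def test_two_valued_field_fills_exactly_two_bins(self, patch_study):
        ud, truth = patch_study
        thr = truth.rim_threshold[0]
        h = voltage_histogram(ud, "map", np.array([0.0, thr, 3.0]))
        assert np.count_nonzero(h.bin_areas) == 2
        assert h.bin_areas[0] * 100.0 == pytest.approx(
            truth.patch_areas_mm2[0], rel=1e-6)

    def test_cumulative_bins_match_low_voltage_area(self, patch_study):
        ud, _ = patch_study
        thr = 0.9
        h = voltage_histogram(ud, "map", np.array([0.0, 0.3, 0.6, thr, 3.0]))
        lva = low_voltage_area(ud, "map", thr)
        assert h.bin_areas[:3].sum() == pytest.approx(lva.low_area, rel=1e-9)

    def test_non_monotone_edges_rejected(self, patch_study):
        ud, _ = patch_study
        with pytest.raises(ValueError):
            voltage_histogram(ud, "map", np.array([1.0, 0.5, 2.0]))
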