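"""Synthetic-fixture generator: chamber meshes, activation and voltage
fields, electrogram templates, determinism."""

import numpy as np
import pytest

from eamkit.geometry import get_anatomical_structures, get_area
from eamkit.synth import (ChamberSpec, EgmSpec, WaveSpec, make_chamber_mesh,
                          make_synthetic_study, simulate_activation,
                          simulate_voltage_field, synthesize_electrograms)


class TestChamberMesh:
    def test_no_holes_gives_closed_mesh(self):
        m = make_chamber_mesh(ChamberSpec(subdivisions=3, holes=(),
                                          jitter=0.0))
        assert m.is_closed()
        assert get_anatomical_structures(m) == []

    def test_five_holes_give_five_loops(self):
        m = make_chamber_mesh(ChamberSpec(subdivisions=3, jitter=0.0))
        assert len(get_anatomical_structures(m)) == 5

    def test_closed_sphere_area_matches_analytic(self):
        m = make_chamber_mesh(ChamberSpec(radius=30.0, subdivisions=4,
                                          holes=(), jitter=0.0))
        assert get_area(m, "nofill") == pytest.approx(4 * np.pi * 9.0,
                                                      rel=0.02)

    def test_overlapping_holes_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            ChamberSpec(holes=(((0, 0, 1), 0.4), ((0, 0.1, 1), 0.4)))

    def test_excessive_jitter_rejected(self):
        with pytest.raises(ValueError, match="jitter"):
            ChamberSpec(radius=30.0, jitter=5.0)


class TestActivation:
    def test_planar_tat_matches_projected_diameter(self):
        m = make_chamber_mesh(ChamberSpec(radius=30.0, subdivisions=3,
                                          holes=(), jitter=0.0))
        lat, truth = simulate_activation(m, WaveSpec(mode="planar",
                                                     speed=1.0))
        proj = m.vertices @ np.array([1.0, 0, 0])
        assert truth.tat == pytest.approx(float(proj.max() - proj.min()))
        assert truth.tat == pytest.approx(60.0, rel=0.01)

    def test_focal_source_is_earliest_with_lat_t0(self, focal_study):
        _, truth = focal_study
        lat = truth.activation.lat
        src = truth.activation.source_vertex
        assert int(np.argmin(lat)) == src
        assert lat[src] == 40.0  # the study's wave offset

    def test_doubling_speed_halves_planar_span(self):
        m = make_chamber_mesh(ChamberSpec(subdivisions=2, holes=(),
                                          jitter=0.0))
        lat1, _ = simulate_activation(m, WaveSpec(speed=1.0))
        lat2, _ = simulate_activation(m, WaveSpec(speed=2.0))
        assert np.ptp(lat2) == pytest.approx(np.ptp(lat1) / 2.0, rel=1e-12)

    def test_removed_source_vertex_rejected(self):
        m = make_chamber_mesh(ChamberSpec(subdivisions=2, jitter=0.0))
        with pytest.raises(ValueError, match="source vertex"):
            simulate_activation(m, WaveSpec(mode="focal",
                                            source_vertex=10 ** 6))


class TestVoltageField:
    def test_no_patches_gives_uniform_background(self):
        m = make_chamber_mesh(ChamberSpec(subdivisions=2, holes=(),
                                          jitter=0.0))
        v, truth = simulate_voltage_field(m, (), background=1.0)
        assert np.all(v == 1.0)
        assert truth.patch_areas_mm2 == []

    def test_patch_creates_low_voltage_region(self):
        m = make_chamber_mesh(ChamberSpec(subdivisions=3, holes=(),
                                          jitter=0.0))
        v, truth = simulate_voltage_field(m, [(0, 10.0, 0.2)],
                                          background=1.0)
        assert v.min() == 0.2
        assert truth.patch_areas_mm2[0] > 0

    def test_patch_area_bounded_by_euclidean_disc(self):
        """On a convex chamber a geodesic disc covers no more area than the
        flat disc of the same radius."""
        m = make_chamber_mesh(ChamberSpec(radius=30.0, subdivisions=4,
                                          holes=(), jitter=0.0))
        _, truth = simulate_voltage_field(m, [(0, 10.0, 0.2)],
                                          background=1.0)
        assert truth.patch_areas_mm2[0] <= np.pi * 10.0 ** 2


class TestElectrograms:
    def test_steepest_negative_slope_at_activation_time(self):
        """The unipolar template's minimum slope instant is the imposed
        activation time (dense numerical minimization oracle)."""
        m = make_chamber_mesh(ChamberSpec(subdivisions=2, holes=(),
                                          jitter=0.0))
        lat = np.full(m.n_vertices, 77.0)
        e = synthesize_electrograms(m, lat, [0], EgmSpec(fs=1000,
                                                         n_samples=256))
        t_dense = np.linspace(40.0, 120.0, 100001)
        tau, A = 5.0, 1.0
        z = (t_dense - 77.0) / tau
        u = -A * z * np.exp(-0.5 * z * z)
        slope = np.gradient(u, t_dense)
        assert t_dense[np.argmin(slope)] == pytest.approx(77.0, abs=1e-2)
        assert e.map_annot[0] == 77.0

    def test_zero_delay_cancels_bipolar(self):
        m = make_chamber_mesh(ChamberSpec(subdivisions=2, holes=(),
                                          jitter=0.0))
        lat = np.full(m.n_vertices, 60.0)
        e = synthesize_electrograms(m, lat, [0, 1],
                                    EgmSpec(delay=0.0, noise=0.0,
                                            n_samples=256))
        assert np.all(e.bip_trace == 0.0)

    def test_point_voltage_linear_in_amplitude(self):
        m = make_chamber_mesh(ChamberSpec(subdivisions=2, holes=(),
                                          jitter=0.0))
        lat = np.full(m.n_vertices, 60.0)
        e1 = synthesize_electrograms(m, lat, [0], EgmSpec(amplitude=1.0,
                                                          n_samples=256))
        e3 = synthesize_electrograms(m, lat, [0], EgmSpec(amplitude=3.0,
                                                          n_samples=256))
        assert e3.voltage_bip[0] == pytest.approx(3 * e1.voltage_bip[0])

    def test_activation_outside_trace_rejected(self):
        m = make_chamber_mesh(ChamberSpec(subdivisions=2, holes=(),
                                          jitter=0.0))
        lat = np.full(m.n_vertices, 900.0)
        with pytest.raises(ValueError, match="outside the trace"):
            synthesize_electrograms(m, lat, [0], EgmSpec(n_samples=256))


class TestDeterminism:
    def test_same_seed_bitwise_identical_studies(self):
        a, _ = make_synthetic_study(n_points=30, seed=4,
                                    egm=EgmSpec(seed=4, n_samples=256))
        b, _ = make_synthetic_study(n_points=30, seed=4,
                                    egm=EgmSpec(seed=4, n_samples=256))
        assert np.array_equal(a.surface.vertices, b.surface.vertices)
        assert np.array_equal(a.electric.bip_trace, b.electric.bip_trace)
        assert np.array_equal(a.electric.egm_x, b.electric.egm_x)

    def test_different_seed_changes_sampling(self):
        a, _ = make_synthetic_study(n_points=30, seed=4,
                                    egm=EgmSpec(seed=4, n_samples=256))
        c, _ = make_synthetic_study(n_points=30, seed=5,
                                    egm=EgmSpec(seed=5, n_samples=256))
        assert not np.array_equal(a.electric.egm_surf_x, c.electric.egm_surf_x)
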