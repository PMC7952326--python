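"""Conduction-velocity mapping: planar-wave recovery, scaling laws,
histogram conservation."""

import numpy as np
import pytest
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from eamkit.errors import MissingDataError
from eamkit.interpolate import InterpolatorSpec
from eamkit.model import ElectricData, SurfaceMesh, UserData
from eamkit.synth import (EgmSpec, WaveSpec, make_planar_sheet,
                          simulate_activation, synthesize_electrograms)
from eamkit.velocity import compute_conduction_velocity, cv_histogram


def _interior_mask(mesh, valid, margin=10.0):
    rim = mesh.is_vertex_at_rim()
    d, _ = cKDTree(mesh.vertices[rim]).query(mesh.vertices)
    return valid & (d >= margin)


class TestPlanarRecovery:
    def test_speed_and_direction_recovered_on_flat_sheet(self, sheet_study):
        ud, truth, _ = sheet_study
        cv = compute_conduction_velocity(ud)
        interior = _interior_mask(ud.surface, cv.valid)
        speeds = cv.speed[interior]
        assert np.median(speeds) == pytest.approx(1.0, rel=0.05)
        n = truth.direction
        ang = np.degrees(np.arccos(np.clip(
            np.abs(cv.direction[interior] @ n), 0, 1)))
        assert ang.mean() < 10.0

    def test_directions_are_tangential(self, sheet_study):
        ud, _, _ = sheet_study
        cv = compute_conduction_velocity(ud)
        normals = ud.surface.vertex_normals()
        dot = np.abs(np.einsum("ij,ij->i", cv.direction[cv.valid],
                               normals[cv.valid]))
        assert dot.max() < 1e-3

    def test_error_shrinks_with_sample_count_pure_rbf(self):
        """Without the polynomial tail the reconstruction is inexact and
        refines as sampling densifies (50 -> 200 sites)."""
        sheet = make_planar_sheet(21, 21, 2.0, jitter=0.4, seed=3)
        lat, _ = simulate_activation(sheet, WaveSpec(speed=1.0, t0=40.0))
        errs = []
        for n, seed in ((50, 1), (200, 1)):
            rng = np.random.default_rng(seed)
            samp = np.sort(rng.choice(sheet.n_vertices, n, replace=False))
            e = synthesize_electrograms(sheet, lat, samp,
                                        EgmSpec(seed=seed, n_samples=256))
            ud = UserData(surface=sheet, electric=e)
            cv = compute_conduction_velocity(
                ud, InterpolatorSpec(poly=False))
            interior = _interior_mask(sheet, cv.valid)
            errs.append(abs(float(np.median(cv.speed[interior])) - 1.0))
        assert errs[1] < errs[0]


class TestScalingAndInvariance:
    def test_doubled_lat_halves_speed_exactly(self, sheet_study):
        ud, _, samples = sheet_study
        cv1 = compute_conduction_velocity(ud)
        e = ud.electric
        scaled = ElectricData(
            point_ids=e.point_ids, names=e.names, tags=e.tags,
            egm_x=e.egm_x, egm_surf_x=e.egm_surf_x,
            ref_trace=e.ref_trace, bip_trace=e.bip_trace,
            uni_traces=e.uni_traces, sample_frequency=e.sample_frequency,
            ref_annot=e.ref_annot, map_annot=e.ref_annot + 2.0 * (e.map_annot - e.ref_annot),
            woi=e.woi * 2.0, voltage_bip=e.voltage_bip,
            voltage_uni=e.voltage_uni, impedance=e.impedance)
        cv2 = compute_conduction_velocity(UserData(surface=ud.surface,
                                                   electric=scaled))
        both = cv1.valid & cv2.valid & ~cv1.clamped & ~cv2.clamped
        np.testing.assert_array_equal(cv2.speed[both], cv1.speed[both] / 2.0)

    def test_constant_lat_plateau_marks_vertices_invalid(self):
        sheet = make_planar_sheet(11, 11, 2.0)
        lat = np.full(sheet.n_vertices, 60.0)
        e = synthesize_electrograms(sheet, lat, np.arange(0, 121, 4),
                                    EgmSpec(n_samples=256))
        cv = compute_conduction_velocity(UserData(surface=sheet, electric=e))
        assert not cv.valid.any()

    def test_additive_lat_shift_preserves_speed(self, sheet_study):
        ud, _, _ = sheet_study
        cv1 = compute_conduction_velocity(ud)
        e = ud.electric
        shifted = ElectricData(
            point_ids=e.point_ids, names=e.names, tags=e.tags,
            egm_x=e.egm_x, egm_surf_x=e.egm_surf_x,
            ref_trace=e.ref_trace, bip_trace=e.bip_trace,
            uni_traces=e.uni_traces, sample_frequency=e.sample_frequency,
            ref_annot=e.ref_annot, map_annot=e.map_annot + 30.0,
            woi=e.woi + 30.0, voltage_bip=e.voltage_bip,
            voltage_uni=e.voltage_uni, impedance=e.impedance)
        cv2 = compute_conduction_velocity(UserData(surface=ud.surface,
                                                   electric=shifted))
        both = cv1.valid & cv2.valid
        np.testing.assert_allclose(cv2.speed[both], cv1.speed[both],
                                   rtol=1e-9)

    def test_rigid_rotation_preserves_speeds(self, sheet_study):
        ud, _, _ = sheet_study
        cv1 = compute_conduction_velocity(ud)
        R = Rotation.from_euler("xyz", [20, -35, 50],
                                degrees=True).as_matrix()
        mesh_r = SurfaceMesh(ud.surface.vertices @ R.T,
                             ud.surface.triangles)
        e = ud.electric
        rot = ElectricData(
            point_ids=e.point_ids, names=e.names, tags=e.tags,
            egm_x=e.egm_x @ R.T, egm_surf_x=e.egm_surf_x @ R.T,
            ref_trace=e.ref_trace, bip_trace=e.bip_trace,
            uni_traces=e.uni_traces, sample_frequency=e.sample_frequency,
            ref_annot=e.ref_annot, map_annot=e.map_annot,
            woi=e.woi, voltage_bip=e.voltage_bip,
            voltage_uni=e.voltage_uni, impedance=e.impedance)
        cv2 = compute_conduction_velocity(UserData(surface=mesh_r,
                                                   electric=rot))
        both = cv1.valid & cv2.valid
        med1 = np.median(cv1.speed[both])
        med2 = np.median(cv2.speed[both])
        assert abs(med2 - med1) / med1 < 0.01

    def test_nondifferentiable_scheme_rejected(self, sheet_study):
        ud, _, _ = sheet_study
        with pytest.raises(ValueError, match="differentiable"):
            compute_conduction_velocity(ud, InterpolatorSpec(scheme="idw"))

    def test_too_few_points_rejected(self, sheet_study):
        ud, _, _ = sheet_study
        e = ud.electric
        with pytest.raises(MissingDataError):
            few = ElectricData(
                point_ids=e.point_ids[:5], names=e.names[:5],
                tags=e.tags[:5], egm_x=e.egm_x[:5],
                egm_surf_x=e.egm_surf_x[:5], ref_trace=e.ref_trace[:5],
                bip_trace=e.bip_trace[:5], uni_traces=e.uni_traces[:5],
                sample_frequency=e.sample_frequency,
                ref_annot=e.ref_annot[:5], map_annot=e.map_annot[:5],
                woi=e.woi[:5], voltage_bip=e.voltage_bip[:5],
                voltage_uni=e.voltage_uni[:5], impedance=e.impedance[:5])
            compute_conduction_velocity(UserData(surface=ud.surface,
                                                 electric=few))


class TestCvHistogram:
    def test_bin_areas_conserve_valid_area(self, sheet_study):
        ud, _, _ = sheet_study
        cv = compute_conduction_velocity(ud)
        h = cv_histogram(cv, ud.surface)
        tri = ud.surface.triangles
        valid_tri = cv.valid[tri].all(axis=1)
        expected = ud.surface.triangle_areas()[valid_tri].sum() / 100.0
        assert h.bin_areas.sum() == pytest.approx(expected, rel=1e-9)
        assert h.total_area == pytest.approx(expected, rel=1e-9)

    def test_median_bin_contains_true_speed(self, sheet_study):
        ud, _, _ = sheet_study
        cv = compute_conduction_velocity(ud)
        h = cv_histogram(cv, ud.surface)
        assert h.median_speed == pytest.approx(1.0, abs=0.1)
        # default display convention spans 0-2 m/s
        assert h.bin_edges[0] == 0.0 and h.bin_edges[-1] == pytest.approx(2.0)

    def test_mismatched_mesh_rejected(self, sheet_study, closed_icosphere):
        ud, _, _ = sheet_study
        cv = compute_conduction_velocity(ud)
        with pytest.raises(ValueError, match="mesh"):
            cv_histogram(cv, closed_icosphere)
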