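"""Shared fixtures: synthetic studies with known ground truth and small
analytic toy meshes."""

import numpy as np
import pytest

from eamkit.model import SurfaceMesh, UserData
from eamkit.synth import (ChamberSpec, EgmSpec, WaveSpec, make_chamber_mesh,
                          make_planar_sheet, make_synthetic_study,
                          simulate_activation, synthesize_electrograms)


@pytest.fixture(scope="session")
def planar_study():
    """Default chamber study: planar wave at 1 m/s, 120 points, ablation
    sites, a few location-only points."""
    ud, truth = make_synthetic_study(
        preset="planar", n_points=120, n_location_only=4, seed=7,
        n_visitag_sites=25, egm=EgmSpec(seed=7, n_samples=256))
    return ud, truth


@pytest.fixture(scope="session")
def focal_study():
    """Focal activation from a seeded source vertex, 200 points."""
    ud, truth = make_synthetic_study(
        preset="focal", n_points=200, seed=11,
        egm=EgmSpec(seed=11, n_samples=256))
    return ud, truth


@pytest.fixture(scope="session")
def sheet_study():
    """Flat-sheet study used for quantitative conduction-velocity checks
    (no apparent-velocity inflation from curvature)."""
    sheet = make_planar_sheet(21, 21, 2.0, jitter=0.4, seed=3)
    wave = WaveSpec(mode="planar", speed=1.0, direction=(1.0, 0.3, 0.0),
                    t0=40.0)
    lat, truth = simulate_activation(sheet, wave)
    rng = np.random.default_rng(5)
    samples = np.sort(rng.choice(sheet.n_vertices, 200, replace=False))
    electric = synthesize_electrograms(sheet, lat, samples,
                                       EgmSpec(seed=5, n_samples=256))
    ud = UserData(system_name="synthetic", surface=sheet, electric=electric)
    return ud, truth, samples


@pytest.fixture(scope="session")
def closed_icosphere():
    """r=30 mm icosphere, subdivision 4, no holes, no jitter."""
    return make_chamber_mesh(ChamberSpec(radius=30.0, subdivisions=4,
                                         holes=(), jitter=0.0))


@pytest.fixture()
def unit_cube():
    v = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
                  [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1]], dtype=float)
    t = np.array([[0, 1, 2], [0, 2, 3], [4, 6, 5], [4, 7, 6],
                  [0, 4, 5], [0, 5, 1], [1, 5, 6], [1, 6, 2],
                  [2, 6, 7], [2, 7, 3], [3, 7, 4], [3, 4, 0]])
    return SurfaceMesh(v, t)


@pytest.fixture()
def unit_tetrahedron():
    v = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
    t = np.array([[0, 1, 2], [0, 1, 3], [0, 2, 3], [1, 2, 3]])
    return SurfaceMesh(v, t)


@pytest.fixture()
def square_with_hole():
    """Unit square (area 1) with a triangular hole of area 0.125."""
    v = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
                  [0.25, 0.25, 0], [0.75, 0.25, 0], [0.5, 0.75, 0]],
                 dtype=float)
    t = np.array([[0, 1, 5], [0, 5, 4], [1, 2, 5], [2, 6, 5],
                  [2, 3, 6], [3, 0, 4], [3, 4, 6]])
    return SurfaceMesh(v, t)
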