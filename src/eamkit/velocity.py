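"""Conduction-velocity mapping from local activation time samples.

For an activation field t(x) on the chamber surface, the wavefront speed
is 1/||grad_tangential t||.  The field is reconstructed from the scattered
(position, LAT) samples with a differentiable radial-basis-function
interpolant; its analytic gradient is evaluated at every vertex and
projected onto the local tangent plane (the raw 3D gradient of a surface
field carries a spurious normal component), giving

    g = grad s - (grad s . n) n,    speed = 1 / ||g||  (mm/ms == m/s),
    direction = g / ||g||.

Plateau vertices (||g|| below 1e-6 ms/mm) are marked invalid rather than
infinite; physiologically impossible speeds are clamped (default analysis
range 0-10 m/s) and flagged.  Display convention for CV maps is 0-2 m/s.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import MissingDataError
from .interpolate import (DEFAULT_FILL_THRESHOLD_MM, InterpolatorSpec,
                          ScatteredInterpolator, color_fill_mask)
from .model import SurfaceMesh, UserData

__all__ = ["CvField", "compute_conduction_velocity", "cv_histogram",
           "CvHistogram", "DEFAULT_CV_DISPLAY_RANGE"]

#: Conventional CV color-axis range for display, m/s.
DEFAULT_CV_DISPLAY_RANGE = (0.0, 2.0)

_PLATEAU_GRAD = 1e-6  # ms/mm


@dataclass
class CvField:
    """Per-vertex conduction-velocity result."""

    speed: np.ndarray  # (n,) m/s, NaN where invalid
    direction: np.ndarray  # (n, 3) tangential unit vectors
    valid: np.ndarray  # (n,) bool
    clamped: np.ndarray  # (n,) bool, speed was outside the clamp range
    clamp: tuple  # (lo, hi) m/s
    n_vertices: int = 0

    def __post_init__(self):
        self.n_vertices = len(self.speed)


def compute_conduction_velocity(userdata: UserData,
                                spec: Optional[InterpolatorSpec] = None,
                                clamp: tuple = (0.0, 10.0),
                                fill_threshold: float = DEFAULT_FILL_THRESHOLD_MM) -> CvField:
    """Map conduction velocity over the chamber from point LAT samples.

    Requires >= 10 annotated, non-location-only points and a differentiable
    (RBF) interpolation scheme.
    """
    if userdata.surface is None:
        raise MissingDataError("study has no surface mesh")
    e = userdata.electric
    if e is None:
        raise MissingDataError("study has no electrical data")
    spec = spec or InterpolatorSpec()
    if not spec.scheme.startswith("rbf"):
        raise ValueError(
            "conduction velocity requires a differentiable (rbf) scheme, "
            f"got {spec.scheme!r}"
        )
    lat = e.lat_values()
    ok = np.isfinite(lat) & np.isfinite(e.egm_surf_x).all(axis=1)
    if ok.sum() < 10:
        raise MissingDataError(
            f"need >= 10 annotated points for CV mapping, got {int(ok.sum())}"
        )
    x, y = e.egm_surf_x[ok], lat[ok]
    interp = ScatteredInterpolator(x, y, spec)
    mesh = userdata.surface
    grad = interp.gradient(mesh.vertices)  # ms/mm
    normals = mesh.vertex_normals()
    g = grad - np.einsum("ij,ij->i", grad, normals)[:, None] * normals
    gnorm = np.linalg.norm(g, axis=1)
    valid = color_fill_mask(mesh, x, fill_threshold)
    plateau = gnorm < _PLATEAU_GRAD
    valid = valid & ~plateau
    speed = np.full(mesh.n_vertices, np.nan)
    with np.errstate(divide="ignore"):
        speed[~plateau] = 1.0 / gnorm[~plateau]
    lo, hi = clamp
    clamped = np.zeros(mesh.n_vertices, dtype=bool)
    finite = np.isfinite(speed)
    clamped[finite] = (speed[finite] < lo) | (speed[finite] > hi)
    speed[finite] = np.clip(speed[finite], lo, hi)
    direction = np.zeros_like(g)
    nz = gnorm > 0
    direction[nz] = g[nz] / gnorm[nz, None]
    speed[~valid] = np.nan
    return CvField(speed=speed, direction=direction, valid=valid,
                   clamped=clamped & valid, clamp=(float(lo), float(hi)))


@dataclass
class CvHistogram:
    """Area-weighted conduction-velocity distribution."""

    bin_edges: np.ndarray  # m/s
    bin_areas: np.ndarray  # cm^2 per bin
    total_area: float  # cm^2, all-valid triangles
    median_speed: float  # m/s, area-weighted
    mean_speed: float  # m/s, area-weighted


def cv_histogram(cv: CvField, mesh: SurfaceMesh,
                 bin_edges=None) -> CvHistogram:
    """Histogram of surface area by conduction velocity.

    Each triangle whose three vertices are valid contributes its area to
    the bin holding its mean vertex speed (values clamped to the outer
    edges so the bins conserve the total valid area).  Default bins span
    the conventional display range 0-2 m/s in 0.1 m/s steps.
    """
    if cv.n_vertices != mesh.n_vertices:
        raise ValueError("CV field does not match this mesh")
    if bin_edges is None:
        bin_edges = np.arange(0.0, 2.0 + 1e-9, 0.1)
    bin_edges = np.asarray(bin_edges, dtype=np.float64)
    if len(bin_edges) < 2 or np.any(np.diff(bin_edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    tri = mesh.triangles
    tri_valid = cv.valid[tri].all(axis=1)
    areas = mesh.triangle_areas()[tri_valid] / 100.0  # cm^2
    speeds = cv.speed[tri[tri_valid]].mean(axis=1)
    speeds = np.clip(speeds, bin_edges[0], bin_edges[-1])
    idx = np.clip(np.searchsorted(bin_edges, speeds, side="right") - 1,
                  0, len(bin_edges) - 2)
    bin_areas = np.zeros(len(bin_edges) - 1)
    np.add.at(bin_areas, idx, areas)
    total = float(areas.sum())
    if total > 0:
        order = np.argsort(speeds)
        cum = np.cumsum(areas[order])
        median = float(speeds[order][np.searchsorted(cum, 0.5 * total)])
        mean = float(np.dot(speeds, areas) / total)
    else:
        median = mean = float("nan")
    return CvHistogram(bin_edges=bin_edges, bin_areas=bin_areas,
                       total_area=total, median_speed=median, mean_speed=mean)
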