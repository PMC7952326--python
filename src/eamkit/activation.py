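"""Total activation time and earliest-activation-site metrics.

Total activation time (TAT) is the span of local activation over the
chamber.  Six methods are provided, the cross product of three value
populations with two span definitions:

================  ==========================================================
ptbased           max - min of the per-point LATs (map_annot - ref_annot)
ptbasedprct       central percentile span P(100-q) - P(q) of the same LATs
clinmap           max - min of the clinical per-vertex 'act' field
clinmapprct       percentile span of the same field
openepmap         max - min of the re-interpolated LAT surface field
openepmapprct     percentile span of the same field
================  ==========================================================

The default q = 2.5 gives a central 95% span; percentile-based variants
are robust to single mis-annotated points on high-density maps.
Percentiles use linear interpolation between closest order statistics.
Location-only points are always excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import MissingDataError
from .geometry import closest_point_on_mesh
from .interpolate import InterpolatorSpec, generate_interp_data
from .model import SurfaceField, UserData

__all__ = ["TAT_METHODS", "EarliestSiteResult", "total_activation_time",
           "earliest_activation_site"]

TAT_METHODS = ("ptbased", "ptbasedprct", "clinmap", "clinmapprct",
               "openepmap", "openepmapprct")


@dataclass
class EarliestSiteResult:
    """Earliest-activation location on the chamber."""

    position: np.ndarray  # mm, on the surface
    vertex_index: int  # nearest mesh vertex
    lat: float  # ms (LAT at the identified point/vertex; for the
    # percentile method, the q-th percentile defining the cohort)
    method: str


def _lat_population(userdata: UserData, source: str,
                    spec: Optional[InterpolatorSpec] = None,
                    field: Optional[SurfaceField] = None):
    """Values + positions for one of the three LAT populations."""
    if source == "pt":
        e = userdata.electric
        if e is None:
            raise MissingDataError("study has no electrical data")
        lat = e.lat_values()
        ok = np.isfinite(lat)
        return lat[ok], e.egm_surf_x[ok]
    if userdata.surface is None:
        raise MissingDataError("study has no surface mesh")
    if source == "clinmap":
        if "act" not in userdata.surface.fields:
            raise MissingDataError("surface has no clinical 'act' field")
        vals = userdata.surface.fields["act"]
        ok = np.isfinite(vals)
    else:  # openepmap
        if field is None:
            field = generate_interp_data(userdata, "lat-map", spec)
        vals = field.values
        ok = field.valid & np.isfinite(vals)
    return vals[ok], userdata.surface.vertices[ok]


def _split_method(method: str):
    if method not in TAT_METHODS:
        raise ValueError(f"unknown TAT method {method!r}; choose from {TAT_METHODS}")
    prct = method.endswith("prct")
    base = method[:-4] if prct else method
    source = {"ptbased": "pt", "clinmap": "clinmap",
              "openepmap": "openepmap"}[base]
    return source, prct


def total_activation_time(userdata: UserData, method: str = "ptbased",
                          q: float = 2.5,
                          spec: Optional[InterpolatorSpec] = None,
                          field: Optional[SurfaceField] = None) -> float:
    """Total activation time (ms) by the requested method.

    ``q`` is the percentile tail for the *prct methods (0 < q < 50); an
    interpolated LAT field may be supplied via ``field`` to avoid
    recomputation for the openepmap methods.
    """
    source, prct = _split_method(method)
    if prct and not 0 < q < 50:
        raise ValueError("percentile q must lie in (0, 50)")
    vals, _ = _lat_population(userdata, source, spec, field)
    if len(vals) < 2:
        raise MissingDataError(
            f"need >= 2 usable LAT values for {method}, got {len(vals)}"
        )
    if prct:
        lo, hi = np.percentile(vals, [q, 100.0 - q])  # linear interpolation
        return float(hi - lo)
    return float(vals.max() - vals.min())


def earliest_activation_site(userdata: UserData, method: str = "ptbased",
                             q: float = 2.5,
                             spec: Optional[InterpolatorSpec] = None,
                             field: Optional[SurfaceField] = None) -> EarliestSiteResult:
    """Locate the earliest-activation site.

    'ptbased', 'clinmap' and 'openepmap' return the position of the minimum
    LAT in the respective population (ties broken by lowest index);
    'ptbasedprct' returns the centroid of all mapping points with LAT at or
    below the q-th percentile, projected back onto the surface — a cohort
    estimate that is robust to a single early outlier.
    """
    if method == "ptbasedprct":
        vals, pos = _lat_population(userdata, "pt")
        if len(vals) == 0:
            raise MissingDataError("no usable LAT values")
        thr = np.percentile(vals, q)
        cohort = pos[vals <= thr]
        centroid = cohort.mean(axis=0)
        if userdata.surface is not None:
            position = closest_point_on_mesh(centroid, userdata.surface)[0]
            d = np.linalg.norm(userdata.surface.vertices - position, axis=1)
            vtx = int(np.argmin(d))
        else:
            position, vtx = centroid, -1
        return EarliestSiteResult(position=position, vertex_index=vtx,
                                  lat=float(thr), method=method)
    source, prct = _split_method(method)
    if prct:
        raise ValueError(
            f"earliest site supports methods "
            f"('ptbased', 'ptbasedprct', 'clinmap', 'openepmap'), got {method!r}"
        )
    vals, pos = _lat_population(userdata, source, spec, field)
    if len(vals) == 0:
        raise MissingDataError("no usable LAT values")
    i = int(np.argmin(vals))  # argmin takes the lowest index on ties
    position = pos[i]
    if userdata.surface is not None:
        d = np.linalg.norm(userdata.surface.vertices - position, axis=1)
        vtx = int(np.argmin(d))
    else:
        vtx = -1
    return EarliestSiteResult(position=position.copy(), vertex_index=vtx,
                              lat=float(vals[i]), method=method)
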