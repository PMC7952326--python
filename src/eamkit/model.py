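"""In-memory study model for electroanatomic mapping data.

A study (:class:`UserData`) bundles a chamber surface (:class:`SurfaceMesh`,
a triangulated shell with per-vertex clinical map fields), the per-mapping-
point electrical record (:class:`ElectricData`: catheter positions, raw
electrogram traces, annotations and point voltages) and, optionally, a set
of radiofrequency ablation sites (:class:`~eamkit.ablation.VisitagSet`).

Units follow clinical convention throughout: positions in mm, times in ms,
voltages in mV, sampling rate in Hz.  Speeds are mm/ms which is numerically
identical to m/s.  Reported areas and volumes are converted to cm^2 / cm^3
at the reporting boundary (divide mm^2 by 100, mm^3 by 1000).

Missing scalar values (e.g. the activation annotation of an unannotated
point) are carried as NaN; derived surface fields carry an explicit
validity mask (:class:`SurfaceField`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import MissingDataError, PointNotFoundError, TopologyError

__all__ = [
    "UNITS",
    "SurfaceMesh",
    "ElectricData",
    "SurfaceField",
    "EgmRecord",
    "UserData",
    "get_num_points",
    "get_electrogram_positions",
    "index_from_clinical_point_id",
    "get_egms_at_points",
    "get_window_of_interest",
]

#: Unit conventions used by every module in the package.
UNITS = {
    "position": "mm",
    "time": "ms",
    "voltage": "mV",
    "speed": "m/s",  # == mm/ms
    "area_report": "cm^2",
    "volume_report": "cm^3",
}

#: Tag marking a stored catheter position with no linked electrical data.
LOCATION_ONLY_TAG = "Location only"


def _as_float2d(a, cols, name):
    a = np.asarray(a, dtype=np.float64)
    if a.size == 0:
        return a.reshape(0, cols)
    if a.ndim != 2 or a.shape[1] != cols:
        raise ValueError(f"{name} must be (n, {cols}), got {a.shape}")
    return a


@dataclass
class SurfaceMesh:
    """Triangulated chamber surface with optional per-vertex map fields.

    Parameters
    ----------
    vertices : (n, 3) float array, mm
    triangles : (m, 3) int array
        Vertex indices; no degenerate (zero-area) triangle is allowed.
    fields : dict of str -> (n,) float array
        Per-vertex clinical scalars; conventional keys are ``'act'`` (local
        activation time, ms, relative to the reference annotation) and
        ``'bip'`` (bipolar voltage, mV).  NaN marks missing values.
    """

    vertices: np.ndarray
    triangles: np.ndarray
    fields: dict = field(default_factory=dict)

    def __post_init__(self):
        self.vertices = _as_float2d(self.vertices, 3, "vertices")
        t = np.asarray(self.triangles, dtype=np.int64)
        if t.size == 0:
            t = t.reshape(0, 3)
        if t.ndim != 2 or t.shape[1] != 3:
            raise ValueError(f"triangles must be (m, 3), got {t.shape}")
        n = len(self.vertices)
        if t.size and (t.min() < 0 or t.max() >= n):
            raise ValueError("triangle index out of range")
        self.triangles = t
        areas = self.triangle_areas()
        if np.any(areas <= 0):
            bad = int(np.argmin(areas))
            raise ValueError(f"degenerate (zero-area) triangle at index {bad}")
        # manifold-with-boundary: every edge borders 1 or 2 triangles
        counts = self.edge_counts()
        if counts.size and counts.max() > 2:
            raise TopologyError("non-manifold edge shared by >2 triangles")
        clean = {}
        for k, v in self.fields.items():
            v = np.asarray(v, dtype=np.float64)
            if v.shape != (n,):
                raise ValueError(f"field {k!r} must have length {n}")
            clean[k] = v
        self.fields = clean

    # -- basic quantities -------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def triangle_corners(self):
        v = self.vertices
        t = self.triangles
        return v[t[:, 0]], v[t[:, 1]], v[t[:, 2]]

    def triangle_areas(self) -> np.ndarray:
        """Per-triangle areas in mm^2."""
        a, b, c = self.triangle_corners()
        return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)

    def triangle_centroids(self) -> np.ndarray:
        a, b, c = self.triangle_corners()
        return (a + b + c) / 3.0

    def total_area(self) -> float:
        """Open-surface area in mm^2 (sum over triangles)."""
        return float(self.triangle_areas().sum())

    # -- edges -------------------------------------------------------------

    def _sorted_edges(self) -> np.ndarray:
        t = self.triangles
        e = np.concatenate([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
        return np.sort(e, axis=1)

    def edge_counts(self):
        if self.n_triangles == 0:
            return np.zeros(0, dtype=np.int64)
        _, counts = np.unique(self._sorted_edges(), axis=0, return_counts=True)
        return counts

    def unique_edges(self):
        """(edges, counts): unique undirected edges and incidence counts."""
        if self.n_triangles == 0:
            return np.zeros((0, 2), dtype=np.int64), np.zeros(0, dtype=np.int64)
        return np.unique(self._sorted_edges(), axis=0, return_counts=True)

    def free_edges(self) -> np.ndarray:
        """Edges incident to exactly one triangle (the boundary rim)."""
        edges, counts = self.unique_edges()
        return edges[counts == 1]

    def is_closed(self) -> bool:
        return len(self.free_edges()) == 0

    def mean_edge_length(self) -> float:
        edges, _ = self.unique_edges()
        if len(edges) == 0:
            return 0.0
        d = self.vertices[edges[:, 0]] - self.vertices[edges[:, 1]]
        return float(np.linalg.norm(d, axis=1).mean())

    def is_vertex_at_rim(self) -> np.ndarray:
        flags = np.zeros(self.n_vertices, dtype=bool)
        fe = self.free_edges()
        if fe.size:
            flags[np.unique(fe)] = True
        return flags

    def vertex_normals(self) -> np.ndarray:
        """Area-weighted vertex normals (unit length where defined)."""
        a, b, c = self.triangle_corners()
        fn = np.cross(b - a, c - a)  # magnitude = 2*area
        vn = np.zeros_like(self.vertices)
        for k in range(3):
            np.add.at(vn, self.triangles[:, k], fn)
        norms = np.linalg.norm(vn, axis=1)
        nz = norms > 0
        vn[nz] /= norms[nz, None]
        return vn

    def copy(self) -> "SurfaceMesh":
        return SurfaceMesh(
            self.vertices.copy(),
            self.triangles.copy(),
            {k: v.copy() for k, v in self.fields.items()},
        )


@dataclass
class ElectricData:
    """Per-mapping-point electrical record.

    All per-point arrays share leading dimension ``p``; all traces share the
    sample count ``T`` at ``sample_frequency`` Hz, with sample 0 at t = 0 ms
    on the trace clock.  ``ref_annot``/``map_annot`` are absolute times on
    that clock; the window of interest ``woi`` is stored relative to
    ``ref_annot`` (clinical convention).  Unipolar channel order is
    (distal, proximal) and the bipolar sign convention is distal - proximal.
    """

    point_ids: np.ndarray  # (p,) opaque integer labels, unique
    names: list
    tags: list  # list of lists of str
    egm_x: np.ndarray  # (p,3) raw catheter positions, mm
    egm_surf_x: np.ndarray  # (p,3) surface-projected positions, mm
    ref_trace: np.ndarray  # (p,T) mV
    bip_trace: np.ndarray  # (p,T) mV
    uni_traces: np.ndarray  # (p,T,2) mV, (distal, proximal)
    sample_frequency: float  # Hz
    ref_annot: np.ndarray  # (p,) ms
    map_annot: np.ndarray  # (p,) ms, NaN if unannotated
    woi: np.ndarray  # (p,2) ms relative to ref_annot
    voltage_bip: np.ndarray  # (p,) mV
    voltage_uni: np.ndarray  # (p,) mV
    impedance: Optional[np.ndarray] = None  # (p,) Ohm

    def __post_init__(self):
        self.point_ids = np.asarray(self.point_ids, dtype=np.int64).reshape(-1)
        p = len(self.point_ids)
        if len(np.unique(self.point_ids)) != p:
            raise ValueError("clinical point ids must be unique")
        self.names = [str(x) for x in self.names]
        self.tags = [list(map(str, t)) for t in self.tags]
        if len(self.names) != p or len(self.tags) != p:
            raise ValueError("names/tags length mismatch")
        self.egm_x = _as_float2d(self.egm_x, 3, "egm_x")
        self.egm_surf_x = _as_float2d(self.egm_surf_x, 3, "egm_surf_x")
        self.ref_trace = np.atleast_2d(np.asarray(self.ref_trace, dtype=np.float64))
        self.bip_trace = np.atleast_2d(np.asarray(self.bip_trace, dtype=np.float64))
        self.uni_traces = np.asarray(self.uni_traces, dtype=np.float64)
        if p == 0:
            T = self.ref_trace.shape[1] if self.ref_trace.size else 0
            self.ref_trace = self.ref_trace.reshape(0, T)
            self.bip_trace = self.bip_trace.reshape(0, T)
            self.uni_traces = self.uni_traces.reshape(0, T, 2)
        T = self.ref_trace.shape[1]
        if self.bip_trace.shape != (p, T) or self.uni_traces.shape != (p, T, 2):
            raise ValueError("trace shapes inconsistent across channels")
        if not self.sample_frequency > 0:
            raise ValueError("sample_frequency must be > 0")
        self.sample_frequency = float(self.sample_frequency)
        for name in ("ref_annot", "map_annot", "voltage_bip", "voltage_uni"):
            v = np.asarray(getattr(self, name), dtype=np.float64).reshape(-1)
            if len(v) != p:
                raise ValueError(f"{name} must have length {p}")
            setattr(self, name, v)
        self.woi = _as_float2d(self.woi, 2, "woi")
        if len(self.woi) != p:
            raise ValueError("woi must be (p, 2)")
        ok = ~np.isnan(self.woi).any(axis=1)
        if np.any(self.woi[ok, 0] >= self.woi[ok, 1]):
            raise ValueError("window of interest must satisfy low < high")
        # annotated points: relative LAT must fall inside the window
        lat = self.map_annot - self.ref_annot
        ann = np.isfinite(lat) & ok
        if np.any((lat[ann] < self.woi[ann, 0]) | (lat[ann] > self.woi[ann, 1])):
            raise ValueError("activation annotation outside window of interest")
        if self.impedance is not None:
            z = np.asarray(self.impedance, dtype=np.float64).reshape(-1)
            if len(z) != p:
                raise ValueError("impedance length mismatch")
            self.impedance = z

    @property
    def n_points(self) -> int:
        return len(self.point_ids)

    @property
    def n_samples(self) -> int:
        return self.ref_trace.shape[1]

    def time_axis(self) -> np.ndarray:
        """Sample times in ms on the trace clock."""
        return np.arange(self.n_samples) * 1000.0 / self.sample_frequency

    def location_only_mask(self) -> np.ndarray:
        """True for points tagged as location-only (no usable electrogram)."""
        return np.array(
            [any(t.strip().lower() == "location only" for t in tags)
             for tags in self.tags],
            dtype=bool,
        )

    def lat_values(self) -> np.ndarray:
        """Relative LAT (map_annot - ref_annot, ms); NaN where unannotated
        or location-only."""
        lat = self.map_annot - self.ref_annot
        lat = lat.copy()
        lat[self.location_only_mask()] = np.nan
        return lat


@dataclass
class SurfaceField:
    """Per-vertex scalar field with an explicit validity mask.

    ``values`` carries NaN at invalid vertices; ``source`` records whether
    the field came from the clinical system or from re-interpolation, and
    ``quantity`` names the physical quantity ('lat', 'bip', 'uni', 'cv').
    """

    values: np.ndarray
    valid: np.ndarray
    source: str = "interpolated"
    quantity: str = "lat"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64).reshape(-1)
        self.valid = np.asarray(self.valid, dtype=bool).reshape(-1)
        if len(self.values) != len(self.valid):
            raise ValueError("values/valid length mismatch")
        self.values = self.values.copy()
        self.values[~self.valid] = np.nan


@dataclass
class EgmRecord:
    """Electrogram bundle for one mapping point (untruncated traces)."""

    index: int
    point_id: int
    ref: np.ndarray
    bip: np.ndarray
    uni: np.ndarray  # (T, 2): distal, proximal
    sample_frequency: float
    ref_annot: float
    map_annot: float
    woi_absolute: tuple
    annotation_sample: Optional[int]


@dataclass
class UserData:
    """Root study record: surface + electric + ablation + provenance."""

    system_name: str = "unknown"
    notes: list = field(default_factory=list)
    surface: Optional[SurfaceMesh] = None
    electric: Optional[ElectricData] = None
    rfindex: Optional[object] = None  # VisitagSet

    def __post_init__(self):
        self.notes = list(self.notes)

    # thin delegating accessors, so `userdata.get_num_points()` also works
    def get_num_points(self, include_location_only: bool = False) -> int:
        return get_num_points(self, include_location_only)

    def get_electrogram_positions(self, kind: str = "surface") -> np.ndarray:
        return get_electrogram_positions(self, kind)

    def index_from_clinical_point_id(self, point_id) -> int:
        return index_from_clinical_point_id(self, point_id)


def _require_electric(userdata: UserData) -> ElectricData:
    if userdata.electric is None:
        raise MissingDataError("study has no electrical data")
    return userdata.electric


def get_num_points(userdata: UserData, include_location_only: bool = False) -> int:
    """Number of mapping points; location-only points are excluded unless
    ``include_location_only`` is set."""
    e = _require_electric(userdata)
    if include_location_only:
        return e.n_points
    return int((~e.location_only_mask()).sum())


def get_electrogram_positions(userdata: UserData, kind: str = "surface") -> np.ndarray:
    """Point positions: raw catheter ('raw') or surface-projected
    ('surface'); row order matches internal point order."""
    e = _require_electric(userdata)
    if kind == "raw":
        return e.egm_x.copy()
    if kind == "surface":
        return e.egm_surf_x.copy()
    raise ValueError(f"unknown position kind {kind!r}; use 'raw' or 'surface'")


def index_from_clinical_point_id(userdata: UserData, point_id) -> int:
    """0-based internal index of the point whose clinical id equals
    ``point_id``."""
    e = _require_electric(userdata)
    hits = np.nonzero(e.point_ids == int(point_id))[0]
    if len(hits) == 0:
        raise PointNotFoundError(
            f"point id {point_id} not found; study holds {e.n_points} points "
            f"with ids in [{e.point_ids.min() if e.n_points else '-'}, "
            f"{e.point_ids.max() if e.n_points else '-'}]"
        )
    return int(hits[0])


def get_egms_at_points(userdata: UserData, indices: Sequence[int]) -> list:
    """Electrogram records (untruncated traces + annotations) at the given
    internal indices.  Location-only points carry no electrogram and raise."""
    e = _require_electric(userdata)
    loc_only = e.location_only_mask()
    out = []
    for i in indices:
        i = int(i)
        if not 0 <= i < e.n_points:
            raise IndexError(f"point index {i} out of range [0, {e.n_points})")
        if loc_only[i]:
            raise MissingDataError(
                f"no electrogram at location-only point index {i} "
                f"(id {e.point_ids[i]})"
            )
        ma = float(e.map_annot[i])
        if np.isfinite(ma):
            # trace clock starts at 0 ms
            ann = int(round(ma * e.sample_frequency / 1000.0))
        else:
            ann = None
        woi_abs = (float(e.ref_annot[i] + e.woi[i, 0]),
                   float(e.ref_annot[i] + e.woi[i, 1]))
        out.append(EgmRecord(
            index=i,
            point_id=int(e.point_ids[i]),
            ref=e.ref_trace[i].copy(),
            bip=e.bip_trace[i].copy(),
            uni=e.uni_traces[i].copy(),
            sample_frequency=e.sample_frequency,
            ref_annot=float(e.ref_annot[i]),
            map_annot=ma,
            woi_absolute=woi_abs,
            annotation_sample=ann,
        ))
    return out


def get_window_of_interest(userdata: UserData, indices: Optional[Sequence[int]] = None) -> np.ndarray:
    """Absolute window-of-interest bounds (ms on the trace clock):
    ``[ref_annot + woi_low, ref_annot + woi_high]`` per requested point."""
    e = _require_electric(userdata)
    if indices is None:
        idx = np.arange(e.n_points)
    else:
        idx = np.asarray(list(indices), dtype=np.int64)
        if idx.size and (idx.min() < 0 or idx.max() >= e.n_points):
            raise IndexError("point index out of range")
    return e.ref_annot[idx, None] + e.woi[idx]
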