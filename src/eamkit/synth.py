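"""Synthetic study generation with known ground truth.

Every analysis stage in the package (geometry, activation, conduction
velocity, voltage, ablation, I/O) is testable without clinical data: this
module builds ellipsoidal chamber shells with valve/vein cut-outs, imposes
activation wavefronts and voltage fields with closed-form or graph-geodesic
truth, synthesizes electrogram traces whose annotations match that truth,
and assembles complete studies.

The default study emulates a left-atrium-scale chamber: 30 mm base radius,
subdivision level 3 (~1280 triangles before cutting), five cut-outs (one
valve + four veins), 1 kHz sampling, and a planar wavefront at 1.0 m/s —
small enough that every test runs in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import trimesh
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .ablation import VisitagSet
from .model import ElectricData, SurfaceMesh, UserData

__all__ = [
    "ChamberSpec",
    "WaveSpec",
    "EgmSpec",
    "ActivationTruth",
    "VoltageTruth",
    "StudyTruth",
    "make_chamber_mesh",
    "make_planar_sheet",
    "simulate_activation",
    "simulate_voltage_field",
    "synthesize_electrograms",
    "make_visitags",
    "make_synthetic_study",
    "DEFAULT_HOLES",
]

#: One mitral-valve-like cut-out plus four pulmonary-vein-like cut-outs,
#: as (unit direction, angular radius in radians) on the chamber sphere.
DEFAULT_HOLES = (
    ((0.0, 0.0, -1.0), 0.45),
    ((0.5, 0.5, 0.7071067811865476), 0.25),
    ((-0.5, 0.5, 0.7071067811865476), 0.25),
    ((-0.5, -0.5, 0.7071067811865476), 0.25),
    ((0.5, -0.5, 0.7071067811865476), 0.25),
)


@dataclass
class ChamberSpec:
    """Chamber-shell recipe: ellipsoidally scaled, jittered icosphere with
    angular cut-outs."""

    radius: float = 30.0  # mm
    scale: tuple = (1.0, 1.0, 1.0)  # ellipsoid axis factors
    subdivisions: int = 3
    holes: tuple = DEFAULT_HOLES  # ((direction, angular radius rad), ...)
    jitter: float = 0.0  # mm, seeded vertex noise
    seed: int = 0

    def __post_init__(self):
        if self.subdivisions < 1:
            raise ValueError("subdivisions must be >= 1")
        if self.jitter >= 0.1 * self.radius:
            raise ValueError("jitter must stay below 0.1 * radius")
        dirs = [np.asarray(d, dtype=float) for d, _ in self.holes]
        radii = [float(r) for _, r in self.holes]
        for i in range(len(dirs)):
            for j in range(i + 1, len(dirs)):
                a = dirs[i] / np.linalg.norm(dirs[i])
                b = dirs[j] / np.linalg.norm(dirs[j])
                sep = np.arccos(np.clip(a @ b, -1, 1))
                if sep <= radii[i] + radii[j]:
                    raise ValueError(f"holes {i} and {j} overlap")


@dataclass
class WaveSpec:
    """Activation wavefront: planar (direction + speed) or focal (source
    vertex + speed along graph geodesics)."""

    mode: str = "planar"
    speed: float = 1.0  # m/s == mm/ms
    direction: tuple = (1.0, 0.0, 0.0)  # planar mode
    source_vertex: int = 0  # focal mode
    t0: float = 0.0  # ms offset

    def __post_init__(self):
        if self.mode not in ("planar", "focal"):
            raise ValueError("mode must be 'planar' or 'focal'")
        if not self.speed > 0:
            raise ValueError("speed must be > 0")
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if not n > 0:
            raise ValueError("direction must be nonzero")
        self.direction = tuple(d / n)


@dataclass
class EgmSpec:
    """Electrogram synthesis parameters.

    The unipolar template is a Gaussian derivative
    ``u(t) = -A * ((t - t*) / tau) * exp(-(t - t*)^2 / (2 tau^2))`` whose
    steepest negative slope falls exactly at the activation time t* — the
    conventional LAT marker.  The second (proximal) unipole is the same
    template delayed by ``delay``; the bipolar trace is their difference
    plus seeded Gaussian noise.
    """

    fs: float = 1000.0  # Hz
    n_samples: int = 1000
    amplitude: float = 1.0  # mV
    tau: float = 5.0  # ms
    delay: float = 3.0  # ms inter-electrode conduction delay
    noise: float = 0.0  # mV std of additive Gaussian noise on bip
    seed: int = 0

    def __post_init__(self):
        if self.fs < 500:
            raise ValueError("fs must be >= 500 Hz")
        if not self.tau > 0:
            raise ValueError("tau must be > 0")
        if self.noise < 0:
            raise ValueError("noise must be >= 0")


@dataclass
class ActivationTruth:
    """Ground truth accompanying a simulated activation field."""

    lat: np.ndarray  # per-vertex ms
    tat: float  # max - min over vertices, ms
    earliest_vertex: int
    speed: float  # m/s
    mode: str
    direction: Optional[np.ndarray] = None
    source_vertex: Optional[int] = None


@dataclass
class VoltageTruth:
    """Ground truth accompanying a simulated voltage field."""

    values: np.ndarray  # per-vertex mV
    background: float
    patch_vertex_masks: list  # per patch: bool mask incl. the blended rim
    patch_areas_mm2: list  # exact triangle-aligned sub-threshold areas
    rim_threshold: list  # per patch: threshold at which alignment is exact


def make_chamber_mesh(spec: Optional[ChamberSpec] = None) -> SurfaceMesh:
    """Build the chamber shell: subdivided icosphere, scaled to an
    ellipsoid, jittered with seeded noise, with triangles inside each
    hole's angular radius removed.  The result is manifold-with-boundary
    with one free-boundary loop per hole."""
    spec = spec or ChamberSpec()
    ico = trimesh.creation.icosphere(subdivisions=spec.subdivisions, radius=1.0)
    unit = np.asarray(ico.vertices, dtype=np.float64)
    tris = np.asarray(ico.faces, dtype=np.int64)
    # hole test on the unit sphere (pre-scale, pre-jitter) by triangle centroid
    keep = np.ones(len(tris), dtype=bool)
    for d, ang in spec.holes:
        d = np.asarray(d, dtype=float)
        d = d / np.linalg.norm(d)
        cen = unit[tris].mean(axis=1)
        cen = cen / np.linalg.norm(cen, axis=1, keepdims=True)
        keep &= np.arccos(np.clip(cen @ d, -1, 1)) > ang
    tris = tris[keep]
    used = np.unique(tris)
    remap = -np.ones(len(unit), dtype=np.int64)
    remap[used] = np.arange(len(used))
    tris = remap[tris]
    verts = unit[used] * spec.radius * np.asarray(spec.scale, dtype=float)
    if spec.jitter > 0:
        rng = np.random.default_rng(spec.seed)
        verts = verts + rng.normal(0.0, spec.jitter, verts.shape)
    return SurfaceMesh(verts, tris)


def make_planar_sheet(nx: int = 21, ny: int = 21, spacing: float = 2.0,
                      jitter: float = 0.0, seed: int = 0) -> SurfaceMesh:
    """Flat triangulated sheet in the z = 0 plane (nx x ny vertex grid).

    On a flat surface the tangential-projected activation gradient equals
    the full gradient, so wavefront speed recovery is free of the apparent-
    velocity inflation a curved chamber introduces — the quantitative
    conduction-velocity fixtures are built on this sheet.  Optional seeded
    in-plane jitter breaks the grid regularity.
    """
    xs = np.arange(nx) * spacing
    ys = np.arange(ny) * spacing
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    verts = np.column_stack([gx.ravel(), gy.ravel(), np.zeros(nx * ny)])
    if jitter > 0:
        rng = np.random.default_rng(seed)
        verts[:, :2] += rng.uniform(-jitter, jitter, (nx * ny, 2))
    tris = []
    for i in range(nx - 1):
        for j in range(ny - 1):
            a = i * ny + j
            b = (i + 1) * ny + j
            tris.append([a, b, a + 1])
            tris.append([b, b + 1, a + 1])
    return SurfaceMesh(verts, np.asarray(tris, dtype=np.int64))


def _edge_graph_distances(mesh: SurfaceMesh, sources) -> np.ndarray:
    """Shortest-path distances over the mesh edge graph (mm) from each
    source vertex; rows correspond to sources."""
    edges, _ = mesh.unique_edges()
    w = np.linalg.norm(mesh.vertices[edges[:, 0]] - mesh.vertices[edges[:, 1]],
                       axis=1)
    n = mesh.n_vertices
    g = csr_matrix(
        (np.concatenate([w, w]),
         (np.concatenate([edges[:, 0], edges[:, 1]]),
          np.concatenate([edges[:, 1], edges[:, 0]]))),
        shape=(n, n),
    )
    return dijkstra(g, directed=False, indices=list(sources))


def simulate_activation(mesh: SurfaceMesh, wave: Optional[WaveSpec] = None):
    """Impose an activation field with known truth.

    Planar mode: ``t(x) = t0 + n . (x - x_ref) / v`` with ``x_ref`` the
    vertex minimizing ``n . x`` (so the earliest vertex has LAT exactly
    t0).  Focal mode: ``t = t0 + geodesic_edge_distance(source, x) / v``
    via Dijkstra over the edge graph.  Returns (lat, ActivationTruth).
    """
    wave = wave or WaveSpec()
    v = wave.speed  # m/s == mm/ms
    if wave.mode == "planar":
        n = np.asarray(wave.direction)
        proj = mesh.vertices @ n
        lat = wave.t0 + (proj - proj.min()) / v
        earliest = int(np.argmin(proj))
        truth = ActivationTruth(
            lat=lat, tat=float(lat.max() - lat.min()),
            earliest_vertex=earliest, speed=v, mode="planar",
            direction=np.asarray(n, dtype=float),
        )
    else:
        src = int(wave.source_vertex)
        if not 0 <= src < mesh.n_vertices:
            raise ValueError(
                f"focal source vertex {src} not in mesh "
                f"(n={mesh.n_vertices}; was it removed by a hole cut-out?)"
            )
        d = _edge_graph_distances(mesh, [src])[0]
        lat = wave.t0 + d / v
        truth = ActivationTruth(
            lat=lat, tat=float(lat.max() - lat.min()),
            earliest_vertex=src, speed=v, mode="focal", source_vertex=src,
        )
    return lat, truth


def simulate_voltage_field(mesh: SurfaceMesh, patches: Sequence = (),
                           background: float = 2.0,
                           rim: str = "mid"):
    """Impose a bipolar-voltage field with low-voltage patches.

    Vertices within the geodesic ``radius`` of each patch center get the
    patch ``level``; all others the ``background``.  With ``rim='mid'``
    (default) patch vertices bordering the outside are set to the midpoint
    ``(level + background) / 2``: the sub-level-set of the field at the
    midpoint threshold is then exactly triangle-aligned, so the reported
    ``patch_areas_mm2`` are recovered exactly by isoline-clipped area
    integration.  ``rim='level'`` keeps a hard two-valued step.

    patches : sequence of (center_vertex, radius_mm, level_mV), levels >= 0.
    Returns (values, VoltageTruth).
    """
    if rim not in ("mid", "level"):
        raise ValueError("rim must be 'mid' or 'level'")
    values = np.full(mesh.n_vertices, float(background))
    masks, areas, thresholds = [], [], []
    tri = mesh.triangles
    tri_areas = mesh.triangle_areas()
    for center, radius, level in patches:
        if level < 0:
            raise ValueError("patch level must be >= 0")
        d = _edge_graph_distances(mesh, [int(center)])[0]
        inside = d <= radius
        # rim = inside vertices adjacent to an outside vertex
        edges, _ = mesh.unique_edges()
        rim_mask = np.zeros(mesh.n_vertices, dtype=bool)
        a_in = inside[edges[:, 0]]
        b_in = inside[edges[:, 1]]
        rim_mask[edges[:, 0][a_in & ~b_in]] = True
        rim_mask[edges[:, 1][b_in & ~a_in]] = True
        mid = 0.5 * (level + background)
        values[inside] = level
        if rim == "mid":
            values[inside & rim_mask] = mid
        # true sub-threshold area at the midpoint: triangles entirely inside
        # the patch with at least one strictly-interior vertex
        strict = inside & ~rim_mask
        all_in = inside[tri].all(axis=1)
        any_strict = strict[tri].any(axis=1)
        area = float(tri_areas[all_in & any_strict].sum()) if rim == "mid" \
            else float(tri_areas[all_in].sum())
        masks.append(inside)
        areas.append(area)
        thresholds.append(mid)
    truth = VoltageTruth(values=values, background=float(background),
                         patch_vertex_masks=masks, patch_areas_mm2=areas,
                         rim_threshold=thresholds)
    return values, truth


def synthesize_electrograms(mesh: SurfaceMesh, lat_field: np.ndarray,
                            sample_vertices: Sequence[int],
                            egm: Optional[EgmSpec] = None,
                            point_ids: Optional[Sequence[int]] = None,
                            n_location_only: int = 0) -> ElectricData:
    """Build the per-point electrical record at sampled mesh vertices.

    For each sampled vertex with true relative LAT t*, the distal unipole
    is the Gaussian-derivative template centered at the absolute activation
    time, the proximal unipole is delayed by ``egm.delay``, and the bipolar
    trace is distal - proximal plus seeded noise.  ``map_annot`` is set to
    the true activation time, the reference trace is a fixed template at
    ``ref_annot``, the window of interest brackets all true LATs, and the
    point bipolar voltage is the peak-to-peak of the noiseless bipolar
    trace.  Optionally appends location-only points (positions only).
    """
    egm = egm or EgmSpec()
    idx = np.asarray(list(sample_vertices), dtype=np.int64)
    lat_field = np.asarray(lat_field, dtype=np.float64)
    tstar = lat_field[idx]  # relative LAT, ms
    T_ms = egm.n_samples * 1000.0 / egm.fs
    margin = 6.0 * egm.tau
    # reference annotation pinned to the trace origin so the stored relative
    # LAT (map_annot - ref_annot) equals the imposed field value exactly
    ref_annot_val = 0.0
    map_annot = ref_annot_val + tstar
    if len(tstar) and (map_annot.min() < 0 or map_annot.max() > T_ms - margin):
        raise ValueError(
            "activation time falls outside the trace; increase n_samples "
            "or shift the wave offset t0"
        )
    t = np.arange(egm.n_samples) * 1000.0 / egm.fs  # ms

    def template(center):
        z = (t - center) / egm.tau
        return -egm.amplitude * z * np.exp(-0.5 * z * z)

    rng = np.random.default_rng(egm.seed)
    p = len(idx)
    uni = np.zeros((p, egm.n_samples, 2))
    bip = np.zeros((p, egm.n_samples))
    ref = np.tile(0.5 * template(ref_annot_val), (p, 1))
    vbip = np.zeros(p)
    vuni = np.zeros(p)
    for i, tm in enumerate(map_annot):
        u1 = template(tm)
        u2 = template(tm + egm.delay)
        uni[i, :, 0] = u1
        uni[i, :, 1] = u2
        clean = u1 - u2
        bip[i] = clean + (rng.normal(0.0, egm.noise, egm.n_samples)
                          if egm.noise > 0 else 0.0)
        vbip[i] = float(np.ptp(clean))
        vuni[i] = float(np.ptp(u1))

    pad = 10.0
    if len(tstar):
        woi_lo = float(tstar.min() - pad)
        woi_hi = float(tstar.max() + pad)
    else:
        woi_lo, woi_hi = -pad, pad
    pos = mesh.vertices[idx]
    centroid = mesh.vertices.mean(axis=0)
    raw = pos + 0.05 * (centroid - pos)  # catheter sits just inside the shell

    n_extra = int(n_location_only)
    if n_extra:
        # location-only positions: jittered copies of existing vertices
        extra_idx = rng.integers(0, mesh.n_vertices, n_extra)
        epos = mesh.vertices[extra_idx] + rng.normal(0, 0.5, (n_extra, 3))
        pos = np.vstack([pos, epos])
        raw = np.vstack([raw, epos + 0.05 * (centroid - epos)])
        uni = np.concatenate([uni, np.zeros((n_extra, egm.n_samples, 2))])
        bip = np.vstack([bip, np.zeros((n_extra, egm.n_samples))])
        ref = np.vstack([ref, np.zeros((n_extra, egm.n_samples))])
        map_annot = np.concatenate([map_annot, np.full(n_extra, np.nan)])
        vbip = np.concatenate([vbip, np.full(n_extra, np.nan)])
        vuni = np.concatenate([vuni, np.full(n_extra, np.nan)])
    p_tot = p + n_extra
    if point_ids is None:
        point_ids = np.arange(1, p_tot + 1)
    tags = [[] for _ in range(p)] + [["Location only"] for _ in range(n_extra)]
    names = [f"P{pid}" for pid in point_ids]
    return ElectricData(
        point_ids=point_ids,
        names=names,
        tags=tags,
        egm_x=raw,
        egm_surf_x=pos,
        ref_trace=ref,
        bip_trace=bip,
        uni_traces=uni,
        sample_frequency=egm.fs,
        ref_annot=np.full(p_tot, ref_annot_val),
        map_annot=map_annot,
        woi=np.tile([woi_lo, woi_hi], (p_tot, 1)),
        voltage_bip=vbip,
        voltage_uni=vuni,
        impedance=np.full(p_tot, 100.0),
    )


def make_visitags(mesh: SurfaceMesh, n_sites: int = 30, seed: int = 0,
                  with_grid: bool = True) -> VisitagSet:
    """Synthesize an ablation-site set with physiologic parameter ranges
    (ablation index 300-550, force 5-40 g, power 25-50 W, temperature
    25-45 degC, impedance 80-120 Ohm, duration 10-60 s)."""
    rng = np.random.default_rng(seed)
    idx = rng.choice(mesh.n_vertices, size=min(n_sites, mesh.n_vertices),
                     replace=False)
    proj = mesh.vertices[idx]
    centroid = mesh.vertices.mean(axis=0)
    pos = proj + 0.03 * (centroid - proj)
    k = len(idx)
    grid_pos = None
    grid_params = None
    if with_grid and k:
        reps = 4
        grid_pos = np.repeat(proj, reps, axis=0) + rng.normal(0, 1.0,
                                                              (k * reps, 3))
        grid_params = {"index_value": np.repeat(
            rng.uniform(300, 550, k), reps)}
    return VisitagSet(
        positions=pos,
        projected_positions=proj,
        index_name="AblationIndex",
        index_value=rng.uniform(300, 550, k),
        force=rng.uniform(5, 40, k),
        power=rng.uniform(25, 50, k),
        temperature=rng.uniform(25, 45, k),
        impedance=rng.uniform(80, 120, k),
        duration=rng.uniform(10, 60, k),
        grid_positions=grid_pos,
        grid_params=grid_params,
    )


@dataclass
class StudyTruth:
    """Everything needed to score downstream metrics without re-deriving
    truth: the activation and voltage truths plus the sampled subset."""

    activation: ActivationTruth
    voltage: VoltageTruth
    sample_vertices: np.ndarray
    sample_lat: np.ndarray  # relative LAT at the sampled vertices, ms
    tat_points: float  # max - min over sampled LATs, ms
    earliest_sample: int  # index (into samples) of the earliest sampled point


def make_synthetic_study(preset: str = "planar", n_points: int = 100,
                         n_location_only: int = 0, seed: int = 0,
                         chamber: Optional[ChamberSpec] = None,
                         wave: Optional[WaveSpec] = None,
                         egm: Optional[EgmSpec] = None,
                         n_visitag_sites: int = 0,
                         patches: Optional[Sequence] = None):
    """Assemble a complete synthetic study.

    Returns (UserData, StudyTruth).  The mesh carries the full simulated
    LAT field as its clinical 'act' field and the simulated voltage field
    as 'bip'; the electric block samples ``n_points`` seeded vertices.
    """
    rng = np.random.default_rng(seed)
    chamber = chamber or ChamberSpec(seed=seed)
    mesh = make_chamber_mesh(chamber)
    if wave is None:
        # t0 leaves room for the electrogram template before the first
        # activation on the trace clock
        if preset == "planar":
            wave = WaveSpec(mode="planar", speed=1.0, t0=40.0)
        elif preset == "focal":
            src = int(rng.integers(0, mesh.n_vertices))
            wave = WaveSpec(mode="focal", speed=1.0, source_vertex=src, t0=40.0)
        else:
            raise ValueError(f"unknown preset {preset!r}; use 'planar' or 'focal'")
    lat, act_truth = simulate_activation(mesh, wave)
    if patches is None:
        center = int(rng.integers(0, mesh.n_vertices))
        patches = [(center, 10.0, 0.2)]
    volt, volt_truth = simulate_voltage_field(mesh, patches, background=2.0)
    mesh.fields["act"] = lat.copy()
    mesh.fields["bip"] = volt.copy()
    n_points = min(n_points, mesh.n_vertices)
    samples = np.sort(rng.choice(mesh.n_vertices, size=n_points, replace=False))
    egm = egm or EgmSpec(seed=seed)
    electric = synthesize_electrograms(mesh, lat, samples, egm,
                                       n_location_only=n_location_only)
    rf = make_visitags(mesh, n_visitag_sites, seed=seed) \
        if n_visitag_sites else None
    ud = UserData(system_name="synthetic", notes=[f"seed={seed}", f"preset={preset}"],
                  surface=mesh, electric=electric, rfindex=rf)
    sample_lat = lat[samples]
    truth = StudyTruth(
        activation=act_truth,
        voltage=volt_truth,
        sample_vertices=samples,
        sample_lat=sample_lat,
        tat_points=float(sample_lat.max() - sample_lat.min()),
        earliest_sample=int(np.argmin(sample_lat)),
    )
    return ud, truth
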