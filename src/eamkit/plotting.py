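"""Visualization: electrogram stacks, surface maps, ablation overlays.

Every plot function is split into a pure data-assembly helper (returning
the exact traces/vertices/colors that will be drawn — unit-testable
without rendering) and a thin matplotlib renderer that writes PNG/SVG by
file extension.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
from matplotlib.colors import LinearSegmentedColormap  # noqa: E402
from mpl_toolkits.mplot3d.art3d import Poly3DCollection  # noqa: E402

from .errors import MissingDataError  # noqa: E402
from .model import SurfaceField, UserData, get_egms_at_points  # noqa: E402

__all__ = ["egm_plot_data", "plot_egms", "draw_map", "visitag_plot_data",
           "plot_visitags", "plot_ablation_area"]

#: Ablation-index color convention: low = white, high = red.
_ABLATION_CMAP = LinearSegmentedColormap.from_list("ablation",
                                                   ["white", "red"])


def egm_plot_data(userdata: UserData, indices: Sequence[int],
                  separation: float = 3.0) -> list:
    """Assemble the stacked-trace layout for :func:`plot_egms`.

    Per point, four traces (reference, bipolar, two unipolar) are offset
    vertically by ``separation`` mV; the annotation marker sits at
    ``map_annot`` on the time axis.  Returns a list of dicts with keys
    't_ms', 'traces' (label -> offset trace), 'annotation_ms',
    'annotation_values', 'woi_absolute', 'point_id'.
    """
    records = get_egms_at_points(userdata, indices)
    t = userdata.electric.time_axis()
    out = []
    base = 0.0
    for rec in records:
        traces = {}
        for label, y in (("ref", rec.ref), ("bip", rec.bip),
                         ("uni1", rec.uni[:, 0]), ("uni2", rec.uni[:, 1])):
            traces[label] = y + base
            base += separation
        ann_vals = None
        if rec.annotation_sample is not None:
            s = rec.annotation_sample
            ann_vals = {k: float(v[s]) for k, v in traces.items()}
        out.append({
            "t_ms": t,
            "traces": traces,
            "annotation_ms": rec.map_annot,
            "annotation_values": ann_vals,
            "woi_absolute": rec.woi_absolute,
            "point_id": rec.point_id,
        })
    return out


def plot_egms(userdata: UserData, indices: Sequence[int], out_path,
              separation: float = 3.0) -> Path:
    """Write a stacked electrogram figure (reference, bipolar and paired
    unipolar traces per point, annotation markers in red)."""
    data = egm_plot_data(userdata, indices, separation)
    fig, ax = plt.subplots(figsize=(8, max(3, 1.5 * len(data))))
    colors = {"ref": "tab:red", "bip": "tab:blue",
              "uni1": "tab:green", "uni2": "tab:green"}
    for block in data:
        for label, y in block["traces"].items():
            ax.plot(block["t_ms"], y, lw=0.8, color=colors[label])
        if block["annotation_values"] is not None:
            for label in ("bip", "uni1", "uni2"):
                ax.plot(block["annotation_ms"],
                        block["annotation_values"][label],
                        "o", ms=4, color="red", zorder=5)
        lo, hi = block["woi_absolute"]
        ax.axvspan(lo, hi, color="0.92", zorder=0)
    ax.set_xlabel("time (ms)")
    ax.set_yticks([])
    ax.set_title(", ".join(f"point {b['point_id']}" for b in data))
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=110)
    plt.close(fig)
    return out_path


_ORIENTATIONS = {"ap": (0.0, 0.0), "pa": (0.0, 180.0)}  # (elev, azim)


def draw_map(userdata: UserData, map_type: str = "act",
             data: Optional[SurfaceField] = None,
             orientation: str = "ap",
             color_axis: Optional[tuple] = None,
             out_path=None, cmap: Optional[str] = None) -> Path:
    """Render the chamber colored by a surface field.

    ``map_type`` selects the clinical vertex field ('act' or 'bip') unless
    an interpolated/derived field is supplied via ``data`` ('cv' always
    needs ``data``).  Masked vertices render neutral gray.  Activation
    maps default to an isoluminant-safe sequential colormap ('viridis');
    pass ``cmap='rainbow'`` for clinical familiarity.  The two supported
    orientations ('ap'/'pa') are camera azimuths 180 degrees apart.
    """
    mesh = userdata.surface
    if mesh is None:
        raise MissingDataError("study has no surface mesh")
    if orientation not in _ORIENTATIONS:
        raise ValueError(f"orientation must be one of {sorted(_ORIENTATIONS)}")
    if data is not None:
        values, valid = data.values, data.valid
    elif map_type in ("act", "bip"):
        if map_type not in mesh.fields:
            raise MissingDataError(
                f"surface has no clinical {map_type!r} field; interpolate "
                "one with generate_interp_data"
            )
        values = mesh.fields[map_type]
        valid = np.isfinite(values)
    else:
        raise MissingDataError(
            f"map type {map_type!r} needs a computed field passed via data="
        )
    if cmap is None:
        cmap = "viridis" if map_type == "act" else "plasma"
    cm = plt.get_cmap(cmap)
    tri_vals = np.where(valid, values, np.nan)[mesh.triangles]
    tri_ok = np.isfinite(tri_vals).all(axis=1)
    tri_mean = np.nanmean(np.where(np.isfinite(tri_vals), tri_vals, 0.0),
                          axis=1)
    if color_axis is None:
        finite = values[valid]
        color_axis = (float(finite.min()), float(finite.max())) if finite.size \
            else (0.0, 1.0)
    lo, hi = color_axis
    span = hi - lo if hi > lo else 1.0
    norm = np.clip((tri_mean - lo) / span, 0, 1)
    face = np.array([cm(v) if ok else (0.6, 0.6, 0.6, 1.0)
                     for v, ok in zip(norm, tri_ok)])
    fig = plt.figure(figsize=(6, 6))
    ax = fig.add_subplot(projection="3d")
    polys = mesh.vertices[mesh.triangles]
    coll = Poly3DCollection(polys, facecolors=face, edgecolors="none")
    ax.add_collection3d(coll)
    span_xyz = mesh.vertices.max(axis=0) - mesh.vertices.min(axis=0)
    mid = (mesh.vertices.max(axis=0) + mesh.vertices.min(axis=0)) / 2
    r = span_xyz.max() / 2
    ax.set_xlim(mid[0] - r, mid[0] + r)
    ax.set_ylim(mid[1] - r, mid[1] + r)
    ax.set_zlim(mid[2] - r, mid[2] + r)
    elev, azim = _ORIENTATIONS[orientation]
    ax.view_init(elev=elev, azim=azim)
    ax.set_axis_off()
    ax.set_title(f"{map_type} map ({orientation})")
    out_path = Path(out_path if out_path is not None else f"{map_type}_map.png")
    fig.savefig(out_path, dpi=110)
    plt.close(fig)
    return out_path


def visitag_plot_data(userdata: UserData, color_by="index_value",
                      mode: str = "tags") -> dict:
    """Positions + raw color values for :func:`plot_visitags` (colors map
    the data range to the colormap; the data itself is never rescaled)."""
    v = userdata.rfindex
    if v is None:
        raise MissingDataError("study has no ablation data")
    if mode == "tags":
        pos = v.projected_positions
        vals = (np.asarray(color_by, dtype=float)
                if not isinstance(color_by, str) else v.parameter(color_by))
        if len(vals) != v.n_sites:
            raise ValueError("color values length does not match site count")
    elif mode == "grid":
        if v.grid_positions is None:
            raise MissingDataError(
                "study has no ablation grid data (sites only)"
            )
        pos = v.grid_positions
        if isinstance(color_by, str):
            params = v.grid_params or {}
            if color_by not in params:
                raise ValueError(
                    f"unknown grid parameter {color_by!r}; "
                    f"available: {sorted(params)}"
                )
            vals = params[color_by]
        else:
            vals = np.asarray(color_by, dtype=float)
    else:
        raise ValueError("mode must be 'tags' or 'grid'")
    return {"positions": pos, "values": np.asarray(vals, dtype=float),
            "mode": mode}


def _render_chamber(ax, mesh, facecolor=(0.85, 0.85, 0.85, 0.35)):
    polys = mesh.vertices[mesh.triangles]
    ax.add_collection3d(Poly3DCollection(polys, facecolors=facecolor,
                                         edgecolors="none"))
    span = mesh.vertices.max(axis=0) - mesh.vertices.min(axis=0)
    mid = (mesh.vertices.max(axis=0) + mesh.vertices.min(axis=0)) / 2
    r = span.max() / 2
    ax.set_xlim(mid[0] - r, mid[0] + r)
    ax.set_ylim(mid[1] - r, mid[1] + r)
    ax.set_zlim(mid[2] - r, mid[2] + r)
    ax.set_axis_off()


def plot_visitags(userdata: UserData, color_by="index_value",
                  mode: str = "tags", out_path="visitags.png") -> Path:
    """Render ablation sites ('tags') or the raw grid ('grid') over the
    chamber, colored by the chosen parameter (low=white, high=red)."""
    data = visitag_plot_data(userdata, color_by, mode)
    fig = plt.figure(figsize=(6, 6))
    ax = fig.add_subplot(projection="3d")
    if userdata.surface is not None:
        _render_chamber(ax, userdata.surface)
    pos, vals = data["positions"], data["values"]
    sc = ax.scatter(pos[:, 0], pos[:, 1], pos[:, 2], c=vals,
                    cmap=_ABLATION_CMAP, s=40 if mode == "tags" else 8,
                    edgecolors="k", linewidths=0.3)
    fig.colorbar(sc, ax=ax, shrink=0.6,
                 label=color_by if isinstance(color_by, str) else "value")
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=110)
    plt.close(fig)
    return out_path


def plot_ablation_area(userdata: UserData, result, out_path="ablation_area.png") -> Path:
    """Overlay the marked (ablated) triangles on the chamber rendering."""
    mesh = userdata.surface
    if mesh is None:
        raise MissingDataError("study has no surface mesh")
    marked = np.asarray(result.triangle_indices, dtype=np.int64)
    if marked.size and marked.max() >= mesh.n_triangles:
        raise ValueError("ablation result was computed on a different mesh")
    fig = plt.figure(figsize=(6, 6))
    ax = fig.add_subplot(projection="3d")
    _render_chamber(ax, mesh)
    if marked.size:
        polys = mesh.vertices[mesh.triangles[marked]]
        ax.add_collection3d(Poly3DCollection(polys, facecolors="crimson",
                                             edgecolors="none"))
    ax.set_title(f"ablated area {result.area:.2f} cm$^2$ "
                 f"(r = {result.radius:g} mm)")
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=110)
    plt.close(fig)
    return out_path
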