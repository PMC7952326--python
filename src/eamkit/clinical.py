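"""A documented, simplified clinical-export dialect.

Clinical mapping platforms export a study as a tree of XML descriptor
files plus many per-point text files and a geometry file.  The proprietary
schemas are not public, so this package defines a *simplified dialect with
the same structure* — a stand-in, not a bit-compatible parser for any
vendor format:

    <root>/
      study.xml            study name, source system, sampling rate,
                           list of maps, each enumerating its point ids
      mesh.xml             vertex / triangle blocks + per-vertex fields
      P<id>_point.xml      position, surface position, window of interest,
                           annotations, point voltages, tags   (one per point)
      P<id>_egm.csv        columns t_ms, ref, bip, uni1, uni2  (one per point)
      visitags/sites.csv   ablation sites (optional)
      visitags/grid.csv    raw ablation grid (optional)

Floats are printed with 17 significant digits so
``parse_clinical_export(emit_clinical_export(study))`` reproduces the
study bit-exactly.  Triangle indices are 0-based; a tree declaring
``index_base="1"`` in ``mesh.xml`` is converted on read.
"""

from __future__ import annotations

import logging
import xml.etree.ElementTree as ET
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .ablation import VisitagSet
from .container import write_container
from .errors import IntegrityError, MissingDataError
from .model import ElectricData, SurfaceMesh, UserData

__all__ = ["emit_clinical_export", "parse_clinical_export",
           "import_visitags", "batch_import"]

log = logging.getLogger("eamkit")

_F = "%.17g"


def _fmt(x) -> str:
    return _F % float(x)


def _fmt_row(row) -> str:
    return " ".join(_F % v for v in row)


# ---------------------------------------------------------------------------
# emitter
# ---------------------------------------------------------------------------

def emit_clinical_export(userdata: UserData, out_dir) -> Path:
    """Write a study as a clinical-dialect export tree; returns the root."""
    root = Path(out_dir)
    root.mkdir(parents=True, exist_ok=True)
    study = ET.Element("study", name=root.name,
                       system=userdata.system_name)
    notes = ET.SubElement(study, "notes")
    for n in userdata.notes:
        ET.SubElement(notes, "note").text = str(n)
    maps = ET.SubElement(study, "maps")
    e = userdata.electric
    m = ET.SubElement(maps, "map", name="map1")
    if e is not None:
        study.set("sample_frequency", _fmt(e.sample_frequency))
        for pid in e.point_ids:
            ET.SubElement(m, "point", id=str(int(pid)))
    ET.ElementTree(study).write(root / "study.xml")

    if userdata.surface is not None:
        _write_mesh(userdata.surface, root / "mesh.xml")
    if e is not None:
        t_ms = e.time_axis()
        for i, pid in enumerate(e.point_ids):
            _write_point(e, i, int(pid), root)
            df = pd.DataFrame({
                "t_ms": t_ms,
                "ref": e.ref_trace[i],
                "bip": e.bip_trace[i],
                "uni1": e.uni_traces[i, :, 0],
                "uni2": e.uni_traces[i, :, 1],
            })
            df.to_csv(root / f"P{int(pid)}_egm.csv", index=False,
                      float_format=_F, na_rep="NaN", lineterminator="\n")
    if userdata.rfindex is not None:
        _write_visitags(userdata.rfindex, root / "visitags")
    return root


def _write_mesh(mesh: SurfaceMesh, path: Path):
    el = ET.Element("mesh", index_base="0")
    v = ET.SubElement(el, "vertices", count=str(mesh.n_vertices))
    v.text = "\n" + "\n".join(_fmt_row(r) for r in mesh.vertices) + "\n"
    t = ET.SubElement(el, "triangles", count=str(mesh.n_triangles))
    t.text = "\n" + "\n".join(" ".join(str(i) for i in r)
                              for r in mesh.triangles) + "\n"
    fields = ET.SubElement(el, "fields")
    for name in sorted(mesh.fields):
        f = ET.SubElement(fields, "field", name=name)
        f.text = "\n" + "\n".join(_fmt(x) for x in mesh.fields[name]) + "\n"
    ET.ElementTree(el).write(path)


def _write_point(e: ElectricData, i: int, pid: int, root: Path):
    el = ET.Element("point", id=str(pid), name=e.names[i])
    tags = ET.SubElement(el, "tags")
    for t in e.tags[i]:
        ET.SubElement(tags, "tag").text = t
    ET.SubElement(el, "position").text = _fmt_row(e.egm_x[i])
    ET.SubElement(el, "surface_position").text = _fmt_row(e.egm_surf_x[i])
    ET.SubElement(el, "ref_annot").text = _fmt(e.ref_annot[i])
    ma = e.map_annot[i]
    ET.SubElement(el, "map_annot").text = _fmt(ma) if np.isfinite(ma) else ""
    ET.SubElement(el, "woi", low=_fmt(e.woi[i, 0]), high=_fmt(e.woi[i, 1]))
    vb, vu = e.voltage_bip[i], e.voltage_uni[i]
    ET.SubElement(el, "voltages",
                  bip=_fmt(vb) if np.isfinite(vb) else "NaN",
                  uni=_fmt(vu) if np.isfinite(vu) else "NaN")
    if e.impedance is not None:
        ET.SubElement(el, "impedance").text = _fmt(e.impedance[i])
    ET.ElementTree(el).write(root / f"P{pid}_point.xml")


def _write_visitags(v: VisitagSet, vdir: Path):
    vdir.mkdir(exist_ok=True)
    pd.DataFrame({
        "x": v.positions[:, 0], "y": v.positions[:, 1], "z": v.positions[:, 2],
        "surf_x": v.projected_positions[:, 0],
        "surf_y": v.projected_positions[:, 1],
        "surf_z": v.projected_positions[:, 2],
        "index_name": [v.index_name] * v.n_sites,
        "index_value": v.index_value, "force": v.force, "power": v.power,
        "temperature": v.temperature, "impedance": v.impedance,
        "duration": v.duration,
    }).to_csv(vdir / "sites.csv", index=False, float_format=_F,
              na_rep="NaN", lineterminator="\n")
    if v.grid_positions is not None:
        g = {"x": v.grid_positions[:, 0], "y": v.grid_positions[:, 1],
             "z": v.grid_positions[:, 2]}
        g.update(v.grid_params or {})
        pd.DataFrame(g).to_csv(vdir / "grid.csv", index=False,
                               float_format=_F, na_rep="NaN",
                               lineterminator="\n")


# ---------------------------------------------------------------------------
# parser
# ---------------------------------------------------------------------------

def _parse_xml(path: Path) -> ET.Element:
    try:
        return ET.parse(path).getroot()
    except ET.ParseError as exc:
        line, col = exc.position
        raise IntegrityError(
            f"malformed XML in {path} at line {line}, column {col}: {exc.msg}"
        ) from exc
    except FileNotFoundError as exc:
        raise IntegrityError(f"missing file {path}") from exc


def _floats(text: str, cols: int, what: str) -> np.ndarray:
    rows = [r for r in (text or "").strip().splitlines() if r.strip()]
    if not rows:
        return np.zeros((0, cols))
    try:
        arr = np.array([[float(x) for x in r.split()] for r in rows])
    except ValueError as exc:
        raise IntegrityError(f"non-numeric entry in {what}: {exc}") from exc
    if arr.shape[1] != cols:
        raise IntegrityError(f"{what} expects {cols} columns, got {arr.shape[1]}")
    return arr


def _read_mesh(path: Path) -> SurfaceMesh:
    el = _parse_xml(path)
    base = int(el.get("index_base", "0"))
    vx = el.find("vertices")
    tx = el.find("triangles")
    if vx is None or tx is None:
        raise IntegrityError(f"{path} lacks vertices/triangles blocks")
    verts = _floats(vx.text, 3, "mesh vertices")
    tris = _floats(tx.text, 3, "mesh triangles").astype(np.int64) - base
    if int(vx.get("count", len(verts))) != len(verts):
        raise IntegrityError(f"{path}: vertex count attribute mismatch")
    if int(tx.get("count", len(tris))) != len(tris):
        raise IntegrityError(f"{path}: triangle count attribute mismatch")
    fields = {}
    fblock = el.find("fields")
    if fblock is not None:
        for f in fblock.findall("field"):
            vals = np.array([float(x) for x in (f.text or "").split()])
            if len(vals) != len(verts):
                raise IntegrityError(
                    f"{path}: field {f.get('name')!r} length mismatch"
                )
            fields[f.get("name")] = vals
    return SurfaceMesh(verts, tris, fields)


def parse_clinical_export(tree_root, map_name: Optional[str] = None,
                          ref_channel: str = "ref",
                          ecg_channel: Optional[str] = None) -> UserData:
    """Parse a clinical-dialect export tree into a study.

    When ``map_name`` is omitted and the study holds exactly one map it is
    selected; with several maps an error lists the available names.
    ``ref_channel`` names the reference column in the per-point trace CSVs
    (the dialect's default channel set is ref/bip/uni1/uni2);
    ``ecg_channel``, if given, must also name a CSV column and is accepted
    for interface parity (the dialect carries no separate ECG block).
    """
    root = Path(tree_root)
    study = _parse_xml(root / "study.xml")
    maps = study.find("maps")
    names = [m.get("name") for m in maps.findall("map")] if maps is not None else []
    if map_name is None:
        if len(names) != 1:
            raise MissingDataError(
                f"study holds {len(names)} maps; specify map_name from {names}"
            )
        map_name = names[0]
    if map_name not in names:
        raise MissingDataError(f"map {map_name!r} not found; available: {names}")
    chosen = [m for m in maps.findall("map") if m.get("name") == map_name][0]
    point_ids = [int(p.get("id")) for p in chosen.findall("point")]

    surface = None
    if (root / "mesh.xml").exists():
        surface = _read_mesh(root / "mesh.xml")

    electric = None
    if point_ids:
        fs_attr = study.get("sample_frequency")
        if fs_attr is None:
            raise IntegrityError("study.xml lacks sample_frequency")
        electric = _read_points(root, point_ids, float(fs_attr),
                                ref_channel, ecg_channel)

    rfindex = None
    if (root / "visitags" / "sites.csv").exists():
        rfindex = import_visitags(root)

    notes = [n.text or "" for n in study.findall("./notes/note")]
    return UserData(system_name=study.get("system", "unknown"),
                    notes=notes, surface=surface, electric=electric,
                    rfindex=rfindex)


def _read_points(root: Path, point_ids, fs: float, ref_channel: str,
                 ecg_channel: Optional[str]) -> ElectricData:
    recs = {k: [] for k in ("names", "tags", "egm_x", "egm_surf_x",
                            "ref_annot", "map_annot", "woi",
                            "voltage_bip", "voltage_uni", "impedance")}
    ref_rows, bip_rows, uni_rows = [], [], []
    for pid in point_ids:
        ppath = root / f"P{pid}_point.xml"
        if not ppath.exists():
            raise IntegrityError(
                f"study.xml lists point id {pid} but {ppath.name} is missing"
            )
        el = _parse_xml(ppath)
        recs["names"].append(el.get("name", f"P{pid}"))
        recs["tags"].append([t.text or "" for t in el.findall("./tags/tag")])
        recs["egm_x"].append([float(x) for x in el.findtext("position").split()])
        recs["egm_surf_x"].append(
            [float(x) for x in el.findtext("surface_position").split()])
        recs["ref_annot"].append(float(el.findtext("ref_annot")))
        ma = (el.findtext("map_annot") or "").strip()
        recs["map_annot"].append(float(ma) if ma else np.nan)
        w = el.find("woi")
        recs["woi"].append([float(w.get("low")), float(w.get("high"))])
        v = el.find("voltages")
        recs["voltage_bip"].append(float(v.get("bip")))
        recs["voltage_uni"].append(float(v.get("uni")))
        z = el.findtext("impedance")
        recs["impedance"].append(float(z) if z is not None else np.nan)
        epath = root / f"P{pid}_egm.csv"
        if not epath.exists():
            raise IntegrityError(
                f"point id {pid}: trace file {epath.name} is missing"
            )
        df = pd.read_csv(epath, float_precision="round_trip")
        for col in (ref_channel, "bip", "uni1", "uni2"):
            if col not in df.columns:
                raise IntegrityError(
                    f"point id {pid}: trace file lacks column {col!r}"
                )
        if ecg_channel is not None and ecg_channel not in df.columns:
            raise IntegrityError(
                f"point id {pid}: trace file lacks ECG column {ecg_channel!r}"
            )
        ref_rows.append(df[ref_channel].to_numpy(float))
        bip_rows.append(df["bip"].to_numpy(float))
        uni_rows.append(np.stack([df["uni1"].to_numpy(float),
                                  df["uni2"].to_numpy(float)], axis=1))
    lengths = {len(r) for r in ref_rows}
    if len(lengths) > 1:
        raise IntegrityError("trace lengths differ between points")
    return ElectricData(
        point_ids=np.asarray(point_ids, dtype=np.int64),
        names=recs["names"], tags=recs["tags"],
        egm_x=np.asarray(recs["egm_x"]),
        egm_surf_x=np.asarray(recs["egm_surf_x"]),
        ref_trace=np.vstack(ref_rows), bip_trace=np.vstack(bip_rows),
        uni_traces=np.stack(uni_rows), sample_frequency=fs,
        ref_annot=np.asarray(recs["ref_annot"]),
        map_annot=np.asarray(recs["map_annot"]),
        woi=np.asarray(recs["woi"]),
        voltage_bip=np.asarray(recs["voltage_bip"]),
        voltage_uni=np.asarray(recs["voltage_uni"]),
        impedance=np.asarray(recs["impedance"]),
    )


_SITE_COLS = ("x", "y", "z", "surf_x", "surf_y", "surf_z", "index_value",
              "force", "power", "temperature", "impedance", "duration")


def import_visitags(tree_root_or_file) -> VisitagSet:
    """Import ablation sites (and, if present, the raw ablation grid) from
    an export tree root or a sites CSV path."""
    p = Path(tree_root_or_file)
    sites_path = p if p.is_file() else p / "visitags" / "sites.csv"
    if not sites_path.exists():
        raise IntegrityError(f"visitag site file not found: {sites_path}")
    df = pd.read_csv(sites_path, float_precision="round_trip")
    for col in _SITE_COLS:
        if col not in df.columns:
            raise IntegrityError(f"visitag site file lacks column {col!r}")
    index_name = (str(df["index_name"].iloc[0])
                  if "index_name" in df.columns and len(df) else "index")
    grid_pos, grid_params = None, None
    grid_path = sites_path.parent / "grid.csv"
    if grid_path.exists():
        g = pd.read_csv(grid_path, float_precision="round_trip")
        for col in ("x", "y", "z"):
            if col not in g.columns:
                raise IntegrityError(f"visitag grid file lacks column {col!r}")
        grid_pos = g[["x", "y", "z"]].to_numpy(float)
        grid_params = {c: g[c].to_numpy(float) for c in g.columns
                       if c not in ("x", "y", "z")}
    return VisitagSet(
        positions=df[["x", "y", "z"]].to_numpy(float),
        projected_positions=df[["surf_x", "surf_y", "surf_z"]].to_numpy(float),
        index_name=index_name,
        index_value=df["index_value"].to_numpy(float),
        force=df["force"].to_numpy(float),
        power=df["power"].to_numpy(float),
        temperature=df["temperature"].to_numpy(float),
        impedance=df["impedance"].to_numpy(float),
        duration=df["duration"].to_numpy(float),
        grid_positions=grid_pos, grid_params=grid_params,
    )


def batch_import(directory, out_dir=None) -> list:
    """Convert every export tree under ``directory`` to a container.

    A subdirectory containing ``study.xml`` is treated as one export tree.
    Per-study failures are logged and skipped; the returned list holds the
    successfully written container paths in lexicographic order.
    """
    directory = Path(directory)
    out_dir = Path(out_dir) if out_dir is not None else directory
    out_dir.mkdir(parents=True, exist_ok=True)
    trees = sorted(p.parent for p in directory.glob("*/study.xml"))
    if not trees:
        log.warning("no export trees found under %s", directory)
        return []
    written = []
    for tree in trees:
        target = out_dir / f"{tree.name}.openep.zip"
        try:
            ud = parse_clinical_export(tree)
            write_container(ud, target)
            written.append(target)
        except Exception as exc:  # per-study isolation is the contract
            log.error("skipping %s: %s", tree.name, exc)
    return sorted(written)
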