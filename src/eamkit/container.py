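"""The exchange container: one zip per study.

A study is stored as ``<name>.openep.zip`` holding ``manifest.json`` plus
one CSV per array.  Design goals, in order: (1) a *single* file per study
(no per-point file-system overhead), (2) no redundancy — identical
electrogram traces are stored once and referenced by index, (3) a
language-agnostic, diff-able representation: comma-separated, header row,
``NaN`` for missing, UTF-8, LF line endings, and all floats printed with
17 significant digits so read-back is bit-exact for 64-bit values.

The manifest declares the schema version, units, study metadata and the
shape/dtype of every array; :func:`read_container` validates the declared
shapes before reconstructing the study and raises an integrity error
naming the offending array otherwise.  Arrays the reader does not know
are accepted with a warning (forward compatibility).
"""

from __future__ import annotations

import io
import json
import warnings
import zipfile
from pathlib import Path

import numpy as np
import pandas as pd

from .ablation import VisitagSet
from .errors import IntegrityError, SchemaError
from .model import UNITS, ElectricData, SurfaceMesh, UserData

__all__ = ["SCHEMA_VERSION", "write_container", "read_container"]

SCHEMA_VERSION = "1.0"
_FLOAT_FMT = "%.17g"

_KNOWN_ARRAYS = {
    "surface_vertices", "surface_triangles", "surface_fields",
    "electric_points", "traces", "visitag_sites", "visitag_grid",
}


def _df_to_csv(df: pd.DataFrame) -> str:
    return df.to_csv(index=False, float_format=_FLOAT_FMT, na_rep="NaN",
                     lineterminator="\n")


def _array_entry(fname, df):
    return {"file": fname, "rows": int(len(df)), "cols": int(df.shape[1]),
            "dtype": "mixed"}


class _TraceStore:
    """Deduplicating trace table: identical rows stored once."""

    def __init__(self):
        self.rows = []
        self._index = {}

    def add(self, trace: np.ndarray) -> int:
        key = np.asarray(trace, dtype=np.float64).tobytes()
        if key not in self._index:
            self._index[key] = len(self.rows)
            self.rows.append(np.asarray(trace, dtype=np.float64))
        return self._index[key]

    def frame(self) -> pd.DataFrame:
        if not self.rows:
            return pd.DataFrame()
        arr = np.vstack(self.rows)
        return pd.DataFrame(arr, columns=[f"s{j}" for j in range(arr.shape[1])])


def write_container(userdata: UserData, path) -> Path:
    """Serialize a study to ``path`` (conventionally ``*.openep.zip``).

    Returns the written path.  Identical traces shared by several points
    (e.g. a common reference channel) are stored once and indexed.
    """
    path = Path(path)
    arrays = {}
    frames = {}
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "units": UNITS,
        "system_name": userdata.system_name,
        "notes": list(userdata.notes),
        "arrays": arrays,
    }
    if userdata.surface is not None:
        m = userdata.surface
        frames["surface_vertices"] = pd.DataFrame(m.vertices,
                                                  columns=["x", "y", "z"])
        frames["surface_triangles"] = pd.DataFrame(m.triangles,
                                                   columns=["v0", "v1", "v2"])
        manifest["surface_field_names"] = sorted(m.fields)
        if m.fields:
            frames["surface_fields"] = pd.DataFrame(
                {k: m.fields[k] for k in sorted(m.fields)})
    if userdata.electric is not None:
        e = userdata.electric
        store = _TraceStore()
        ref_i = [store.add(t) for t in e.ref_trace]
        bip_i = [store.add(t) for t in e.bip_trace]
        uni1_i = [store.add(t) for t in e.uni_traces[:, :, 0]]
        uni2_i = [store.add(t) for t in e.uni_traces[:, :, 1]]
        frames["traces"] = store.frame()
        frames["electric_points"] = pd.DataFrame({
            "id": e.point_ids,
            "name": e.names,
            "tags": ["|".join(t) for t in e.tags],
            "egm_x_x": e.egm_x[:, 0], "egm_x_y": e.egm_x[:, 1],
            "egm_x_z": e.egm_x[:, 2],
            "egm_surf_x_x": e.egm_surf_x[:, 0],
            "egm_surf_x_y": e.egm_surf_x[:, 1],
            "egm_surf_x_z": e.egm_surf_x[:, 2],
            "ref_annot": e.ref_annot, "map_annot": e.map_annot,
            "woi_low": e.woi[:, 0], "woi_high": e.woi[:, 1],
            "voltage_bip": e.voltage_bip, "voltage_uni": e.voltage_uni,
            "impedance": (e.impedance if e.impedance is not None
                          else np.full(e.n_points, np.nan)),
            "trace_ref_index": ref_i, "trace_bip_index": bip_i,
            "trace_uni1_index": uni1_i, "trace_uni2_index": uni2_i,
        })
        manifest["sample_frequency"] = e.sample_frequency
        manifest["n_trace_samples"] = int(e.n_samples)
        manifest["has_impedance"] = e.impedance is not None
    if userdata.rfindex is not None:
        v = userdata.rfindex
        frames["visitag_sites"] = pd.DataFrame({
            "x": v.positions[:, 0], "y": v.positions[:, 1],
            "z": v.positions[:, 2],
            "surf_x": v.projected_positions[:, 0],
            "surf_y": v.projected_positions[:, 1],
            "surf_z": v.projected_positions[:, 2],
            "index_value": v.index_value, "force": v.force,
            "power": v.power, "temperature": v.temperature,
            "impedance": v.impedance, "duration": v.duration,
        })
        manifest["visitag_index_name"] = v.index_name
        if v.grid_positions is not None:
            g = {"x": v.grid_positions[:, 0], "y": v.grid_positions[:, 1],
                 "z": v.grid_positions[:, 2]}
            g.update(v.grid_params or {})
            frames["visitag_grid"] = pd.DataFrame(g)
    for name, df in frames.items():
        arrays[name] = _array_entry(f"{name}.csv", df)
    try:
        with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as z:
            z.writestr("manifest.json", json.dumps(manifest, indent=1))
            for name, df in frames.items():
                z.writestr(f"{name}.csv", _df_to_csv(df))
    except OSError as exc:
        raise IntegrityError(f"cannot write container to {path}: {exc}") from exc
    return path


def _load_array(z: zipfile.ZipFile, manifest: dict, name: str) -> pd.DataFrame:
    entry = manifest["arrays"][name]
    try:
        raw = z.read(entry["file"])
    except KeyError as exc:
        raise IntegrityError(
            f"container missing declared array file {entry['file']!r}"
        ) from exc
    try:
        # round_trip parsing keeps 17-significant-digit text bit-exact
        df = pd.read_csv(io.BytesIO(raw), float_precision="round_trip")
    except Exception as exc:
        raise IntegrityError(f"array {name!r} is unreadable: {exc}") from exc
    if len(df) != entry["rows"] or df.shape[1] != entry["cols"]:
        raise IntegrityError(
            f"array {name!r} shape mismatch: manifest declares "
            f"({entry['rows']}, {entry['cols']}), file holds {df.shape}"
        )
    if df.isna().any().any() and name in ("surface_triangles",):
        raise IntegrityError(f"array {name!r} contains missing entries")
    return df


def read_container(path) -> UserData:
    """Read a study container written by :func:`write_container`,
    validating the manifest before reconstruction."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"container not found: {path}")
    with zipfile.ZipFile(path) as z:
        try:
            manifest = json.loads(z.read("manifest.json"))
        except KeyError as exc:
            raise IntegrityError("container has no manifest.json") from exc
        version = manifest.get("schema_version")
        if version != SCHEMA_VERSION:
            raise SchemaError(
                f"unsupported container schema {version!r}; this build "
                f"reads schema {SCHEMA_VERSION!r}"
            )
        unknown = set(manifest["arrays"]) - _KNOWN_ARRAYS
        if unknown:
            warnings.warn(
                f"container declares unknown arrays {sorted(unknown)}; "
                "ignored for forward compatibility",
                stacklevel=2,
            )
        have = lambda n: n in manifest["arrays"]  # noqa: E731
        surface = None
        if have("surface_vertices"):
            verts = _load_array(z, manifest, "surface_vertices")
            tris = _load_array(z, manifest, "surface_triangles")
            fields = {}
            if have("surface_fields"):
                f = _load_array(z, manifest, "surface_fields")
                if len(f) != len(verts):
                    raise IntegrityError(
                        "array 'surface_fields' row count does not match "
                        "'surface_vertices'"
                    )
                fields = {c: f[c].to_numpy(dtype=np.float64) for c in f.columns}
            surface = SurfaceMesh(verts.to_numpy(dtype=np.float64),
                                  tris.to_numpy(dtype=np.int64), fields)
        electric = None
        if have("electric_points"):
            pts = _load_array(z, manifest, "electric_points")
            traces = _load_array(z, manifest, "traces").to_numpy(
                dtype=np.float64)
            T = manifest.get("n_trace_samples", traces.shape[1] if traces.size else 0)
            if traces.size and traces.shape[1] != T:
                raise IntegrityError(
                    "array 'traces' sample count does not match manifest"
                )

            def tr(col):
                idx = pts[col].to_numpy(dtype=np.int64)
                if idx.size and (idx.min() < 0 or idx.max() >= len(traces)):
                    raise IntegrityError(
                        f"array 'electric_points' column {col!r} references "
                        "a trace outside 'traces'"
                    )
                return traces[idx]

            uni = np.stack([tr("trace_uni1_index"), tr("trace_uni2_index")],
                           axis=2)
            tags = [t.split("|") if t else []
                    for t in pts["tags"].fillna("").astype(str)]
            imp = pts["impedance"].to_numpy(dtype=np.float64)
            electric = ElectricData(
                point_ids=pts["id"].to_numpy(dtype=np.int64),
                names=pts["name"].astype(str).tolist(),
                tags=tags,
                egm_x=pts[["egm_x_x", "egm_x_y", "egm_x_z"]].to_numpy(float),
                egm_surf_x=pts[["egm_surf_x_x", "egm_surf_x_y",
                                "egm_surf_x_z"]].to_numpy(float),
                ref_trace=tr("trace_ref_index"),
                bip_trace=tr("trace_bip_index"),
                uni_traces=uni,
                sample_frequency=manifest["sample_frequency"],
                ref_annot=pts["ref_annot"].to_numpy(float),
                map_annot=pts["map_annot"].to_numpy(float),
                woi=pts[["woi_low", "woi_high"]].to_numpy(float),
                voltage_bip=pts["voltage_bip"].to_numpy(float),
                voltage_uni=pts["voltage_uni"].to_numpy(float),
                impedance=imp if manifest.get("has_impedance", True) else None,
            )
        rfindex = None
        if have("visitag_sites"):
            s = _load_array(z, manifest, "visitag_sites")
            grid_pos, grid_params = None, None
            if have("visitag_grid"):
                g = _load_array(z, manifest, "visitag_grid")
                grid_pos = g[["x", "y", "z"]].to_numpy(float)
                grid_params = {c: g[c].to_numpy(float) for c in g.columns
                               if c not in ("x", "y", "z")}
            rfindex = VisitagSet(
                positions=s[["x", "y", "z"]].to_numpy(float),
                projected_positions=s[["surf_x", "surf_y",
                                       "surf_z"]].to_numpy(float),
                index_name=manifest.get("visitag_index_name", "index"),
                index_value=s["index_value"].to_numpy(float),
                force=s["force"].to_numpy(float),
                power=s["power"].to_numpy(float),
                temperature=s["temperature"].to_numpy(float),
                impedance=s["impedance"].to_numpy(float),
                duration=s["duration"].to_numpy(float),
                grid_positions=grid_pos,
                grid_params=grid_params,
            )
    return UserData(system_name=manifest.get("system_name", "unknown"),
                    notes=list(manifest.get("notes", [])),
                    surface=surface, electric=electric, rfindex=rfindex)
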