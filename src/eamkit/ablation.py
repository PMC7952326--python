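"""Radiofrequency ablation-lesion (visitag) representation and metrics.

Clinical systems record each energy delivery as a site with position and
per-site parameters (contact force, power, temperature, impedance,
duration) plus a lesion-quality index; index semantics vary per platform
(Ablation Index, Lesion Size Index, ...), so the index is stored as a
named value.  Ablated surface area is quantified by marking every triangle
whose centroid lies within an influence radius of any projected site —
union semantics, so overlapping lesions are counted once.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from .errors import MissingDataError
from .model import UserData

__all__ = ["VisitagSet", "AblationAreaResult", "get_ablation_area",
           "DEFAULT_ABLATION_RADIUS_MM"]

#: Influence radius used for ablated-area marking; approximates a typical
#: radiofrequency lesion radius and is exposed as a parameter everywhere.
DEFAULT_ABLATION_RADIUS_MM = 5.0

_PARAMS = ("index_value", "force", "power", "temperature", "impedance",
           "duration")


@dataclass
class VisitagSet:
    """Ablation-lesion sites with per-site parameters and optional raw grid.

    positions / projected_positions : (k, 3) mm (raw catheter vs surface).
    index_name names the lesion-quality index stored in ``index_value``.
    Units: force g, power W, temperature degC, impedance Ohm, duration s.
    """

    positions: np.ndarray
    projected_positions: np.ndarray
    index_name: str = "AblationIndex"
    index_value: Optional[np.ndarray] = None
    force: Optional[np.ndarray] = None
    power: Optional[np.ndarray] = None
    temperature: Optional[np.ndarray] = None
    impedance: Optional[np.ndarray] = None
    duration: Optional[np.ndarray] = None
    grid_positions: Optional[np.ndarray] = None
    grid_params: Optional[dict] = None

    def __post_init__(self):
        self.positions = np.atleast_2d(
            np.asarray(self.positions, dtype=np.float64)).reshape(-1, 3)
        self.projected_positions = np.atleast_2d(
            np.asarray(self.projected_positions, dtype=np.float64)).reshape(-1, 3)
        k = len(self.positions)
        if len(self.projected_positions) != k:
            raise ValueError("positions/projected_positions length mismatch")
        for name in _PARAMS:
            v = getattr(self, name)
            if v is None:
                v = np.full(k, np.nan)
            v = np.asarray(v, dtype=np.float64).reshape(-1)
            if len(v) != k:
                raise ValueError(f"{name} must have length {k}")
            setattr(self, name, v)
        if np.any(self.duration[np.isfinite(self.duration)] < 0):
            raise ValueError("durations must be >= 0")
        if self.grid_positions is not None:
            self.grid_positions = np.atleast_2d(
                np.asarray(self.grid_positions, dtype=np.float64)).reshape(-1, 3)
            gp = {}
            for name, v in (self.grid_params or {}).items():
                v = np.asarray(v, dtype=np.float64).reshape(-1)
                if len(v) != len(self.grid_positions):
                    raise ValueError(f"grid param {name!r} length mismatch")
                gp[name] = v
            self.grid_params = gp
        elif self.grid_params:
            raise ValueError("grid_params without grid_positions")

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    def parameter(self, name: str) -> np.ndarray:
        """Per-site parameter values by name ('index_value', 'force', ...)."""
        if name not in _PARAMS:
            raise ValueError(
                f"unknown ablation parameter {name!r}; available: {_PARAMS}"
            )
        return getattr(self, name)


@dataclass
class AblationAreaResult:
    """Ablated-surface quantification at one influence radius."""

    radius: float  # mm
    area: float  # cm^2
    triangle_indices: np.ndarray  # marked triangles (union over sites)


def get_ablation_area(userdata: UserData,
                      radius: float = DEFAULT_ABLATION_RADIUS_MM) -> AblationAreaResult:
    """Surface area within ``radius`` mm of any projected ablation site.

    A triangle is marked if its centroid lies within the radius of at least
    one site; the area is the sum over marked triangles (cm^2), so
    duplicated or overlapping lesions are never double-counted.
    """
    if userdata.rfindex is None:
        raise MissingDataError(
            "study has no ablation data; run import_visitags first"
        )
    if userdata.surface is None:
        raise MissingDataError("study has no surface mesh")
    mesh = userdata.surface
    sites = userdata.rfindex.projected_positions
    if len(sites) == 0:
        return AblationAreaResult(radius=float(radius), area=0.0,
                                  triangle_indices=np.zeros(0, dtype=np.int64))
    tree = cKDTree(sites)
    d, _ = tree.query(mesh.triangle_centroids())
    marked = np.nonzero(d <= radius)[0]
    area = float(mesh.triangle_areas()[marked].sum()) / 100.0
    return AblationAreaResult(radius=float(radius), area=area,
                              triangle_indices=marked)
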