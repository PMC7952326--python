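"""Scattered interpolation of point measurements onto the chamber surface.

Mapping systems acquire values (activation time, voltage) at scattered
catheter positions; a surface map requires interpolating them to every mesh
vertex.  The default scheme is Gaussian radial-basis-function (RBF)
interpolation

    s(x) = sum_i c_i * phi(||x - x_i||),      (Phi + lambda I) c = y,

with kernel width sigma set to twice the mean nearest-neighbour spacing of
the sample points and a small ridge lambda = 1e-8 * trace(Phi)/p for
numerical stability.  The RBF interpolant is smooth and differentiable,
which the conduction-velocity module relies on; inverse-distance and
nearest-neighbour schemes are provided as alternatives.

Vertices farther than a color-fill threshold (default 10 mm, the clinical
display convention) from every contributing point are masked invalid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .errors import MissingDataError
from .model import SurfaceField, SurfaceMesh, UserData

__all__ = [
    "InterpolatorSpec",
    "ScatteredInterpolator",
    "generate_interp_data",
    "color_fill_mask",
    "DEFAULT_FILL_THRESHOLD_MM",
]

#: Clinical display convention: surface farther than this from every mapping
#: point is left uncolored.
DEFAULT_FILL_THRESHOLD_MM = 10.0

_SCHEMES = ("rbf-gaussian", "rbf-multiquadric", "idw", "nearest")


@dataclass
class InterpolatorSpec:
    """Configuration of the scattered-data interpolator.

    sigma : kernel width in mm (RBF schemes); None -> 2x mean
        nearest-neighbour spacing of the sample points.
    lam : ridge regularization; None -> 1e-8 * trace(Phi) / p; 0 requests
        exact interpolation (with automatic fallback if the system is
        singular, e.g. duplicate positions).
    idw_power : inverse-distance weighting exponent.
    poly : augment the RBF expansion with a constant + linear polynomial
        tail (coefficients constrained orthogonal to the kernel weights).
        A plain RBF expansion cannot reproduce even a linear field exactly;
        with the tail, constant and linear fields are reproduced to
        rounding, which the conduction-velocity gradient relies on.
        Automatically disabled below 4 sample points.
    """

    scheme: str = "rbf-gaussian"
    sigma: Optional[float] = None
    lam: Optional[float] = None
    idw_power: float = 2.0
    poly: bool = True

    def __post_init__(self):
        if self.scheme not in _SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}; choose from {_SCHEMES}")
        if self.sigma is not None and not self.sigma > 0:
            raise ValueError("sigma must be > 0")
        if self.lam is not None and self.lam < 0:
            raise ValueError("lam must be >= 0")


def _mean_nn_spacing(x: np.ndarray) -> float:
    if len(x) < 2:
        return 1.0
    tree = cKDTree(x)
    d, _ = tree.query(x, k=2)
    nn = d[:, 1]
    nn = nn[nn > 0]
    return float(nn.mean()) if nn.size else 1.0


class ScatteredInterpolator:
    """Fitted scattered-data interpolant with optional analytic gradient.

    Parameters
    ----------
    x : (p, 3) sample positions (mm)
    y : (p,) sample values
    spec : InterpolatorSpec
    """

    def __init__(self, x, y, spec: Optional[InterpolatorSpec] = None):
        self.spec = spec or InterpolatorSpec()
        self.x = np.atleast_2d(np.asarray(x, dtype=np.float64))
        self.y = np.asarray(y, dtype=np.float64).reshape(-1)
        if len(self.x) != len(self.y):
            raise ValueError("x and y length mismatch")
        if len(self.x) == 0:
            raise MissingDataError("no sample points to interpolate")
        s = self.spec
        self.sigma = s.sigma if s.sigma is not None else 2.0 * _mean_nn_spacing(self.x)
        if s.scheme.startswith("rbf"):
            self._fit_rbf()
        elif s.scheme == "nearest":
            self._tree = cKDTree(self.x)

    # -- kernels ----------------------------------------------------------

    def _phi(self, r):
        if self.spec.scheme == "rbf-gaussian":
            return np.exp(-(r * r) / (2.0 * self.sigma ** 2))
        # multiquadric
        return np.sqrt(r * r + self.sigma ** 2)

    def _fit_rbf(self):
        p = len(self.x)
        Phi = self._phi(cdist(self.x, self.x))
        lam = self.spec.lam
        auto = 1e-8 * np.trace(Phi) / p
        if lam is None:
            lam = auto
        self._use_poly = self.spec.poly and p >= 4
        if lam == 0.0 and len(np.unique(self.x, axis=0)) < p:
            # duplicate positions make exact interpolation singular
            warnings.warn(
                "duplicate sample positions make the interpolation system "
                "singular at lambda=0; falling back to lambda=%.3g" % auto,
                stacklevel=3,
            )
            lam = max(auto, 1e-12)
        try:
            self._solve_rbf(Phi, lam)
            if not np.all(np.isfinite(self.coef_)):
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            warnings.warn(
                "interpolation system singular at lambda=%.3g; "
                "falling back to lambda=%.3g" % (lam, auto),
                stacklevel=3,
            )
            self._solve_rbf(Phi, max(auto, 1e-12))

    def _solve_rbf(self, Phi, lam):
        p = len(self.x)
        A_kernel = Phi + lam * np.eye(p)
        if not self._use_poly:
            self.coef_ = np.linalg.solve(A_kernel, self.y)
            self.poly_coef_ = np.zeros(4)
            return
        # saddle system: [Phi+lam*I  P; P^T  0] [c; d] = [y; 0]
        P = np.hstack([np.ones((p, 1)), self.x])
        A = np.block([[A_kernel, P], [P.T, np.zeros((4, 4))]])
        rhs = np.concatenate([self.y, np.zeros(4)])
        # coplanar/collinear sites make the polynomial block rank-deficient
        # and the saddle system exactly singular; take the minimum-norm
        # solution there instead of trusting a pivoted solve
        if np.linalg.matrix_rank(P, tol=1e-9 * max(1.0, np.abs(P).max())) < 4:
            sol = np.linalg.lstsq(A, rhs, rcond=None)[0]
        else:
            try:
                sol = np.linalg.solve(A, rhs)
            except np.linalg.LinAlgError:
                sol = np.linalg.lstsq(A, rhs, rcond=None)[0]
        self.coef_ = sol[:p]
        self.poly_coef_ = sol[p:]

    @property
    def differentiable(self) -> bool:
        return self.spec.scheme.startswith("rbf")

    # -- evaluation -------------------------------------------------------

    def __call__(self, q) -> np.ndarray:
        q = np.atleast_2d(np.asarray(q, dtype=np.float64))
        scheme = self.spec.scheme
        if scheme.startswith("rbf"):
            val = self._phi(cdist(q, self.x)) @ self.coef_
            d = self.poly_coef_
            return val + d[0] + q @ d[1:]
        if scheme == "nearest":
            _, idx = self._tree.query(q)
            return self.y[idx]
        # idw with exact hit handling
        d = cdist(q, self.x)
        out = np.empty(len(q))
        exact = d < 1e-12
        with np.errstate(divide="ignore"):
            w = 1.0 / d ** self.spec.idw_power
        for i in range(len(q)):
            hit = np.nonzero(exact[i])[0]
            if hit.size:
                out[i] = self.y[hit[0]]
            else:
                out[i] = np.dot(w[i], self.y) / w[i].sum()
        return out

    def gradient(self, q) -> np.ndarray:
        """Analytic gradient (value units per mm) at query points; RBF
        schemes only."""
        if not self.differentiable:
            raise ValueError(
                f"scheme {self.spec.scheme!r} is not differentiable; "
                "use an rbf scheme"
            )
        q = np.atleast_2d(np.asarray(q, dtype=np.float64))
        diff = q[:, None, :] - self.x[None, :, :]  # (m, p, 3)
        r = np.linalg.norm(diff, axis=2)
        if self.spec.scheme == "rbf-gaussian":
            # d/dx phi = -phi(r) * (x - xi) / sigma^2
            w = -self._phi(r) / self.sigma ** 2
        else:
            w = 1.0 / self._phi(r)
        grad = np.einsum("mp,mpk,p->mk", w, diff, self.coef_)
        return grad + self.poly_coef_[1:]


def color_fill_mask(mesh: SurfaceMesh, point_positions,
                    threshold: float = DEFAULT_FILL_THRESHOLD_MM) -> np.ndarray:
    """Vertex validity mask: True iff the Euclidean distance to the nearest
    contributing point is <= ``threshold`` mm."""
    if not threshold > 0:
        raise ValueError("threshold must be > 0")
    pts = np.atleast_2d(np.asarray(point_positions, dtype=np.float64))
    if len(pts) == 0:
        return np.zeros(mesh.n_vertices, dtype=bool)
    tree = cKDTree(pts)
    d, _ = tree.query(mesh.vertices)
    return d <= threshold


_DATATYPES = {
    "lat-map": ("lat", "lat"),
    "bip-map": ("bip", "bip"),
    "uni-map": ("uni", "uni"),
}


def _point_samples(userdata: UserData, datatype: str):
    e = userdata.electric
    if e is None:
        raise MissingDataError("study has no electrical data")
    usable = ~e.location_only_mask()
    if datatype == "lat-map":
        vals = e.lat_values()
    elif datatype == "bip-map":
        vals = e.voltage_bip
    elif datatype == "uni-map":
        vals = e.voltage_uni
    else:
        raise ValueError(
            f"unknown datatype {datatype!r}; choose from {sorted(_DATATYPES)}"
        )
    usable = usable & np.isfinite(vals) & np.isfinite(e.egm_surf_x).all(axis=1)
    return e.egm_surf_x[usable], np.asarray(vals, dtype=np.float64)[usable]


def generate_interp_data(userdata: UserData, datatype: str,
                         spec: Optional[InterpolatorSpec] = None,
                         fill_threshold: float = DEFAULT_FILL_THRESHOLD_MM) -> SurfaceField:
    """Interpolate point measurements onto every mesh vertex.

    ``datatype`` selects the point quantity: relative LAT
    (map_annot - ref_annot) for 'lat-map', bipolar point voltage for
    'bip-map', unipolar for 'uni-map'.  Location-only and unannotated
    points are excluded.  The returned field is masked by
    :func:`color_fill_mask` at ``fill_threshold`` mm.
    """
    if userdata.surface is None:
        raise MissingDataError("study has no surface mesh")
    x, y = _point_samples(userdata, datatype)
    if len(x) < 4:
        raise MissingDataError(
            f"insufficient data for {datatype}: {len(x)} usable points (need >= 4)"
        )
    interp = ScatteredInterpolator(x, y, spec)
    values = interp(userdata.surface.vertices)
    valid = color_fill_mask(userdata.surface, x, fill_threshold)
    return SurfaceField(values=values, valid=valid, source="interpolated",
                        quantity=_DATATYPES[datatype][0])
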