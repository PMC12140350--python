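"""Circle-fit curvature and Laplace pressure, automated.

The original measurement drew a circle by hand over the imaged interface
and read off its radius.  Here the circle is fit in two stages: an
algebraic least-squares solution of the linearized circle equation
(Kasa fit) followed by geometric Gauss-Newton refinement of the orthogonal
distances.  Collinear points yield a flagged-infinite radius (zero
curvature), not an exception — a flat interface is a valid measurement.
The RMS orthogonal residual is reported so fits can be audited.

Sign convention: curvature of an interface bulging toward the oil
(convex up, confining the cell) is positive; both radii enter the Laplace
sum as positive magnitudes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from liqchan.geometry_model import ChannelGeometry, arc_from_width_height, laplace_pressure
from liqchan.interface_extraction import HeightMap, InterfaceProfile, extract_profile

__all__ = [
    "CircleFitResult",
    "PressureProfile",
    "fit_circle",
    "curvature_at",
    "pressure_profile_along_cell",
]


@dataclass(frozen=True)
class CircleFitResult:
    """A fitted circle: center (u, v) and radius in um, with fit diagnostics.

    ``radius_R`` is ``math.inf`` (and ``collinear`` True) when the points
    lie on a line within tolerance.  ``arc_span`` is the angular extent of
    the data around the fitted center, in degrees.
    """

    center: tuple[float, float]
    radius_R: float
    rms_residual: float
    n_points: int
    arc_span: float

    @property
    def collinear(self) -> bool:
        return math.isinf(self.radius_R)

    @property
    def curvature(self) -> float:
        return 0.0 if self.collinear else 1.0 / self.radius_R


@dataclass
class PressureProfile:
    """Confining pressure sampled along a cell's long (migration) axis."""

    positions: np.ndarray
    r_xz: np.ndarray
    r_yz: np.ndarray
    pressure: np.ndarray
    front_pressure: float
    rear_pressure: float


def fit_circle(points, collinear_tol: float = 1e-7) -> CircleFitResult:
    """Least-squares circle through 2D points (um).

    Algebraic (Kasa) fit of ``u^2 + v^2 = 2 a u + 2 b v + c`` followed by
    Gauss-Newton refinement of ``|p - center| - R``.  Points collinear
    within ``collinear_tol`` (RMS line residual relative to the point-cloud
    extent) return an infinite radius.

    Raises
    ------
    ValueError
        For fewer than 3 points.
    """
    pts = np.asarray(points, float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise ValueError("need at least 3 (u, v) points")
    u, v = pts[:, 0], pts[:, 1]

    # collinearity: smallest principal-axis spread relative to the largest
    centered = pts - pts.mean(axis=0)
    svals = np.linalg.svd(centered, compute_uv=False)
    span = svals[0] / math.sqrt(len(pts))
    line_rms = svals[-1] / math.sqrt(len(pts))
    if span == 0 or line_rms <= collinear_tol * max(span, 1.0):
        return CircleFitResult(
            center=(math.nan, math.nan),
            radius_R=math.inf,
            rms_residual=float(line_rms),
            n_points=len(pts),
            arc_span=0.0,
        )

    A = np.column_stack([2.0 * u, 2.0 * v, np.ones_like(u)])
    sol, *_ = np.linalg.lstsq(A, u * u + v * v, rcond=None)
    a, b, c = sol
    r0 = math.sqrt(max(c + a * a + b * b, 1e-300))

    def resid(p):
        return np.hypot(u - p[0], v - p[1]) - p[2]

    fit = least_squares(resid, x0=[a, b, r0], method="lm")
    cu, cv, radius = fit.x
    radius = abs(radius)
    res = resid((cu, cv, radius))
    angles = np.unwrap(np.sort(np.arctan2(v - cv, u - cu)))
    return CircleFitResult(
        center=(float(cu), float(cv)),
        radius_R=float(radius),
        rms_residual=float(np.sqrt(np.mean(res**2))),
        n_points=len(pts),
        arc_span=float(np.degrees(angles[-1] - angles[0])),
    )


def curvature_at(
    profile: InterfaceProfile,
    center_position: float,
    window: float,
    collinear_tol: float = 1e-7,
) -> tuple[float, CircleFitResult]:
    """Signed curvature of a profile around ``center_position`` (um).

    Fits a circle to the samples within ``window`` of the center.  The sign
    is positive when the interface is convex toward the oil (fitted circle
    center below the samples), negative when concave.

    Raises
    ------
    ValueError
        When fewer than 5 samples fall inside the window.
    """
    sel = np.abs(profile.positions - center_position) <= window / 2.0
    if sel.sum() < 5:
        raise ValueError("window contains fewer than 5 profile samples")
    pts = np.column_stack([profile.positions[sel], profile.heights[sel]])
    fit = fit_circle(pts, collinear_tol=collinear_tol)
    if fit.collinear:
        return 0.0, fit
    sign = 1.0 if fit.center[1] < float(np.mean(pts[:, 1])) else -1.0
    return sign / fit.radius_R, fit


def pressure_profile_along_cell(
    hmap: HeightMap,
    cell_mask: np.ndarray,
    geom: ChannelGeometry,
    window: float | None = None,
    n_stations: int = 9,
    edge_fraction: float = 0.2,
    centerline_x: float | None = None,
    kappa_min: float = 1e-4,
) -> PressureProfile:
    """Confining pressure at stations along a cell's migration (y) axis.

    At each station the cross-sectional radius ``R_xz`` comes from the
    pinned circular arc with the locally measured apex height, and the
    side-plane radius ``R_yz`` from a circle fit to the centerline yz
    profile within ``window`` (default: the cell's masked length, mirroring
    a per-region hand-drawn circle over the deformation cap).  Pressures
    follow the Laplace relation; curvatures below ``kappa_min`` (1/um)
    count as flat.  The front (rear) summary pressure is evaluated at the
    center of the leading (trailing) ``edge_fraction`` band of the mask
    along +y.
    """
    cell_mask = np.asarray(cell_mask, bool)
    if cell_mask.shape != hmap.heights.shape:
        raise ValueError("cell_mask must match the height-map grid")
    rows = np.where(cell_mask.any(axis=1))[0]
    if len(rows) < 3:
        raise ValueError("degenerate cell mask")
    y_lo, y_hi = hmap.y_um[rows[0]], hmap.y_um[rows[-1]]
    length = y_hi - y_lo
    if window is None:
        window = length
    if centerline_x is None:
        cols = np.where(cell_mask.any(axis=0))[0]
        centerline_x = float(np.mean(hmap.x_um[cols]))

    yz = extract_profile(hmap, "yz", centerline_x)
    stations = np.linspace(y_lo, y_hi, n_stations)
    y_front = y_hi - 0.5 * edge_fraction * length
    y_rear = y_lo + 0.5 * edge_fraction * length

    def station_pressure(y_st: float) -> tuple[float, float, float]:
        h_st = hmap.height_at(centerline_x, y_st)
        if math.isnan(h_st) or h_st <= 0:
            raise ValueError(f"no interface height at station y={y_st:.1f} um")
        r_xz = arc_from_width_height(geom.width_w, h_st).radius_R
        kappa, _ = curvature_at(yz, y_st, window)
        r_yz = math.inf if abs(kappa) < kappa_min else 1.0 / abs(kappa)
        return r_xz, r_yz, laplace_pressure(r_xz, r_yz, geom.gamma_om)

    r_xz_arr = np.empty(n_stations)
    r_yz_arr = np.empty(n_stations)
    p_arr = np.empty(n_stations)
    for s, y_st in enumerate(stations):
        r_xz_arr[s], r_yz_arr[s], p_arr[s] = station_pressure(y_st)
    _, _, p_front = station_pressure(y_front)
    _, _, p_rear = station_pressure(y_rear)

    return PressureProfile(
        positions=stations,
        r_xz=r_xz_arr,
        r_yz=r_yz_arr,
        pressure=p_arr,
        front_pressure=p_front,
        rear_pressure=p_rear,
    )
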