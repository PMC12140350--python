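"""Seeded synthetic microscopy scenes with exact ground truth.

The generators emulate the imaging conditions of the liquid-channel
migration experiments:

* :func:`render_channel_stack` — a confocal z-stack of a media-filled
  channel (bright dye-labeled media below the oil-media interface, dark oil
  above) whose cross-section is a circular arc pinned at the channel edges;
  cells appear as smooth bumps in the apex-height profile along the channel
  axis.  Default axial step 0.2 um.
* :func:`render_timelapse` — a 2D migration movie at 30 s intervals in
  which the foremost ("pioneer") cell migrates at a reduced speed because
  it must deform the interface, while trailing cells follow at full speed;
  a faster trailing cell can catch up and take over the pioneer role.
* :func:`render_protrusion_movie` — a fast (<= 1 s interval) movie of a
  single cell emitting bleb-like protrusions (rapid, rounded, short-lived)
  and pseudopods (slow, sheet-like).
* :func:`render_tissue_scene` — a two-channel movie of a cell migrating
  through a polygonal tessellation of surrounding cells whose boundaries
  it displaces outward, with exponential elastic recovery.

Every generator is a pure function of its configuration (including the
seed): identical inputs give byte-identical outputs.  Ground-truth
quantities are computed from the generation parameters in closed form,
never re-measured from pixels.

:func:`mixture_concentration` carries the protocol bookkeeping for the
collagen/media/HEPES mixtures (exact rational arithmetic).
"""

from __future__ import annotations

import json
import math
import numbers
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from liqchan.geometry_model import ChannelGeometry, arc_from_width_height

__all__ = [
    "SceneConfig",
    "SyntheticCell",
    "ProtrusionSpec",
    "GroundTruth",
    "render_channel_stack",
    "render_timelapse",
    "render_protrusion_movie",
    "render_tissue_scene",
    "mixture_concentration",
    "arc_height_profile",
]


@dataclass(frozen=True)
class SceneConfig:
    """Imaging and channel parameters shared by all generators.

    Parameters
    ----------
    geometry : ChannelGeometry
        Pinned channel width, tension, length.
    baseline_h : float
        Undeformed interface apex height (um).
    voxel_xy : float
        Lateral voxel / pixel size (um).
    voxel_z : float
        Axial step (um); 0.2 um matches confocal z-stacks at 200 nm steps.
    psf_sigma : float
        Gaussian blur scale (um), an idealized point-spread function.
    noise_sd : float
        Additive Gaussian noise, as a fraction of the media-oil contrast.
    seed : int
        RNG seed; fixed seed implies byte-identical output.
    fov_y : float or None
        Rendered extent along the channel axis (um); defaults to the
        channel length.
    margin_x : float
        Rendered margin beyond each pinned edge (um).
    media_level, oil_level : float
        Two-level intensity model (media bright, oil dark).
    """

    geometry: ChannelGeometry
    baseline_h: float = 2.0
    voxel_xy: float = 0.5
    voxel_z: float = 0.2
    psf_sigma: float = 0.3
    noise_sd: float = 0.05
    seed: int = 0
    fov_y: float | None = None
    margin_x: float = 2.5
    media_level: float = 1000.0
    oil_level: float = 100.0

    def __post_init__(self) -> None:
        if self.voxel_xy <= 0 or self.voxel_z <= 0:
            raise ValueError("voxel sizes must be positive")
        if self.baseline_h <= 0:
            raise ValueError("baseline_h must be positive")
        if self.noise_sd < 0 or self.psf_sigma < 0:
            raise ValueError("noise_sd and psf_sigma must be non-negative")
        if self.media_level <= self.oil_level:
            raise ValueError("media_level must exceed oil_level")

    @property
    def extent_y(self) -> float:
        return self.geometry.length if self.fov_y is None else self.fov_y

    @property
    def extent_x(self) -> float:
        return self.geometry.width_w + 2.0 * self.margin_x


@dataclass(frozen=True)
class SyntheticCell:
    """A migrating cell and the interface deformation it causes.

    ``position`` is the (x, y) centroid in channel coordinates: x = 0 on
    the channel centerline, y measured along the migration axis from the
    rendered field's near edge.  ``body_height`` is the absolute interface
    apex height over the cell (h_cell >= h_0); ``footprint`` the (x, y)
    ellipse semi-axes; ``nucleus_offset`` shifts the deformation maximum
    rear-ward (positive = toward -y) to emulate rear-ward nuclear
    positioning; ``speed`` the unconstrained migration speed in um/min.
    """

    position: tuple[float, float]
    body_height: float = 5.0
    footprint: tuple[float, float] = (3.0, 4.0)
    nucleus_offset: float = 0.0
    speed: float = 20.0


@dataclass(frozen=True)
class ProtrusionSpec:
    """One planted protrusion event for :func:`render_protrusion_movie`.

    kind: ``"bleb"`` or ``"pseudopod"``.  ``onset_s``/``duration_s`` in
    seconds, ``max_extent`` the peak radial extension beyond the cell
    boundary (um), ``angle_deg`` the boundary position (auto-spaced when
    None), ``rise_s`` the time to reach max extent (defaults: blebs fast,
    pseudopods slow).
    """

    kind: str
    onset_s: float
    duration_s: float
    max_extent: float = 3.0
    angle_deg: float | None = None
    rise_s: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("bleb", "pseudopod"):
            raise ValueError(f"unknown protrusion kind {self.kind!r}")
        if self.max_extent <= 0 or self.duration_s <= 0:
            raise ValueError("max_extent and duration_s must be positive")


@dataclass
class GroundTruth:
    """Exact generation record sufficient to score every downstream stage."""

    params: dict = field(default_factory=dict)
    height_map: np.ndarray | None = None
    tracks: pd.DataFrame | None = None
    events: list[dict] | None = None
    displacement: np.ndarray | None = None

    def to_dict(self) -> dict:
        out: dict = {"params": _jsonable(self.params)}
        if self.height_map is not None:
            out["height_map"] = self.height_map.tolist()
        if self.tracks is not None:
            out["tracks"] = self.tracks.to_dict(orient="records")
        if self.events is not None:
            out["events"] = _jsonable(self.events)
        if self.displacement is not None:
            out["displacement"] = self.displacement.tolist()
        return out

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, (ChannelGeometry, SceneConfig)):
        return _jsonable(vars(obj))
    return obj


# ---------------------------------------------------------------------------
# channel z-stack


def arc_height_profile(x: np.ndarray, width_w: float, apex: float) -> np.ndarray:
    """Interface height z(x) of the pinned circular arc, 0 outside the strip."""
    arc = arc_from_width_height(width_w, apex)
    r = arc.radius_R
    inside = np.abs(x) <= width_w / 2.0
    z = np.sqrt(np.maximum(r * r - x * x, 0.0)) - (r - apex)
    return np.where(inside, np.maximum(z, 0.0), 0.0)


def _apex_profile(config: SceneConfig, cells: Sequence[SyntheticCell], y: np.ndarray) -> np.ndarray:
    """Apex height along y: baseline plus one Gaussian bump per cell."""
    apex = np.full_like(y, config.baseline_h, dtype=float)
    for cell in cells:
        amp = cell.body_height - config.baseline_h
        if amp < 0:
            raise ValueError("cell body_height below baseline interface height")
        y_c = cell.position[1] - cell.nucleus_offset
        sigma = cell.footprint[1]
        apex += amp * np.exp(-((y - y_c) ** 2) / (2.0 * sigma**2))
    return apex


def _check_cells_in_strip(config: SceneConfig, cells: Sequence[SyntheticCell]) -> None:
    half_w = config.geometry.width_w / 2.0
    for cell in cells:
        x_c, y_c = cell.position
        if abs(x_c) + cell.footprint[0] > half_w:
            raise ValueError(f"cell at x={x_c} extends outside the pinned strip")
        if not (0.0 <= y_c <= config.extent_y):
            raise ValueError(f"cell at y={y_c} outside the rendered field")


def render_channel_stack(
    config: SceneConfig, cells: Sequence[SyntheticCell] = ()
) -> tuple[np.ndarray, GroundTruth]:
    """Render a confocal z-stack (z, y, x) of the labeled-media channel.

    Voxel intensity is the media level where the voxel center lies below the
    interface height h(x, y) and the oil level above it, followed by
    Gaussian blur (``psf_sigma``) and additive Gaussian noise.  h(x, y) is
    the pinned circular arc at each y whose apex is the baseline height plus
    a smooth Gaussian bump per cell.  The ground truth records the exact
    h(x, y) on the voxel-center grid.
    """
    _check_cells_in_strip(config, cells)
    geom = config.geometry
    nx = int(round(config.extent_x / config.voxel_xy))
    ny = int(round(config.extent_y / config.voxel_xy))
    x = (np.arange(nx) + 0.5) * config.voxel_xy - config.extent_x / 2.0
    y = (np.arange(ny) + 0.5) * config.voxel_xy

    apex = _apex_profile(config, cells, y)
    z_top = float(apex.max()) + max(1.5, 3.0 * config.psf_sigma + 0.5)
    nz = int(math.ceil(z_top / config.voxel_z))
    z = (np.arange(nz) + 0.5) * config.voxel_z

    height = np.empty((ny, nx))
    for j in range(ny):
        height[j] = arc_height_profile(x, geom.width_w, apex[j])

    volume = np.where(
        z[:, None, None] < height[None, :, :], config.media_level, config.oil_level
    ).astype(np.float32)

    if config.psf_sigma > 0:
        sig = (
            config.psf_sigma / config.voxel_z,
            config.psf_sigma / config.voxel_xy,
            config.psf_sigma / config.voxel_xy,
        )
        volume = gaussian_filter(volume, sigma=sig)
    if config.noise_sd > 0:
        rng = np.random.default_rng(config.seed)
        contrast = config.media_level - config.oil_level
        volume = volume + rng.normal(
            0.0, config.noise_sd * contrast, size=volume.shape
        ).astype(np.float32)

    truth = GroundTruth(
        params={
            "kind": "channel_stack",
            "config": config,
            "cells": [vars(c) for c in cells],
            "x_um": x,
            "y_um": y,
            "apex_profile": apex,
        },
        height_map=height,
    )
    return volume, truth


# ---------------------------------------------------------------------------
# migration timelapse


def _paint_ellipse(frame, xc, yc, ax_x, ax_y, px, level):
    """Set pixels of an axis-aligned ellipse (um coords, frame-left origin)."""
    ny, nx = frame.shape
    j0 = max(int((yc - ax_y) / px) - 1, 0)
    j1 = min(int((yc + ax_y) / px) + 2, ny)
    i0 = max(int((xc - ax_x) / px) - 1, 0)
    i1 = min(int((xc + ax_x) / px) + 2, nx)
    if j0 >= j1 or i0 >= i1:
        return
    jj, ii = np.mgrid[j0:j1, i0:i1]
    xs = (ii + 0.5) * px
    ys = (jj + 0.5) * px
    inside = ((xs - xc) / ax_x) ** 2 + ((ys - yc) / ax_y) ** 2 <= 1.0
    frame[j0:j1, i0:i1][inside] = level


def render_timelapse(
    config: SceneConfig,
    cast: Sequence[SyntheticCell],
    frame_interval_s: float = 30.0,
    n_frames: int = 20,
    slowdown_factor: float = 0.35,
    contact_distance: float | None = None,
) -> tuple[np.ndarray, GroundTruth]:
    """Render a 2D migration movie (t, y, x) with pioneer/trailing dynamics.

    Cells migrate along +y.  The cell whose front has reached the
    undeformed interface (the furthest any cell front has advanced) holds
    the pioneer role and moves at ``speed * slowdown_factor``; trailing
    cells migrate at full speed through the pre-deformed conduit, queuing
    without overlap.  When a trailing cell closes on the pioneer to within
    ``contact_distance`` (default: the sum of the two cells' y semi-axes,
    i.e. touching), the pioneer yields — it sidesteps laterally and
    arrests — and the trailing cell advances at full speed until its own
    front reaches the interface, whereupon it assumes the pioneer role and
    its slowdown.  Ground truth records per-frame positions, roles, imposed
    speeds, and the transition frame (first frame with the new pioneer in
    role).
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    if not cast:
        raise ValueError("cast must contain at least one cell")
    _check_cells_in_strip(config, cast)

    dt_min = frame_interval_s / 60.0
    px = config.voxel_xy
    nx = int(round(config.extent_x / px))
    ny = int(round(config.extent_y / px))
    x_off = config.extent_x / 2.0  # channel-center x -> frame-left x

    n = len(cast)
    xs = np.array([c.position[0] for c in cast], float)
    ys = np.array([c.position[1] for c in cast], float)
    speeds = np.array([c.speed for c in cast], float)
    ax_x = np.array([c.footprint[0] for c in cast], float)
    ax_y = np.array([c.footprint[1] for c in cast], float)

    stalled = np.zeros(n, bool)
    front_y = float(np.max(ys + ax_y))  # furthest interface deformation so far
    eps = 1e-9

    def current_pioneer() -> int | None:
        best = None
        for i in range(n):
            if stalled[i]:
                continue
            if ys[i] + ax_y[i] >= front_y - eps:
                if best is None or ys[i] > ys[best]:
                    best = i
        return best

    pioneer = current_pioneer()
    pioneer_history: list[int | None] = []
    transition_frame: int | None = None
    transition_cell: int | None = None

    movie = np.empty((n_frames, ny, nx), np.float32)
    rng = np.random.default_rng(config.seed)
    records = []

    for t in range(n_frames):
        pioneer_history.append(pioneer)
        if (
            transition_frame is None
            and t > 0
            and pioneer is not None
            and pioneer_history[0] is not None
            and pioneer != pioneer_history[0]
        ):
            transition_frame = t
            transition_cell = pioneer

        for i in range(n):
            role = "stalled" if stalled[i] else ("pioneer" if i == pioneer else "trailing")
            imposed = (
                0.0
                if stalled[i]
                else speeds[i] * (slowdown_factor if i == pioneer else 1.0)
            )
            records.append(
                {
                    "frame": t,
                    "t_s": t * frame_interval_s,
                    "cell_id": i,
                    "x_um": xs[i] + x_off,
                    "y_um": ys[i],
                    "area_um2": math.pi * ax_x[i] * ax_y[i],
                    "role": role,
                    "speed_um_min": imposed,
                }
            )

        frame = np.full((ny, nx), config.oil_level, np.float32)
        for i in range(n):
            _paint_ellipse(
                frame, xs[i] + x_off, ys[i], ax_x[i], ax_y[i], px, config.media_level
            )
        if config.psf_sigma > 0:
            frame = gaussian_filter(frame, config.psf_sigma / px)
        if config.noise_sd > 0:
            frame = frame + rng.normal(
                0.0,
                config.noise_sd * (config.media_level - config.oil_level),
                size=frame.shape,
            ).astype(np.float32)
        movie[t] = frame

        if t == n_frames - 1:
            break

        # advance front-to-back: pioneer slowed, others full speed, queued
        ys_new = ys.copy()
        order = [i for i in np.argsort(-ys) if not stalled[i]]
        for i in order:
            v = speeds[i] * (slowdown_factor if i == pioneer else 1.0)
            target = ys[i] + v * dt_min
            for j in order:
                if j != i and ys[j] > ys[i]:
                    target = min(target, ys_new[j] - (ax_y[i] + ax_y[j]))
            ys_new[i] = max(target, ys[i])
        ys = ys_new
        front_y = max(front_y, float(np.max((ys + ax_y)[~stalled])) if (~stalled).any() else front_y)

        # pioneer yields when a faster trailing cell makes contact
        if pioneer is not None:
            for i in range(n):
                if i == pioneer or stalled[i]:
                    continue
                thresh = (
                    ax_y[i] + ax_y[pioneer]
                    if contact_distance is None
                    else contact_distance
                )
                if (
                    ys[pioneer] - ys[i] <= thresh + 1e-6
                    and speeds[i] > slowdown_factor * speeds[pioneer]
                ):
                    stalled[pioneer] = True
                    side = config.geometry.width_w / 2.0 - ax_x[pioneer] - 0.5
                    xs[pioneer] = side if xs[pioneer] <= 0 else -side
                    break
        pioneer = current_pioneer()

    tracks = pd.DataFrame.from_records(records)
    truth = GroundTruth(
        params={
            "kind": "timelapse",
            "config": config,
            "frame_interval_s": frame_interval_s,
            "slowdown_factor": slowdown_factor,
            "x_offset_um": x_off,
            "transition_frame": transition_frame,
            "transition_cell": transition_cell,
            "cast": [vars(c) for c in cast],
        },
        tracks=tracks,
    )
    return movie, truth


# ---------------------------------------------------------------------------
# protrusion movies


def _extent_profile(spec: ProtrusionSpec, frame_interval_s: float) -> Callable[[float], float]:
    """Extension-vs-time profile e(t) for one event (t relative to onset)."""
    if spec.kind == "bleb":
        rise = spec.rise_s if spec.rise_s is not None else min(2.0 * frame_interval_s, 2.0)
        fall = min(2.0, spec.duration_s - rise)
    else:
        rise = spec.rise_s if spec.rise_s is not None else 0.6 * spec.duration_s
        fall = spec.duration_s - rise
    rise = min(max(rise, frame_interval_s), spec.duration_s)
    plateau_end = spec.duration_s - max(fall, 1e-9)

    def e(t: float) -> float:
        if t < 0 or t > spec.duration_s:
            return 0.0
        if t <= rise:
            return spec.max_extent * t / rise
        if t <= plateau_end:
            return spec.max_extent
        return spec.max_extent * (spec.duration_s - t) / max(fall, 1e-9)

    return e


def render_protrusion_movie(
    config: SceneConfig,
    events: Sequence[ProtrusionSpec],
    frame_interval_s: float = 1.0,
    n_frames: int | None = None,
    body_axes: tuple[float, float] = (4.0, 6.0),
) -> tuple[np.ndarray, GroundTruth]:
    """Render a fast single-cell movie (t, y, x) with planted protrusions.

    Blebs grow as near-circular lobes reaching their maximal extension
    within at most two frames and retract within their (short) lifespan;
    pseudopods grow as wide, low-circularity sheets over tens of seconds.
    Ground truth stores each event's class, onset, lifespan, maximal radial
    extension, time-to-max, and expansion speed (max extent / time-to-max).
    """
    if any(e.kind == "bleb" for e in events) and frame_interval_s > 1.0:
        raise ValueError("bleb-resolving movies require frame_interval_s <= 1 s")
    for e in events:
        if e.duration_s < 2.0 * frame_interval_s:
            raise ValueError("event duration shorter than two frame intervals")

    max_ext = max((e.max_extent for e in events), default=0.0)
    half = max(body_axes) + max_ext + 2.0
    px = config.voxel_xy
    npix = int(round(2.0 * half / px))
    cx = cy = half
    if n_frames is None:
        last = max((e.onset_s + e.duration_s for e in events), default=0.0)
        n_frames = int(math.ceil(last / frame_interval_s)) + 3

    # auto-space angles so events do not overlap spatially
    angles = []
    auto = 0
    for e in events:
        if e.angle_deg is not None:
            angles.append(e.angle_deg)
        else:
            angles.append((auto * 137.5) % 360.0)
            auto += 1

    profiles = [_extent_profile(e, frame_interval_s) for e in events]
    movie = np.empty((n_frames, npix, npix), np.float32)
    rng = np.random.default_rng(config.seed)

    for t in range(n_frames):
        frame = np.full((npix, npix), config.oil_level, np.float32)
        _paint_ellipse(frame, cx, cy, body_axes[0], body_axes[1], px, config.media_level)
        for spec, ang, prof in zip(events, angles, profiles):
            ext = prof(t * frame_interval_s - spec.onset_s)
            if ext <= 0:
                continue
            th = math.radians(ang)
            ux, uy = math.cos(th), math.sin(th)
            # boundary point of the body ellipse along direction (ux, uy)
            rb = 1.0 / math.sqrt((ux / body_axes[0]) ** 2 + (uy / body_axes[1]) ** 2)
            bx, by = cx + rb * ux, cy + rb * uy
            lx, ly = bx + 0.5 * ext * ux, by + 0.5 * ext * uy
            if spec.kind == "bleb":
                _paint_disc(frame, lx, ly, 0.5 * ext, px, config.media_level)
            else:
                _paint_rot_ellipse(
                    frame, lx, ly, 0.5 * ext, 1.8 * spec.max_extent, th, px,
                    config.media_level,
                )
        if config.psf_sigma > 0:
            frame = gaussian_filter(frame, config.psf_sigma / px)
        if config.noise_sd > 0:
            frame = frame + rng.normal(
                0.0,
                config.noise_sd * (config.media_level - config.oil_level),
                size=frame.shape,
            ).astype(np.float32)
        movie[t] = frame

    truth_events = []
    for spec, ang in zip(events, angles):
        if spec.kind == "bleb":
            rise = spec.rise_s if spec.rise_s is not None else min(2.0 * frame_interval_s, 2.0)
        else:
            rise = spec.rise_s if spec.rise_s is not None else 0.6 * spec.duration_s
        rise = min(max(rise, frame_interval_s), spec.duration_s)
        truth_events.append(
            {
                "class": spec.kind,
                "onset_s": spec.onset_s,
                "lifespan_s": spec.duration_s,
                "max_extent_um": spec.max_extent,
                "time_to_max_s": rise,
                "expansion_speed_um_s": spec.max_extent / rise,
                "angle_deg": ang,
            }
        )
    truth = GroundTruth(
        params={
            "kind": "protrusion_movie",
            "config": config,
            "frame_interval_s": frame_interval_s,
            "body_axes": list(body_axes),
            "center_um": [cx, cy],
        },
        events=truth_events,
    )
    return movie, truth


def _paint_disc(frame, xc, yc, r, px, level):
    _paint_ellipse(frame, xc, yc, r, r, px, level)


def _paint_rot_ellipse(frame, xc, yc, a_rad, a_tan, theta, px, level):
    """Ellipse with semi-axis ``a_rad`` along direction theta, ``a_tan`` across."""
    ny, nx = frame.shape
    rmax = max(a_rad, a_tan)
    j0 = max(int((yc - rmax) / px) - 1, 0)
    j1 = min(int((yc + rmax) / px) + 2, ny)
    i0 = max(int((xc - rmax) / px) - 1, 0)
    i1 = min(int((xc + rmax) / px) + 2, nx)
    if j0 >= j1 or i0 >= i1:
        return
    jj, ii = np.mgrid[j0:j1, i0:i1]
    dx = (ii + 0.5) * px - xc
    dy = (jj + 0.5) * px - yc
    u = dx * math.cos(theta) + dy * math.sin(theta)
    v = -dx * math.sin(theta) + dy * math.cos(theta)
    inside = (u / a_rad) ** 2 + (v / a_tan) ** 2 <= 1.0
    frame[j0:j1, i0:i1][inside] = level


# ---------------------------------------------------------------------------
# tissue scene


def render_tissue_scene(
    config: SceneConfig,
    migrating_cell_path: np.ndarray,
    cell_packing: float = 15.0,
    cell_radius: float = 4.0,
    recovery_tau_s: float = 30.0,
    frame_interval_s: float = 10.0,
    field_um: tuple[float, float] = (60.0, 60.0),
    boundary_sample_um: float = 0.5,
) -> tuple[np.ndarray, GroundTruth]:
    """Render a 2-channel movie of a cell deforming a cell-boundary lattice.

    Channel 0 shows the boundaries of a square tessellation of surrounding
    cells (spacing ``cell_packing``); channel 1 the migrating cell, a disc
    of radius ``cell_radius`` following ``migrating_cell_path`` (n_frames x 2,
    um).  Boundary points within the cell footprint are pushed radially
    outward to its edge, so the maximal displacement equals ``cell_radius``
    when the path crosses a boundary; after passage displacements relax
    exponentially with time constant ``recovery_tau_s``.  Ground truth
    stores the per-frame displacement magnitude of every boundary point.
    """
    path = np.asarray(migrating_cell_path, float)
    if path.ndim != 2 or path.shape[1] != 2:
        raise ValueError("migrating_cell_path must be (n_frames, 2)")
    fx, fy = field_um
    if np.any(path < 0) or np.any(path[:, 0] > fx) or np.any(path[:, 1] > fy):
        raise ValueError("path leaves the rendered field")

    # boundary points of a square tessellation (interior grid lines)
    pts = []
    for gx in np.arange(cell_packing, fx - 1e-9, cell_packing):
        for yy in np.arange(0.0, fy, boundary_sample_um):
            pts.append((gx, yy))
    for gy in np.arange(cell_packing, fy - 1e-9, cell_packing):
        for xx in np.arange(0.0, fx, boundary_sample_um):
            pts.append((xx, gy))
    ref = np.array(pts)
    n_pts = len(ref)
    n_frames = len(path)

    px = config.voxel_xy
    ny, nx = int(round(fy / px)), int(round(fx / px))
    movie = np.empty((n_frames, 2, ny, nx), np.float32)
    disp_vec = np.zeros((n_pts, 2))
    disp_mag_t = np.zeros((n_frames, n_pts))
    decay = math.exp(-frame_interval_s / recovery_tau_s)
    rng = np.random.default_rng(config.seed)

    for t in range(n_frames):
        c = path[t]
        d = ref - c
        r = np.hypot(d[:, 0], d[:, 1])
        degenerate = r < 1e-9
        d[degenerate] = (1.0, 0.0)  # point exactly under the center: push +x
        r_safe = np.where(degenerate, 1.0, r)
        target_mag = np.maximum(cell_radius - r, 0.0)
        target_vec = (d / r_safe[:, None]) * target_mag[:, None]

        prev = disp_vec * decay
        prev_mag = np.hypot(prev[:, 0], prev[:, 1])
        take_target = target_mag > prev_mag
        disp_vec = np.where(take_target[:, None], target_vec, prev)
        disp_mag_t[t] = np.hypot(disp_vec[:, 0], disp_vec[:, 1])

        moved = ref + disp_vec
        ch0 = np.full((ny, nx), config.oil_level, np.float32)
        ii = np.clip((moved[:, 0] / px).astype(int), 0, nx - 1)
        jj = np.clip((moved[:, 1] / px).astype(int), 0, ny - 1)
        ch0[jj, ii] = config.media_level
        ch1 = np.full((ny, nx), config.oil_level, np.float32)
        _paint_disc(ch1, c[0], c[1], cell_radius, px, config.media_level)
        if config.psf_sigma > 0:
            ch0 = gaussian_filter(ch0, config.psf_sigma / px)
            ch1 = gaussian_filter(ch1, config.psf_sigma / px)
        if config.noise_sd > 0:
            contrast = config.media_level - config.oil_level
            ch0 = ch0 + rng.normal(0, config.noise_sd * contrast, ch0.shape).astype(np.float32)
            ch1 = ch1 + rng.normal(0, config.noise_sd * contrast, ch1.shape).astype(np.float32)
        movie[t, 0] = ch0
        movie[t, 1] = ch1

    truth = GroundTruth(
        params={
            "kind": "tissue_scene",
            "config": config,
            "cell_radius_um": cell_radius,
            "cell_packing_um": cell_packing,
            "recovery_tau_s": recovery_tau_s,
            "frame_interval_s": frame_interval_s,
            "reference_boundary": ref,
            "path": path,
            "max_displacement_um": float(disp_mag_t.max()),
        },
        displacement=disp_mag_t,
    )
    return movie, truth


# ---------------------------------------------------------------------------
# protocol bookkeeping


def mixture_concentration(stock_concentration, parts: Sequence, ndigits: int | None = None):
    """Final concentration of the stock after mixing ``parts`` volume parts.

    The stock contributes ``parts[0]`` of ``sum(parts)`` total parts, e.g. a
    10 mg/mL collagen stock mixed 1:1:1 with media and 2X HEPES gives
    10/3 = 3.33 mg/mL.  Exact rational arithmetic; ``ndigits`` rounds the
    result for reporting (``ndigits=0`` rounds to an integer count).
    """
    if len(parts) == 0:
        raise ValueError("parts must be non-empty")
    fparts = []
    for p in parts:
        if not isinstance(p, numbers.Real) or p <= 0:
            raise ValueError("all parts must be positive numbers")
        fparts.append(Fraction(p).limit_denominator(10**9))
    stock = Fraction(stock_concentration).limit_denominator(10**9)
    final = stock * fparts[0] / sum(fparts)
    if ndigits is None:
        return float(final)
    value = round(float(final), ndigits)
    return int(value) if ndigits == 0 else value
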