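"""Interface height maps and profiles from labeled-media volumes.

The aqueous phase carries a fluorescent dye, so in a z-stack each (x, y)
column is bright from the substrate up to the oil-media interface and dark
above it.  The interface height is localized per column on the falling
(media -> oil) intensity edge at half maximum, with sub-voxel linear
interpolation, after a one-voxel median smoothing along z.  Columns whose
peak intensity does not rise a factor ``k`` above the local oil background
are masked out (outside the pinned strip, or no media signal).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter

__all__ = ["HeightMap", "InterfaceProfile", "height_map", "extract_profile", "pre_post_passage"]


@dataclass
class HeightMap:
    """Interface apex heights h(x, y) on the lateral voxel grid.

    ``heights`` is (ny, nx) in um; ``mask`` is True where the column held a
    valid media signal; ``spacing`` the lateral voxel size (um).  ``x_um``
    are measured from the left field edge, ``y_um`` along the channel axis.
    """

    heights: np.ndarray
    mask: np.ndarray
    spacing: float
    x_um: np.ndarray
    y_um: np.ndarray

    def height_at(self, x: float, y: float) -> float:
        """Height at the grid node nearest to (x, y) in um; NaN if masked."""
        i = int(np.argmin(np.abs(self.x_um - x)))
        j = int(np.argmin(np.abs(self.y_um - y)))
        if not self.mask[j, i]:
            return math.nan
        return float(self.heights[j, i])


@dataclass
class InterfaceProfile:
    """A 1D interface cross-section: ``xz`` at fixed y, or ``yz`` at fixed x."""

    plane: str
    positions: np.ndarray
    heights: np.ndarray

    def __post_init__(self) -> None:
        if self.plane not in ("xz", "yz"):
            raise ValueError("plane must be 'xz' or 'yz'")
        if len(self.positions) < 3:
            raise ValueError("profile needs at least 3 samples")
        if not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")


def height_map(
    volume: np.ndarray,
    voxel_z: float,
    voxel_xy: float,
    k_background: float = 3.0,
    oil_fraction: float = 0.2,
    min_media_voxels: int = 5,
) -> HeightMap:
    """Extract the interface height per (x, y) column of a (z, y, x) stack.

    The oil background per column is the median over the top
    ``oil_fraction`` of z-slices.  The media phase always extends up from
    the substrate, so columns are masked unless their bottom
    ``min_media_voxels`` voxels all exceed the media threshold
    (``k_background`` times the background, with an additive floor of five
    robust noise scales); isolated noise peaks and sub-voxel contact-line
    films at the strip edge cannot pass.  For valid columns the height is
    the z of the half-maximum crossing of the falling edge above the
    intensity peak, interpolated between voxel centers.
    """
    vol = np.asarray(volume, float)
    if vol.ndim != 3:
        raise ValueError("volume must be 3D (z, y, x)")
    nz, ny, nx = vol.shape
    if nz < 4:
        raise ValueError("volume too shallow along z to localize an interface")
    if float(vol.max() - vol.min()) == 0.0 and float(vol.max()) > 0.0:
        raise ValueError("volume is saturated/constant; no interface to localize")

    # 3x3x3 median: denoises without edge blurring; lateral bias is
    # negligible because the interface is smooth on the voxel scale
    vol = median_filter(vol, size=(3, 3, 3))
    n_oil = max(int(round(oil_fraction * nz)), 1)
    top = vol[-n_oil:]
    background = np.median(top, axis=0)
    # the per-column median rests on few samples; floor it with the global
    # oil level so a noise dip cannot collapse the threshold
    background = np.maximum(background, float(np.median(top)))
    # global robust noise scale of the oil region (MAD -> sigma)
    sigma = 1.4826 * float(np.median(np.abs(top - np.median(top, axis=0)[None])))
    peak = vol.max(axis=0)
    # the bottom slab must sit at media level (half-max), not merely above
    # the oil background, so blur-smeared sub-voxel films do not qualify
    media_thresh = np.maximum.reduce(
        [
            k_background * background,
            background + 5.0 * sigma,
            0.5 * (peak + background),
        ]
    )
    bottom_bright = (vol[:min_media_voxels] >= media_thresh[None, :, :]).all(axis=0)
    # a resolvable media layer must reach near the global media brightness;
    # a thin film's blur foot peaks well below it
    global_bg = float(np.median(top))
    global_media = float(np.percentile(vol, 99.0))
    reaches_media = peak >= global_bg + 0.6 * (global_media - global_bg)
    valid = bottom_bright & reaches_media & (peak - background > 0)
    if not valid.any():
        warnings.warn("no column exceeds the background threshold; map fully masked")

    heights = np.full((ny, nx), np.nan)
    z_centers = (np.arange(nz) + 0.5) * voxel_z
    # half-max level between the media brightness (median of the known-media
    # bottom slab) and the oil background; locate the falling edge from the
    # top, where oil noise cannot reach the level
    media_level = np.median(vol[:min_media_voxels], axis=0)
    level = 0.5 * (media_level + background)
    for j in range(ny):
        for i in range(nx):
            if not valid[j, i]:
                continue
            col = vol[:, j, i]
            lv = level[j, i]
            above = np.nonzero(col >= lv)[0]
            if len(above) == 0 or above[-1] >= nz - 1:
                valid[j, i] = False
                continue
            kk = above[-1]
            frac = (col[kk] - lv) / (col[kk] - col[kk + 1])
            heights[j, i] = max(z_centers[kk] + frac * voxel_z, 0.0)

    # lateral consistency: the interface is smooth on the voxel scale, so a
    # column disagreeing grossly with its 3x3 neighborhood is a noise artifact
    med = _nanmedian3x3(np.where(valid, heights, np.nan))
    outlier = valid & np.isfinite(med) & (np.abs(heights - med) > 3.0 * voxel_z)
    valid &= ~outlier

    x = (np.arange(nx) + 0.5) * voxel_xy
    y = (np.arange(ny) + 0.5) * voxel_xy
    return HeightMap(heights=heights, mask=valid, spacing=voxel_xy, x_um=x, y_um=y)


def _nanmedian3x3(a: np.ndarray) -> np.ndarray:
    """Median over each 3x3 neighborhood, ignoring NaNs (edge-padded)."""
    padded = np.pad(a, 1, constant_values=np.nan)
    stack = [
        padded[1 + dj : 1 + dj + a.shape[0], 1 + di : 1 + di + a.shape[1]]
        for dj in (-1, 0, 1)
        for di in (-1, 0, 1)
        if not (dj == 0 and di == 0)
    ]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmedian(np.stack(stack), axis=0)


def extract_profile(hmap: HeightMap, plane: str, position: float) -> InterfaceProfile:
    """Slice the height map into a 1D profile.

    ``plane='xz'`` takes the row nearest ``position`` (a y coordinate, um)
    and returns h(x); ``plane='yz'`` takes the column nearest ``position``
    (an x coordinate) and returns h(y).  Masked columns are dropped.
    """
    if plane == "xz":
        j = int(np.argmin(np.abs(hmap.y_um - position)))
        sel = hmap.mask[j]
        pos, hts = hmap.x_um[sel], hmap.heights[j, sel]
    elif plane == "yz":
        i = int(np.argmin(np.abs(hmap.x_um - position)))
        sel = hmap.mask[:, i]
        pos, hts = hmap.y_um[sel], hmap.heights[sel, i]
    else:
        raise ValueError("plane must be 'xz' or 'yz'")
    if sel.sum() < 3:
        raise ValueError(f"requested {plane} slice at {position} um is (nearly) fully masked")
    return InterfaceProfile(plane=plane, positions=pos, heights=hts)


def pre_post_passage(
    height_maps: list[HeightMap],
    tracks: pd.DataFrame,
    cell_half_length: float,
    probe_positions: np.ndarray | None = None,
    centerline_x: float | None = None,
) -> pd.DataFrame:
    """Paired interface heights before and after pioneer-cell passage.

    ``height_maps`` is one map per frame; ``tracks`` a tidy table with
    columns ``frame``, ``y_um``, and ``role`` (only pioneer rows are used).
    For each probe y-position the height is read at the last frame before
    the pioneer front (centroid + ``cell_half_length``) reaches the probe
    and at the first frame after the cell rear clears it.  Probes default
    to three evenly spaced stations in the middle third of the mapped
    extent.  Returns columns ``probe_um, before_um, after_um, frame_before,
    frame_after``; empty (with a warning) when no passage is bracketed.
    """
    if len(height_maps) < 2:
        raise ValueError("need height maps for at least two time points")
    pio = tracks[tracks["role"] == "pioneer"].sort_values("frame")
    hm0 = height_maps[0]
    if probe_positions is None:
        y_lo, y_hi = hm0.y_um[0], hm0.y_um[-1]
        third = (y_hi - y_lo) / 3.0
        probe_positions = np.linspace(y_lo + third, y_hi - third, 3)
    if centerline_x is None:
        centerline_x = float(np.median(hm0.x_um))

    rows = []
    frames = sorted(tracks["frame"].unique())
    for probe in np.atleast_1d(probe_positions):
        before_f = after_f = None
        for f in frames:
            row = pio[pio["frame"] == f]
            if row.empty:
                continue
            y = float(row["y_um"].iloc[0])
            if y + cell_half_length < probe:
                before_f = f
            if y - cell_half_length > probe and after_f is None:
                after_f = f
        if before_f is None or after_f is None:
            continue
        rows.append(
            {
                "probe_um": float(probe),
                "before_um": height_maps[frames.index(before_f)].height_at(centerline_x, probe),
                "after_um": height_maps[frames.index(after_f)].height_at(centerline_x, probe),
                "frame_before": before_f,
                "frame_after": after_f,
            }
        )
    if not rows:
        warnings.warn("no passage event bracketed by the provided frames")
        return pd.DataFrame(
            columns=["probe_um", "before_um", "after_um", "frame_before", "frame_after"]
        )
    return pd.DataFrame(rows)
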