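"""Cell segmentation, tracking, speeds, and pioneer/trailing roles.

Cells are segmented per frame by Otsu thresholding with hole filling and a
watershed split of touching objects, linked across frames by greedy
nearest-neighbor assignment with a maximum-step gate and one-frame gap
closing, and labeled per frame as *pioneer* (the foremost cell along the
migration axis, which must deform the undeformed interface ahead of it) or
*trailing*.  Speeds are mean per-step centroid displacements converted to
um/min.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import regionprops
from skimage.segmentation import watershed

__all__ = [
    "Detection",
    "CellTrack",
    "segment_cells",
    "link_tracks",
    "track_speed",
    "classify_roles",
    "transition_analysis",
    "tracks_to_frame",
]


@dataclass
class Detection:
    """One segmented cell in one frame: centroid (x, y) in um, area in um^2."""

    centroid: tuple[float, float]
    area: float
    mask: np.ndarray


@dataclass
class CellTrack:
    """A linked centroid trajectory with per-frame role labels."""

    track_id: int
    frames: list[int] = field(default_factory=list)
    x_um: list[float] = field(default_factory=list)
    y_um: list[float] = field(default_factory=list)
    area_um2: list[float] = field(default_factory=list)
    roles: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.frames)


def segment_cells(
    frame: np.ndarray,
    pixel_size: float,
    min_area: float = 20.0,
    max_area: float = 400.0,
    split_min_distance_um: float = 3.0,
) -> list[Detection]:
    """Segment bright cells in one calibrated frame.

    Otsu threshold, hole filling, and a distance-transform watershed to
    split touching cells; objects outside [``min_area``, ``max_area``] um^2
    are rejected.  Returns an empty list for blank frames.
    """
    img = np.asarray(frame, float)
    if img.max() - img.min() <= 0:
        return []
    binary = img > threshold_otsu(img)
    if not binary.any():
        return []
    binary = ndimage.binary_fill_holes(binary)

    distance = ndimage.distance_transform_edt(binary) * pixel_size
    min_dist_px = max(int(round(split_min_distance_um / pixel_size)), 1)
    peaks = peak_local_max(
        distance, min_distance=min_dist_px, labels=binary, exclude_border=False
    )
    markers = np.zeros(binary.shape, int)
    for n, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = n
    if markers.max() == 0:
        labels, _ = ndimage.label(binary)
    else:
        labels = watershed(-distance, markers, mask=binary)

    out = []
    for prop in regionprops(labels):
        area = prop.area * pixel_size**2
        if not (min_area <= area <= max_area):
            continue
        cy, cx = prop.centroid
        out.append(
            Detection(
                centroid=((cx + 0.5) * pixel_size, (cy + 0.5) * pixel_size),
                area=area,
                mask=labels == prop.label,
            )
        )
    return out


def link_tracks(
    detections: list[list[Detection]],
    max_step: float,
    gap_frames: int = 1,
) -> list[CellTrack]:
    """Greedy nearest-neighbor linking of per-frame detections.

    Each active track predicts its next position by constant-velocity
    extrapolation of its last step (plain nearest-neighbor for one-point
    tracks), which keeps identities straight when one cell overtakes
    another.  Candidate (track, detection) pairs are assigned in order of
    increasing distance to the prediction; links farther than ``max_step``
    um per elapsed frame are rejected.  A track missing for up to
    ``gap_frames`` frames may still be extended (gap closing); unmatched
    detections start new tracks.
    """
    if len(detections) < 2:
        raise ValueError("need detections for at least 2 frames")
    tracks: list[CellTrack] = []
    active: list[CellTrack] = []
    next_id = 0

    for t, dets in enumerate(detections):
        candidates = []
        for tr in active:
            elapsed = t - tr.frames[-1]
            if elapsed > gap_frames + 1:
                continue
            px, py = tr.x_um[-1], tr.y_um[-1]
            if len(tr) >= 2:
                step = tr.frames[-1] - tr.frames[-2]
                vx = (tr.x_um[-1] - tr.x_um[-2]) / step
                vy = (tr.y_um[-1] - tr.y_um[-2]) / step
                px, py = px + vx * elapsed, py + vy * elapsed
            for d_idx, det in enumerate(dets):
                dist = math.hypot(det.centroid[0] - px, det.centroid[1] - py)
                if dist <= max_step * elapsed:
                    candidates.append((dist, tr.track_id, d_idx))
        candidates.sort(key=lambda c: c[0])
        used_tracks: set[int] = set()
        used_dets: set[int] = set()
        by_id = {tr.track_id: tr for tr in active}
        for dist, tid, d_idx in candidates:
            if tid in used_tracks or d_idx in used_dets:
                continue
            tr = by_id[tid]
            det = dets[d_idx]
            tr.frames.append(t)
            tr.x_um.append(det.centroid[0])
            tr.y_um.append(det.centroid[1])
            tr.area_um2.append(det.area)
            tr.roles.append("unassigned")
            used_tracks.add(tid)
            used_dets.add(d_idx)
        for d_idx, det in enumerate(dets):
            if d_idx in used_dets:
                continue
            tr = CellTrack(track_id=next_id)
            next_id += 1
            tr.frames.append(t)
            tr.x_um.append(det.centroid[0])
            tr.y_um.append(det.centroid[1])
            tr.area_um2.append(det.area)
            tr.roles.append("unassigned")
            tracks.append(tr)
            active.append(tr)
        active = [tr for tr in tracks if t - tr.frames[-1] <= gap_frames]
    return tracks


def track_speed(track: CellTrack, frame_interval_s: float) -> float:
    """Mean per-step speed of a track in um/min.

    Raises
    ------
    ValueError
        For single-frame tracks (speed undefined).
    """
    if len(track) < 2:
        raise ValueError("speed undefined for a single-frame track")
    steps = []
    for a, b in zip(range(len(track) - 1), range(1, len(track))):
        d = math.hypot(track.x_um[b] - track.x_um[a], track.y_um[b] - track.y_um[a])
        dt = (track.frames[b] - track.frames[a]) * frame_interval_s
        steps.append(d / dt)
    return float(np.mean(steps)) * 60.0


def classify_roles(
    tracks: list[CellTrack],
    stall_speed_um_min: float = 2.0,
    frame_interval_s: float = 30.0,
) -> list[CellTrack]:
    """Assign per-frame pioneer/trailing roles (in place) and return tracks.

    Per frame, the pioneer is the cell with the greatest along-channel (y)
    position among cells still advancing — a cell that has arrested (mean
    forward speed below ``stall_speed_um_min`` over its remaining frames)
    no longer deforms the interface and is not a pioneer even if foremost,
    as when a yielded ex-pioneer is overtaken.  All other cells in the
    channel are trailing.
    """
    if not tracks:
        return tracks
    all_frames = sorted({f for tr in tracks for f in tr.frames})

    def advancing(tr: CellTrack, t: int, window: int = 3) -> bool:
        idx = [k for k, f in enumerate(tr.frames) if t <= f <= t + window]
        if len(idx) < 2:
            # too little future to judge; fall back on recent past motion
            idx = [k for k, f in enumerate(tr.frames) if t - window <= f <= t]
            if len(idx) < 2:
                return True
        dy = tr.y_um[idx[-1]] - tr.y_um[idx[0]]
        dt_min = (tr.frames[idx[-1]] - tr.frames[idx[0]]) * frame_interval_s / 60.0
        return dt_min <= 0 or dy / dt_min >= stall_speed_um_min

    for t in all_frames:
        present = [(tr, tr.frames.index(t)) for tr in tracks if t in tr.frames]
        if not present:
            continue
        movers = [(tr, k) for tr, k in present if advancing(tr, t)]
        pool = movers if movers else present
        lead_tr, lead_k = max(pool, key=lambda p: p[0].y_um[p[1]])
        for tr, k in present:
            tr.roles[k] = "pioneer" if tr is lead_tr else "trailing"
    return tracks


def transition_analysis(
    track: CellTrack, frame_interval_s: float
) -> tuple[float, float, int]:
    """Mean speed before and after a trailing-to-pioneer transition.

    The track must contain exactly one trailing -> pioneer role flip.
    Returns ``(speed_before, speed_after, transition_frame)`` with speeds in
    um/min over the maximal trailing and pioneer segments, excluding the
    steps that span the transition frame itself.
    """
    flips = [
        k
        for k in range(1, len(track))
        if track.roles[k] == "pioneer" and track.roles[k - 1] == "trailing"
    ]
    if len(flips) != 1:
        raise ValueError(
            f"track {track.track_id} has {len(flips)} trailing->pioneer transitions; need exactly 1"
        )
    k0 = flips[0]

    def seg_speed(idx: list[int]) -> float:
        if len(idx) < 2:
            raise ValueError("segment too short to estimate a speed")
        steps = []
        for a, b in zip(idx[:-1], idx[1:]):
            d = math.hypot(
                track.x_um[b] - track.x_um[a], track.y_um[b] - track.y_um[a]
            )
            dt = (track.frames[b] - track.frames[a]) * frame_interval_s
            steps.append(d / dt * 60.0)
        return float(np.mean(steps))

    before = seg_speed(list(range(0, k0)))
    after = seg_speed(list(range(k0 + 1, len(track)))) if k0 + 2 < len(track) else seg_speed(
        list(range(k0, len(track)))
    )
    return before, after, track.frames[k0]


def tracks_to_frame(tracks: list[CellTrack], frame_interval_s: float) -> pd.DataFrame:
    """Tidy table of all tracks: track_id, frame, t_s, x_um, y_um, area_um2, role."""
    rows = []
    for tr in tracks:
        for k in range(len(tr)):
            rows.append(
                {
                    "track_id": tr.track_id,
                    "frame": tr.frames[k],
                    "t_s": tr.frames[k] * frame_interval_s,
                    "x_um": tr.x_um[k],
                    "y_um": tr.y_um[k],
                    "area_um2": tr.area_um2[k],
                    "role": tr.roles[k],
                }
            )
    return pd.DataFrame(rows)
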