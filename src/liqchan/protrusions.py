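"""Membrane protrusion detection and bleb/pseudopod classification.

On fast timelapses (<= 1-2 s frame intervals) new membrane area appearing
between consecutive frames seeds protrusion events, which are then tracked
by overlap until they regress.  Each event is summarized by its lifespan,
maximal area, maximal radial extension beyond the pre-event cell boundary,
time-to-max-extent, expansion speed, and circularity (4 pi A / P^2), and
classified: blebs are rapid (time-to-max <= ~2 s), rounded (circularity
above threshold), short-lived (< 10 s) lobes; everything slower or
sheet-like is a pseudopod.  All thresholds are configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import regionprops

__all__ = [
    "ProtrusionEvent",
    "ClassifierThresholds",
    "segment_movie",
    "detect_protrusions",
    "classify_protrusion",
    "bleb_rate",
]


@dataclass
class ProtrusionEvent:
    """A detected protrusion event and its shape/kinetic summary."""

    onset_frame: int
    onset_s: float
    lifespan_s: float
    max_area_um2: float
    max_extent_um: float
    time_to_max_s: float
    expansion_speed_um_s: float
    circularity: float
    centroid_um: tuple[float, float]
    label: str = "unclassified"


@dataclass(frozen=True)
class ClassifierThresholds:
    """Bleb signature thresholds (all inclusive on the bleb side)."""

    min_circularity: float = 0.7
    max_lifespan_s: float = 10.0
    max_time_to_max_s: float = 2.0


def segment_movie(movie: np.ndarray) -> np.ndarray:
    """Boolean cell masks for a (t, y, x) movie via a global Otsu threshold.

    A single threshold over the whole movie keeps frame-to-frame mask
    differences meaningful; the result is invariant to uniform intensity
    rescaling.
    """
    movie = np.asarray(movie, float)
    thr = threshold_otsu(movie.ravel())
    masks = movie > thr
    # light morphological cleanup: sub-pixel boundary flicker otherwise
    # produces thin spurious new-area arcs between frames
    struct = np.ones((3, 3), bool)
    out = []
    for m in masks:
        m = ndimage.binary_fill_holes(m)
        m = ndimage.binary_opening(m, structure=struct)
        m = ndimage.binary_fill_holes(m)
        out.append(m)
    return np.array(out)


def detect_protrusions(
    masks: np.ndarray,
    frame_interval_s: float,
    pixel_size: float,
    min_area_um2: float = 1.0,
    min_extent_um: float = 1.0,
    confirm_window_s: float = 15.0,
) -> list[ProtrusionEvent]:
    """Detect protrusion events from cell masks over frames.

    New area between consecutive frames (``mask[t] & ~mask[t-1]``) seeds
    candidate events; a candidate is confirmed once its accumulated region
    reaches ``min_area_um2`` (so slowly growing sheets whose per-frame
    increment is small are still found).  An event's region at later frames
    is the connected component of ``mask[t] & ~baseline`` (baseline = the
    cell mask just before onset) that overlaps its previous region; the
    event ends when that region regresses below the minimum area or
    retracts to the boundary.  Confirmation additionally requires a radial
    extension of at least ``min_extent_um`` beyond the baseline boundary,
    which rejects segmentation jitter arcs that hug the cell outline.
    """
    if frame_interval_s > 2.0:
        raise ValueError("protrusion kinetics require frame_interval_s <= 2 s")
    masks = np.asarray(masks, bool)
    if masks.ndim != 3:
        raise ValueError("masks must be (t, y, x)")
    n_frames = len(masks)
    if n_frames < 2:
        return []
    min_px = max(int(round(min_area_um2 / pixel_size**2)), 1)
    seed_px = max(3, min_px // 4)  # single-pixel jitter cannot seed
    confirm_frames = max(int(round(confirm_window_s / frame_interval_s)), 2)

    active: list[dict] = []
    finished: list[dict] = []
    for t in range(1, n_frames):
        new_area = masks[t] & ~masks[t - 1]
        labels, n_lab = ndimage.label(new_area)

        # grow/maintain active events and candidates first (onset order, so
        # fragments that merge into an earlier event are not double-counted)
        still_active = []
        taken = np.zeros_like(new_area)
        for ev in sorted(active, key=lambda e: e["onset"]):
            grown = masks[t] & ~ev["baseline"]
            glab, _ = ndimage.label(grown)
            overlap_labels = np.unique(glab[ev["region"]])
            overlap_labels = overlap_labels[overlap_labels > 0]
            region = np.isin(glab, overlap_labels) if len(overlap_labels) else None
            if region is not None and (region & taken).any():
                # merged into an earlier event's region: drop the duplicate
                continue
            extent = float(ev["dist"][region].max()) if region is not None and region.any() else 0.0
            retracted = region is None or region.sum() < (
                min_px if ev["confirmed"] else 1
            )
            if ev["confirmed"] and extent < 0.5 * min_extent_um:
                retracted = True
            if not ev["confirmed"] and t - ev["onset"] > confirm_frames:
                continue  # never took off: segmentation jitter
            if retracted:
                if ev["confirmed"]:
                    finished.append(ev)
                continue
            taken |= region
            if (
                not ev["confirmed"]
                and region.sum() >= min_px
                and extent >= min_extent_um
            ):
                ev["confirmed"] = True
            ev["region"] = region
            ev["end_frame"] = t
            if region.sum() > max(ev["areas"]):
                ev["best_region"] = region
            ev["areas"].append(region.sum())
            ev["extents"].append(float(ev["dist"][region].max()))
            ev["frames"].append(t)
            still_active.append(ev)
        active = still_active

        # seed new candidates from new-area components not claimed already
        claimed = np.zeros_like(new_area)
        for ev in active:
            claimed |= ev["region"]
        for lab in range(1, n_lab + 1):
            comp = labels == lab
            if comp.sum() < seed_px or (comp & claimed).any():
                continue
            baseline = masks[t - 1]
            dist = ndimage.distance_transform_edt(~baseline) * pixel_size
            active.append(
                {
                    "onset": t,
                    "end_frame": t,
                    "confirmed": comp.sum() >= min_px
                    and float(dist[comp].max()) >= min_extent_um,
                    "baseline": baseline.copy(),
                    "region": comp,
                    "best_region": comp,
                    "dist": dist,
                    "areas": [comp.sum()],
                    "extents": [float(dist[comp].max())],
                    "frames": [t],
                }
            )
    finished.extend(ev for ev in active if ev["confirmed"])

    events = []
    for ev in finished:
        areas = np.array(ev["areas"], float) * pixel_size**2
        extents = np.array(ev["extents"], float)
        k_max = int(np.argmax(extents))
        time_to_max = max((ev["frames"][k_max] - ev["onset"]) * frame_interval_s,
                          frame_interval_s)
        # lifespan from onset until regression (one frame past the last grown frame)
        lifespan = (ev["end_frame"] - ev["onset"] + 1) * frame_interval_s
        circ, centroid = _region_shape(ev["best_region"], pixel_size)
        events.append(
            ProtrusionEvent(
                onset_frame=ev["onset"],
                onset_s=ev["onset"] * frame_interval_s,
                lifespan_s=float(lifespan),
                max_area_um2=float(areas.max()),
                max_extent_um=float(extents.max()),
                time_to_max_s=float(time_to_max),
                expansion_speed_um_s=float(extents.max() / time_to_max),
                circularity=circ,
                centroid_um=centroid,
            )
        )
    events.sort(key=lambda e: e.onset_frame)
    return events


def _region_shape(region: np.ndarray, pixel_size: float) -> tuple[float, tuple[float, float]]:
    """Circularity and centroid of the event region at its maximal area."""
    props = regionprops(region.astype(int))
    if not props:
        return 0.0, (math.nan, math.nan)
    p = props[0]
    perim = p.perimeter_crofton * pixel_size
    area = p.area * pixel_size**2
    circ = 4.0 * math.pi * area / perim**2 if perim > 0 else 0.0
    cy, cx = p.centroid
    return float(min(circ, 1.0)), ((cx + 0.5) * pixel_size, (cy + 0.5) * pixel_size)


def classify_protrusion(
    event: ProtrusionEvent, thresholds: ClassifierThresholds = ClassifierThresholds()
) -> str:
    """Label an event ``"bleb"`` or ``"pseudopod"``.

    Bleb iff circularity >= ``min_circularity`` (inclusive) AND lifespan
    < ``max_lifespan_s`` AND time-to-max-extent <= ``max_time_to_max_s``;
    otherwise pseudopod.
    """
    is_bleb = (
        event.circularity >= thresholds.min_circularity
        and event.lifespan_s < thresholds.max_lifespan_s
        and event.time_to_max_s <= thresholds.max_time_to_max_s
    )
    event.label = "bleb" if is_bleb else "pseudopod"
    return event.label


def bleb_rate(events: list[ProtrusionEvent], observation_span_s: float) -> float:
    """Classified blebs per minute over the observation span.

    Raises
    ------
    ValueError
        For a non-positive span.
    """
    if observation_span_s <= 0:
        raise ValueError("observation span must be positive")
    n_blebs = sum(1 for e in events if e.label == "bleb")
    return n_blebs / (observation_span_s / 60.0)
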