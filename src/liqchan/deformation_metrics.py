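"""Protrusion-width and boundary-deformation metrics.

Two measurements link the in vitro interface deformation to the
deformation of surrounding cells in tissue: the width of the leading
protrusion of a migrating cell (the thin wedge that first deforms the
environment) and the maximal outward displacement of a neighboring cell
boundary as the cell body passes.  Both are reported in um and are
invariant to rigid translation and to uniform, calibrated pixel rescaling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["DeformationMeasurement", "protrusion_width", "max_boundary_deformation"]


@dataclass(frozen=True)
class DeformationMeasurement:
    """Paired deformation metrics for one passage event."""

    protrusion_width_um: float
    max_boundary_deformation_um: float
    event_id: int = 0
    source: str = "in-vitro"


def protrusion_width(
    mask: np.ndarray,
    pixel_size: float,
    axis: str = "y",
    leading_fraction: float = 0.2,
) -> float:
    """Width of a cell mask's leading slab, perpendicular to the migration axis.

    The leading slab is the front ``leading_fraction`` of the mask's extent
    along the migration axis (``'y'``: rows toward larger index are the
    front; ``'x'``: columns).  Width is the perpendicular pixel extent of
    that slab, in um.

    Raises
    ------
    ValueError
        For an empty mask or unknown axis.
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("degenerate (empty) cell mask")
    if axis == "x":
        mask = mask.T
    elif axis != "y":
        raise ValueError("axis must be 'x' or 'y'")
    rows = np.where(mask.any(axis=1))[0]
    lo, hi = rows[0], rows[-1]
    cut = hi - leading_fraction * (hi - lo + 1)
    slab = mask[int(math.ceil(cut)) :, :]
    cols = np.where(slab.any(axis=0))[0]
    return float((cols[-1] - cols[0] + 1) * pixel_size)


def max_boundary_deformation(
    reference: np.ndarray,
    deformed_sequence: list[np.ndarray],
    outward_from: np.ndarray | None = None,
) -> float:
    """Maximal outward boundary displacement over time, in um.

    ``reference`` is an ordered (n, 2) point list of the undeformed
    boundary; each element of ``deformed_sequence`` the same boundary at a
    later time, point-for-point.  The displacement of each point is its
    distance from the reference position; when ``outward_from`` (the
    position of the deforming cell, or any interior point) is given, only
    the displacement component pointing away from it counts, so inward
    jitter cannot inflate the measurement.  The maximum is taken over all
    points and all times — a displacement that later relaxes still reports
    its peak.

    Raises
    ------
    ValueError
        When a deformed boundary does not match the reference point count.
    """
    ref = np.asarray(reference, float)
    if ref.ndim != 2 or ref.shape[1] != 2:
        raise ValueError("reference boundary must be (n, 2)")
    best = 0.0
    for t, deformed in enumerate(deformed_sequence):
        d = np.asarray(deformed, float)
        if d.shape != ref.shape:
            raise ValueError(f"deformed boundary at index {t} does not match the reference")
        disp = d - ref
        if outward_from is None:
            mag = np.hypot(disp[:, 0], disp[:, 1])
        else:
            out_dir = ref - np.asarray(outward_from, float)
            norm = np.hypot(out_dir[:, 0], out_dir[:, 1])
            norm[norm < 1e-12] = 1e-12
            mag = (disp * out_dir).sum(axis=1) / norm
        best = max(best, float(mag.max(initial=0.0)))
    return best
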