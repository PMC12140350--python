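"""TIFF + JSON-sidecar reading and writing.

Volumes are multi-page TIFFs ordered z (then channel for multi-channel
movies: t, c, y, x); calibration (voxel sizes in um, frame interval in s)
travels in a JSON sidecar next to the image file.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["write_image", "read_image", "write_height_map", "read_height_map"]


def write_image(path, array: np.ndarray, metadata: dict) -> None:
    """Write an image stack as TIFF with a ``.json`` calibration sidecar."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(array, np.float32), photometric="minisblack")
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(metadata, fh, indent=1)


def read_image(path) -> tuple[np.ndarray, dict]:
    """Read a TIFF stack and its JSON sidecar (empty dict if absent)."""
    path = Path(path)
    data = tifffile.imread(path)
    sidecar = path.with_suffix(".json")
    meta: dict = {}
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = json.load(fh)
    return data, meta


def write_height_map(path, hmap) -> None:
    """Write a HeightMap as a 32-bit TIFF in um (NaN where masked) + sidecar."""
    heights = np.where(hmap.mask, hmap.heights, np.nan).astype(np.float32)
    write_image(path, heights, {"spacing_um": hmap.spacing, "units": "um"})


def read_height_map(path):
    """Read a height map written by :func:`write_height_map`."""
    from liqchan.interface_extraction import HeightMap

    heights, meta = read_image(path)
    spacing = float(meta.get("spacing_um", 1.0))
    ny, nx = heights.shape
    return HeightMap(
        heights=heights.astype(float),
        mask=~np.isnan(heights),
        spacing=spacing,
        x_um=(np.arange(nx) + 0.5) * spacing,
        y_um=(np.arange(ny) + 0.5) * spacing,
    )
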