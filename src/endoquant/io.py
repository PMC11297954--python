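"""TIFF, ROI-CSV and table I/O.

TIFF reading/writing is delegated to :mod:`tifffile`; channel roles and
pixel sizes are not assumed from metadata — acquisitions rarely carry them
reliably — so they are supplied explicitly (CLI flags or the YAML config).

ROI polygons use the CSV dialect ``roi_id, vertex_index, x, y`` in ImageJ
coordinates (pixel centres, origin top-left, x rightward, y downward,
0-based).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .imgproc import Image2D, ImageStack
from .junction_quant import Polygon

__all__ = [
    "read_image",
    "read_stack",
    "write_image",
    "write_stack",
    "read_rois_csv",
    "write_rois_csv",
]


def read_image(
    path: str | Path, pixel_size: float = 1.0, channel_role: str = "other"
) -> Image2D:
    """Read a single-page TIFF as an :class:`Image2D`."""
    data = tifffile.imread(str(path))
    if data.ndim == 3 and data.shape[0] == 1:
        data = data[0]
    if data.ndim != 2:
        raise ValueError(
            f"{path}: expected a single 2-D page, got shape {data.shape}; "
            "use read_stack for multi-page files"
        )
    return Image2D(np.asarray(data, dtype=float), pixel_size, channel_role)


def read_stack(
    path: str | Path,
    pixel_size: float = 1.0,
    channel_role: str = "other",
    axis_meaning: str = "z",
    frame_interval: float | None = None,
) -> ImageStack:
    """Read a multi-page TIFF as an :class:`ImageStack`."""
    data = tifffile.imread(str(path))
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 2-D or 3-D TIFF, got {data.shape}")
    slices = [
        Image2D(np.asarray(page, dtype=float), pixel_size, channel_role)
        for page in data
    ]
    return ImageStack(slices, axis_meaning, frame_interval)


def write_image(image: Image2D, path: str | Path) -> None:
    tifffile.imwrite(str(path), image.pixels.astype(np.float32))


def write_stack(stack: ImageStack, path: str | Path) -> None:
    tifffile.imwrite(str(path), stack.as_array().astype(np.float32))


def read_rois_csv(path: str | Path) -> list[Polygon]:
    """Read junction-outline polygons from a ROI CSV file."""
    df = pd.read_csv(path)
    required = {"roi_id", "vertex_index", "x", "y"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"ROI CSV missing columns: {sorted(missing)}")
    polys = []
    for roi_id, g in df.groupby("roi_id", sort=True):
        g = g.sort_values("vertex_index")
        polys.append(Polygon(g[["x", "y"]].to_numpy(float), roi_id=roi_id))
    return polys


def write_rois_csv(polygons: list[Polygon], path: str | Path) -> None:
    rows = []
    for i, poly in enumerate(polygons):
        rid = poly.roi_id if poly.roi_id is not None else i
        for j, (x, y) in enumerate(poly.vertices):
            rows.append({"roi_id": rid, "vertex_index": j, "x": x, "y": y})
    pd.DataFrame(rows).to_csv(path, index=False)
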