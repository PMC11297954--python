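"""Adherens-junction (AJ) mask construction and junctional quantification.

The AJ mask is built from the VE-Cadherin channel with the standard pipeline
average-projection -> rolling-ball background subtraction -> automatic
("Default"/isodata) threshold.  Co-stained channels (e.g. N-Cadherin, YAP)
are then quantified against that mask:

* ``junctional_intensity_ratio`` — mean processed channel intensity inside
  the AJ mask divided by the mean outside it ("signal at junctions relative
  to background"),
* ``junctional_yap_fraction`` — area of the thresholded YAP signal
  intersected with the AJ mask, divided by the AJ-mask area,
* ``junction_shape`` — perimeter, area and Feret's diameter of manually
  outlined junction polygons, plus the Feret-normalized descriptors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import shapely.geometry
from scipy.spatial.distance import pdist

from .imgproc import (
    BinaryMask,
    Image2D,
    ImageStack,
    binarize,
    project_stack,
    rolling_ball_subtract,
)

__all__ = [
    "AJMask",
    "Polygon",
    "JunctionShape",
    "build_aj_mask",
    "junctional_intensity_ratio",
    "junctional_yap_fraction",
    "junction_shape",
    "feret_diameter",
]


@dataclass
class AJMask:
    """Binary adherens-junction mask with the parameters that produced it."""

    mask: BinaryMask
    source_params: dict = field(default_factory=dict)

    @property
    def aj_area_um2(self) -> float:
        return self.mask.area_um2


@dataclass
class Polygon:
    """A junction outline: ordered (x, y) pixel-coordinate vertices.

    Uses the ImageJ-ROI convention: pixel centres, origin top-left,
    x rightward, y downward, 0-based.  Two vertices are permitted only for
    degenerate Feret queries; area/perimeter need at least three.
    """

    vertices: np.ndarray
    roi_id: str | int | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 2:
            raise ValueError("Polygon requires an (n>=2, 2) vertex array")
        if not np.all(np.isfinite(v)):
            raise ValueError("Polygon vertices must be finite")
        if np.any(np.all(v[1:] == v[:-1], axis=1)):
            raise ValueError("Polygon has repeated consecutive vertices")
        self.vertices = v

    def __len__(self) -> int:
        return len(self.vertices)


@dataclass
class JunctionShape:
    """Shape descriptors of one junction outline.

    ``perimeter_over_feret`` and ``area_over_feret2`` are the two readings of
    "normalized by the longest distance in the shape (Feret's diameter)";
    both are reported so either is available.
    """

    perimeter_um: float
    area_um2: float
    feret_um: float
    perimeter_over_feret: float
    area_over_feret2: float


def _as_projected(channel: ImageStack | Image2D, method: str) -> Image2D:
    """Project a stack (or pass through an already projected image)."""
    if isinstance(channel, ImageStack):
        return project_stack(channel, method)
    return channel


def build_aj_mask(
    vecad: ImageStack | Image2D,
    rolling_ball_radius_px: int = 300,
    threshold_method: str = "isodata_default",
    fixed_threshold: float | None = None,
) -> AJMask:
    """Build the adherens-junction mask from the VE-Cadherin channel.

    Pipeline: average-intensity projection, rolling-ball background
    subtraction (default radius 300 px), automatic isodata threshold.
    Parameters are overridable but the defaults are the reference workflow's.
    """
    if vecad.channel_role != "VE-Cadherin":
        raise ValueError("build_aj_mask expects the VE-Cadherin channel")
    projected = _as_projected(vecad, "average")
    processed = rolling_ball_subtract(projected, rolling_ball_radius_px)
    mask = binarize(processed, threshold_method, fixed_threshold)
    if not mask.pixels.any():
        warnings.warn("AJ mask is empty: no junctional signal above threshold",
                      stacklevel=2)
    params = {
        "projection": "average",
        "rolling_ball_radius_px": rolling_ball_radius_px,
        "threshold_method": threshold_method,
        "threshold": mask.threshold,
    }
    return AJMask(mask, params)


def junctional_intensity_ratio(
    channel: ImageStack | Image2D,
    aj: AJMask,
    rolling_ball_radius_px: int | None = 80,
) -> float:
    """Mean processed intensity inside the AJ mask over the mean outside it.

    The channel is average-projected and rolling-ball background subtracted
    (default radius 80 px; ``None`` skips the subtraction) before the means
    are taken.  The complement of the AJ mask within the field of view
    serves as the background region.
    """
    projected = _as_projected(channel, "average")
    if projected.shape != aj.mask.shape:
        raise ValueError("channel and AJ mask shapes differ")
    if rolling_ball_radius_px is None:
        processed = projected
    else:
        processed = rolling_ball_subtract(projected, rolling_ball_radius_px)
    inside = aj.mask.pixels
    outside = ~inside
    if not inside.any():
        raise ValueError("AJ mask is empty: junctional ratio undefined")
    if not outside.any():
        raise ValueError("AJ mask covers the whole field: no background region")
    mean_in = float(processed.pixels[inside].mean())
    mean_out = float(processed.pixels[outside].mean())
    if mean_out == 0.0:
        raise ValueError("background mean is zero: ratio undefined")
    return mean_in / mean_out


def junctional_yap_fraction(
    yap: ImageStack | Image2D,
    aj: AJMask,
    fixed_threshold: float,
    rolling_ball_radius_px: int | None = 25,
) -> float:
    """Fraction of the AJ-mask area occupied by thresholded YAP signal.

    The YAP channel is maximum-projected and rolling-ball background
    subtracted (default radius 25 px; ``None`` skips the subtraction), then
    cut at ``fixed_threshold`` — the same value must be applied to every
    image of a batch so fractions are comparable across conditions.
    Returns area(YAP mask ∩ AJ mask) / area(AJ mask), in [0, 1].
    """
    if fixed_threshold <= 0:
        raise ValueError("fixed_threshold must be > 0")
    projected = _as_projected(yap, "max")
    if projected.shape != aj.mask.shape:
        raise ValueError("YAP channel and AJ mask shapes differ")
    if rolling_ball_radius_px is None:
        processed = projected
    else:
        processed = rolling_ball_subtract(projected, rolling_ball_radius_px)
    yap_mask = processed.pixels > fixed_threshold
    aj_pixels = aj.mask.pixels
    n_aj = int(aj_pixels.sum())
    if n_aj == 0:
        raise ValueError("AJ mask is empty: junctional YAP fraction undefined")
    return float((yap_mask & aj_pixels).sum()) / n_aj


def feret_diameter(polygon: Polygon, pixel_size: float = 1.0) -> float:
    """Feret's (maximum caliper) diameter: max pairwise vertex distance."""
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    return float(pdist(polygon.vertices).max()) * pixel_size


def junction_shape(polygon: Polygon, pixel_size: float) -> JunctionShape:
    """Perimeter, area, Feret's diameter and Feret-normalized descriptors.

    Perimeter is the closed polyline length, area the absolute enclosed
    (shoelace) area, Feret the maximum pairwise vertex distance; all in
    physical units via ``pixel_size`` (um/px).
    """
    if len(polygon) < 3:
        raise ValueError("area/perimeter require at least 3 vertices "
                         "(2-point polygons support Feret queries only)")
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    shp = shapely.geometry.Polygon(polygon.vertices)
    perimeter = float(shp.exterior.length) * pixel_size
    area = float(shp.area) * pixel_size**2
    feret = feret_diameter(polygon, pixel_size)
    return JunctionShape(
        perimeter_um=perimeter,
        area_um2=area,
        feret_um=feret,
        perimeter_over_feret=perimeter / feret if feret > 0 else float("nan"),
        area_over_feret2=area / feret**2 if feret > 0 else float("nan"),
    )
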