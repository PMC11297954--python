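"""Structure-tensor orientation analysis and the AJ–actin mismatch score.

Local orientation is estimated from the structure tensor: image gradients
are computed with cubic-B-spline derivative filters, their outer products
are smoothed with a Gaussian window (default sigma 4 px), and the dominant
axial orientation at each pixel is

    theta = 1/2 * atan2(2*Jxy, Jyy - Jxx)   in degrees, [-90, 90)

with the tensor trace as an energy weight.  Angles are measured
counterclockwise from the +x (column) axis with y pointing up; since image
rows run downward, a fiber drawn toward increasing row index has a negative
angle.  Orientations are axial (period 180 deg).

Per-channel orientation distributions are summarized as 18-bin (ten-degree)
normalized histograms, and the mismatch between the actin and the
VE-Cadherin (junction) channel of one region of interest is their L1
distance — 0 for identical distributions, 2 for disjoint ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .imgproc import Image2D, gaussian_blur, sharpen
from .junction_quant import Polygon

__all__ = [
    "N_BINS",
    "BIN_EDGES_DEG",
    "OrientationHistogram",
    "MismatchScore",
    "structure_tensor_orientations",
    "orientation_histogram",
    "mismatch_score",
    "aj_actin_mismatch",
]

N_BINS = 18
BIN_EDGES_DEG = np.linspace(-90.0, 90.0, N_BINS + 1)

#: Central-difference weights applied to cubic-spline coefficients; together
#: with the order-3 prefilter this evaluates the exact derivative of the
#: interpolating cubic B-spline at the pixel centres.
_SPLINE_DERIV = np.array([-0.5, 0.0, 0.5])


@dataclass
class OrientationHistogram:
    """Normalized 18-bin axial orientation distribution.

    ``bins[k]`` is the probability mass on [-90 + 10k, -80 + 10k) degrees;
    ``n_angles`` counts the pixels that contributed.
    """

    bins: np.ndarray
    n_angles: int

    def __post_init__(self) -> None:
        b = np.asarray(self.bins, dtype=float)
        if b.shape != (N_BINS,):
            raise ValueError(f"histogram must have exactly {N_BINS} bins")
        if np.any(b < 0):
            raise ValueError("histogram weights must be non-negative")
        if abs(b.sum() - 1.0) > 1e-9:
            raise ValueError("histogram must sum to 1")
        self.bins = b


@dataclass
class MismatchScore:
    """L1 distance between two orientation histograms, in [0, 2]."""

    value: float
    roi_id: str | int | None = None

    def __post_init__(self) -> None:
        if not (-1e-9 <= self.value <= 2.0 + 1e-9):
            raise ValueError("mismatch score must lie in [0, 2]")
        self.value = float(min(max(self.value, 0.0), 2.0))


def _spline_gradient(pixels: np.ndarray, axis: int) -> np.ndarray:
    coeffs = ndi.spline_filter(pixels, order=3, mode="mirror")
    return ndi.correlate1d(coeffs, _SPLINE_DERIV, axis=axis, mode="mirror")


def structure_tensor_orientations(
    image: Image2D, window_sigma_px: float = 4.0
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel dominant orientation (degrees in [-90, 90)) and energy.

    Returns ``(orientation_deg, energy)`` arrays of the image's shape.
    Energy is the structure-tensor trace; pixels with zero energy have no
    defined orientation and should be excluded from histograms (NaN is
    stored there).
    """
    if window_sigma_px <= 0:
        raise ValueError("window_sigma_px must be positive")
    support = max(4, int(np.ceil(2 * window_sigma_px)))
    if min(image.shape) < support:
        raise ValueError(
            f"image {image.shape} smaller than the filter support ({support} px)"
        )
    p = image.pixels
    gx = _spline_gradient(p, axis=1)
    # raw row-axis gradient: rows run downward, and that sign flip is what
    # makes the +2*Jxy convention below return angles in the y-up frame
    gy = _spline_gradient(p, axis=0)
    jxx = ndi.gaussian_filter(gx * gx, window_sigma_px, mode="nearest")
    jyy = ndi.gaussian_filter(gy * gy, window_sigma_px, mode="nearest")
    jxy = ndi.gaussian_filter(gx * gy, window_sigma_px, mode="nearest")
    energy = jxx + jyy
    theta = 0.5 * np.arctan2(2.0 * jxy, jyy - jxx)
    deg = np.degrees(theta)
    deg = (deg + 90.0) % 180.0 - 90.0  # wrap to [-90, 90)
    # scale-aware floor: filter round-off on flat images must not count as
    # a defined orientation
    floor = (1e-9 * float(np.abs(p).max() + np.ptp(p))) ** 2
    undefined = energy <= floor
    deg[undefined] = np.nan
    energy = np.where(undefined, 0.0, energy)
    return deg, energy


def orientation_histogram(
    orientation_deg: np.ndarray,
    energy: np.ndarray | None = None,
    weighting: str = "uniform",
    energy_threshold: float = 0.0,
) -> OrientationHistogram:
    """Bin an orientation map into the normalized 18-bin histogram.

    ``weighting="uniform"`` counts every contributing pixel once (each pixel
    one angle); ``"energy"`` weights each pixel by its tensor energy.
    Pixels with NaN orientation or energy <= ``energy_threshold`` are
    excluded.
    """
    if weighting not in ("uniform", "energy"):
        raise ValueError(f"unknown weighting {weighting!r}")
    angles = np.asarray(orientation_deg, dtype=float).ravel()
    valid = np.isfinite(angles)
    if energy is not None:
        e = np.asarray(energy, dtype=float).ravel()
        valid &= e > energy_threshold
    if not valid.any():
        raise ValueError("no pixels with defined orientation")
    angles = angles[valid]
    if weighting == "energy":
        if energy is None:
            raise ValueError("energy weighting requires an energy map")
        weights = np.asarray(energy, dtype=float).ravel()[valid]
    else:
        weights = None
    counts, _ = np.histogram(angles, bins=BIN_EDGES_DEG, weights=weights)
    total = counts.sum()
    if total <= 0:
        raise ValueError("no histogram mass after weighting")
    return OrientationHistogram(counts / total, int(valid.sum()))


def mismatch_score(
    h1: OrientationHistogram,
    h2: OrientationHistogram,
    roi_id: str | int | None = None,
) -> MismatchScore:
    """Sum over bins of the absolute histogram difference (L1 distance)."""
    return MismatchScore(float(np.abs(h1.bins - h2.bins).sum()), roi_id)


def _enlarged_bbox(
    roi: Polygon, margin_px: float, shape: tuple[int, int]
) -> tuple[int, int, int, int]:
    """ROI bounding box grown by the margin on each side, clipped to image."""
    x0, y0 = roi.vertices.min(axis=0)
    x1, y1 = roi.vertices.max(axis=0)
    r0 = int(np.floor(y0 - margin_px))
    r1 = int(np.ceil(y1 + margin_px)) + 1
    c0 = int(np.floor(x0 - margin_px))
    c1 = int(np.ceil(x1 + margin_px)) + 1
    if r0 < 0 or c0 < 0 or r1 > shape[0] or c1 > shape[1]:
        warnings.warn("enlarged ROI extends past the image: clipping",
                      stacklevel=3)
    r0, c0 = max(r0, 0), max(c0, 0)
    r1, c1 = min(r1, shape[0]), min(c1, shape[1])
    if r1 - r0 < 1 or c1 - c0 < 1:
        raise ValueError("ROI lies outside the image")
    return r0, r1, c0, c1


def aj_actin_mismatch(
    actin_patch: Image2D,
    vecad_patch: Image2D,
    roi: Polygon,
    pixel_size: float,
    margin_um: float = 3.0,
    window_sigma_px: float = 4.0,
    blur_sigma_px: float = 2.0,
    weighting: str = "uniform",
) -> MismatchScore:
    """Orientation mismatch between actin and junction for one junction ROI.

    The ROI bounding box is enlarged by ``margin_um`` on each side; within
    that patch the actin channel is sharpened and the VE-Cadherin channel
    Gaussian-blurred (sigma 2 px), each is run through structure-tensor
    orientation analysis, and the two normalized ten-degree histograms are
    compared by their L1 distance.
    """
    if actin_patch.shape != vecad_patch.shape:
        raise ValueError("actin and VE-Cadherin patches must be registered")
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    margin_px = margin_um / pixel_size
    r0, r1, c0, c1 = _enlarged_bbox(roi, margin_px, actin_patch.shape)
    actin = actin_patch.with_pixels(actin_patch.pixels[r0:r1, c0:c1])
    vecad = vecad_patch.with_pixels(vecad_patch.pixels[r0:r1, c0:c1])
    actin = sharpen(actin)
    vecad = gaussian_blur(vecad, blur_sigma_px)
    hists = []
    for patch in (actin, vecad):
        deg, energy = structure_tensor_orientations(patch, window_sigma_px)
        hists.append(orientation_histogram(deg, energy, weighting))
    return mismatch_score(hists[0], hists[1], roi.roi_id)
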