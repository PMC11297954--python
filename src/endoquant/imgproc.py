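"""Low-level image operations shared by every quantification module.

The processing vocabulary mirrors the Fiji/ImageJ functions commonly used in
endothelial junction quantification workflows: intensity projections,
rolling-ball background subtraction, the "Default" (isodata/intermeans)
automatic threshold, the 3x3 sharpen kernel, Gaussian blur and temporal
median-projection background removal.  Semantics are documented explicitly so
results are reproducible outside ImageJ:

* rolling-ball background = grayscale opening with a spherical-cap
  structuring element of the stated pixel radius (no shrink/paraboloid
  approximations, so values may differ slightly from Fiji's),
* all convolutions use replicate (edge) padding,
* subtraction results are clipped at zero (intensities are photon counts).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

__all__ = [
    "CHANNEL_ROLES",
    "Image2D",
    "ImageStack",
    "BinaryMask",
    "project_stack",
    "rolling_ball_subtract",
    "binarize",
    "isodata_threshold",
    "sharpen",
    "gaussian_blur",
    "subtract_median_projection",
]

CHANNEL_ROLES = frozenset(
    {
        "VE-Cadherin",
        "N-Cadherin",
        "actin",
        "YAP",
        "DAPI",
        "streptavidin",
        "brightfield",
        "other",
    }
)

#: 3x3 ImageJ "Sharpen" kernel (sums to one, so flat regions are preserved).
SHARPEN_KERNEL = np.array(
    [[-1.0, -1.0, -1.0], [-1.0, 12.0, -1.0], [-1.0, -1.0, -1.0]]
) / 4.0


@dataclass
class Image2D:
    """A single-channel 2-D fluorescence (or brightfield) image.

    Parameters
    ----------
    pixels
        2-D array of intensities in arbitrary fluorescence units.
    pixel_size
        Physical size of one pixel in micrometres.
    channel_role
        Biological channel identity, one of :data:`CHANNEL_ROLES`.
    """

    pixels: np.ndarray
    pixel_size: float = 1.0
    channel_role: str = "other"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("Image2D requires a non-empty 2-D pixel grid")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("Image2D pixels must be finite")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive (um/px)")
        if self.channel_role not in CHANNEL_ROLES:
            raise ValueError(
                f"unknown channel_role {self.channel_role!r}; "
                f"expected one of {sorted(CHANNEL_ROLES)}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def with_pixels(self, pixels: np.ndarray) -> "Image2D":
        """Copy of this image with new pixel data, metadata preserved."""
        return Image2D(pixels, self.pixel_size, self.channel_role)


@dataclass
class ImageStack:
    """An ordered stack of equally shaped :class:`Image2D` slices.

    ``axis_meaning`` distinguishes z-stacks (``"z"``) from time-lapse
    sequences (``"time"``); time-lapse stacks carry a ``frame_interval`` in
    minutes.
    """

    slices: list
    axis_meaning: str = "z"
    frame_interval: float | None = None

    def __post_init__(self) -> None:
        if len(self.slices) < 1:
            raise ValueError("ImageStack requires at least one slice")
        shape = self.slices[0].shape
        px = self.slices[0].pixel_size
        for s in self.slices:
            if s.shape != shape:
                raise ValueError("all slices must share the same shape")
            if s.pixel_size != px:
                raise ValueError("all slices must share the same pixel_size")
        if self.axis_meaning not in ("z", "time"):
            raise ValueError("axis_meaning must be 'z' or 'time'")
        if self.axis_meaning == "time":
            if self.frame_interval is None or self.frame_interval <= 0:
                raise ValueError("time stacks require frame_interval > 0 (min)")

    def __len__(self) -> int:
        return len(self.slices)

    @property
    def pixel_size(self) -> float:
        return self.slices[0].pixel_size

    @property
    def channel_role(self) -> str:
        return self.slices[0].channel_role

    def as_array(self) -> np.ndarray:
        """Return the stack as a (n_slices, H, W) float array."""
        return np.stack([s.pixels for s in self.slices])


@dataclass
class BinaryMask:
    """A {0,1} segmentation mask with physical pixel size.

    ``threshold`` records the intensity cut that produced the mask (``None``
    for masks not derived from a threshold).
    """

    pixels: np.ndarray
    pixel_size: float = 1.0
    threshold: float | None = field(default=None)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels).astype(bool)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("BinaryMask requires a non-empty 2-D grid")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive (um/px)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def area_um2(self) -> float:
        """Mask area in square micrometres."""
        return float(self.pixels.sum()) * self.pixel_size**2


# ---------------------------------------------------------------------------
# projections


def project_stack(stack: ImageStack, method: str = "average") -> Image2D:
    """Reduce a stack to a single image per pixel.

    ``method`` is one of ``average``, ``max``, ``sum``, ``median`` (the
    ImageJ Z-project modes used here).  Channel role and pixel size are
    inherited from the slices.
    """
    reducers = {
        "average": np.mean,
        "max": np.max,
        "sum": np.sum,
        "median": np.median,
    }
    if method not in reducers:
        raise ValueError(f"unknown projection method {method!r}")
    data = stack.as_array()
    out = reducers[method](data, axis=0)
    return Image2D(out, stack.pixel_size, stack.channel_role)


# ---------------------------------------------------------------------------
# rolling-ball background subtraction


def _ball_structure(radius_px: int) -> tuple[np.ndarray, np.ndarray]:
    """Spherical-cap structuring element: footprint and (non-flat) heights.

    Heights are relative to the ball apex, i.e. ``sqrt(r^2 - d^2) - r`` which
    is 0 at the centre and negative toward the rim.
    """
    r = int(radius_px)
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    d2 = xx.astype(float) ** 2 + yy.astype(float) ** 2
    footprint = d2 <= r * r
    heights = np.zeros_like(d2)
    heights[footprint] = np.sqrt(r * r - d2[footprint]) - r
    return footprint, heights


def rolling_ball_background(image: Image2D, radius_px: int) -> Image2D:
    """Estimate the smooth background by rolling a ball under the surface.

    Mathematically the rolling-ball background equals the grayscale opening
    of the intensity surface with a ball structuring element of the same
    radius; edges are handled by replicate padding.
    """
    if radius_px < 1:
        raise ValueError("radius_px must be >= 1")
    footprint, heights = _ball_structure(radius_px)
    eroded = ndi.grey_erosion(
        image.pixels, footprint=footprint, structure=heights, mode="nearest"
    )
    opened = ndi.grey_dilation(
        eroded, footprint=footprint, structure=heights, mode="nearest"
    )
    return image.with_pixels(opened)


def rolling_ball_subtract(image: Image2D, radius_px: int) -> Image2D:
    """Subtract the rolling-ball background estimate, clipping at zero.

    The output is pointwise <= the input and >= 0.  Features narrower than
    the ball scale are preserved; smooth illumination gradients and plateau
    offsets are removed.
    """
    background = rolling_ball_background(image, radius_px)
    out = np.clip(image.pixels - background.pixels, 0.0, None)
    return image.with_pixels(out)


# ---------------------------------------------------------------------------
# thresholding

N_HISTOGRAM_BINS = 256


def isodata_threshold(pixels: np.ndarray) -> float | None:
    """Intermeans (isodata) threshold on a 256-bin min-max histogram.

    Iterates ``t <- (mean(below t) + mean(above t)) / 2`` to its fixed point,
    the computation behind ImageJ's "Default" automatic threshold.  Float
    images are binned linearly between their min and max, mirroring 8-bit
    behaviour.  Returns ``None`` for a constant image, where no threshold
    separates two modes.
    """
    flat = np.asarray(pixels, dtype=float).ravel()
    lo, hi = float(flat.min()), float(flat.max())
    if lo == hi:
        return None
    counts, edges = np.histogram(flat, bins=N_HISTOGRAM_BINS, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    csum = np.cumsum(counts)
    cmass = np.cumsum(counts * centers)
    total_n, total_m = csum[-1], cmass[-1]

    t = float(flat.mean())
    for _ in range(N_HISTOGRAM_BINS):
        k = int(np.searchsorted(centers, t, side="right")) - 1
        if k < 0:
            n_below, m_below = 0, 0.0
        else:
            n_below, m_below = csum[k], cmass[k]
        n_above = total_n - n_below
        m_above = total_m - m_below
        if n_below == 0:
            t_new = m_above / n_above / 2.0 + centers[0] / 2.0
        elif n_above == 0:
            t_new = m_below / n_below / 2.0 + centers[-1] / 2.0
        else:
            t_new = 0.5 * (m_below / n_below + m_above / n_above)
        if abs(t_new - t) < 1e-12:
            break
        t = t_new
    return float(t)


def binarize(
    image: Image2D,
    method: str = "isodata_default",
    fixed_threshold: float | None = None,
) -> BinaryMask:
    """Threshold an image to a binary mask (pixels strictly above -> 1).

    ``method="isodata_default"`` computes the intermeans threshold (ImageJ
    "Default"); ``method="fixed"`` uses the supplied ``fixed_threshold``.
    A constant image under isodata yields an all-zero mask with a warning.
    """
    if method == "fixed":
        if fixed_threshold is None:
            raise ValueError("method='fixed' requires fixed_threshold")
        t = float(fixed_threshold)
    elif method == "isodata_default":
        if fixed_threshold is not None:
            raise ValueError("fixed_threshold only valid with method='fixed'")
        t = isodata_threshold(image.pixels)
        if t is None:
            warnings.warn(
                "constant image: isodata threshold undefined, returning empty mask",
                stacklevel=2,
            )
            return BinaryMask(
                np.zeros(image.shape, dtype=bool), image.pixel_size, None
            )
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    return BinaryMask(image.pixels > t, image.pixel_size, t)


# ---------------------------------------------------------------------------
# convolution filters


def sharpen(image: Image2D) -> Image2D:
    """3x3 ImageJ-style sharpen (centre 12, ring -1, divided by 4).

    Replicate padding at the edges; negative results are clipped at zero.
    """
    out = ndi.correlate(image.pixels, SHARPEN_KERNEL, mode="nearest")
    return image.with_pixels(np.clip(out, 0.0, None))


def gaussian_blur(image: Image2D, sigma_px: float) -> Image2D:
    """Isotropic Gaussian smoothing with replicate padding."""
    if sigma_px <= 0:
        raise ValueError("sigma_px must be positive")
    out = ndi.gaussian_filter(image.pixels, sigma=sigma_px, mode="nearest")
    return image.with_pixels(out)


# ---------------------------------------------------------------------------
# temporal background removal


def subtract_median_projection(stack: ImageStack) -> ImageStack:
    """Remove static background from a time-lapse by temporal-median subtraction.

    Each frame has the per-pixel median over time subtracted and is clipped
    at zero; stationary structure vanishes while transient (moving) signal
    survives in its frame.
    """
    if stack.axis_meaning != "time":
        raise ValueError("subtract_median_projection requires a time stack")
    if len(stack) < 2:
        raise ValueError("temporal median needs at least 2 frames")
    data = stack.as_array()
    median = np.median(data, axis=0)
    residual = np.clip(data - median, 0.0, None)
    slices = [stack.slices[i].with_pixels(residual[i]) for i in range(len(stack))]
    return ImageStack(slices, "time", stack.frame_interval)
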