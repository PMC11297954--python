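"""Synthetic microscopy and tracking data with attached ground truth.

Every generator is a pure function of its parameter object, including the
seed (one seed is split into independent per-channel streams, so adding a
channel never perturbs the others).  Generated samples carry the *realized*
ground-truth values (actual leak fraction after patch placement, actual
junctional enrichment, per-nucleus positivity, per-frame wound areas, drawn
fiber angles), and recovery tests compare against these realized values
rather than the nominal parameters.

What is emulated
----------------
* ``generate_monolayer`` — a confluent endothelial monolayer: seeded
  Voronoi tessellation of Poisson-disk cell centres; the junction band is
  the tessellation edge set dilated to a physical width and warped by a
  smooth random displacement field (the "jaggedness" of remodelling
  junctions); VE-Cadherin marks the band; N-Cadherin adds a punctate
  cytoplasmic pool with junctional enrichment; one elliptical nucleus per
  cell; YAP partitions between nucleus and cytoplasm at a controllable
  ratio; a marker channel is bright in a random subset of nuclei; the
  streptavidin channel carries junction-adjacent leak patches; Poisson shot
  noise plus Gaussian read noise last.
* ``generate_fiber_patch`` — straight fibers with axial von Mises
  orientations (period 180 deg) around a set angle.
* ``generate_tracks`` — persistent random walks with wrapped-normal
  turning.
* ``generate_wound_series`` — a textured monolayer with a smooth central
  wound band closing linearly in time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from skimage.draw import line_aa

from .imgproc import BinaryMask, Image2D, ImageStack
from .motility import Track
from .nuclei_quant import LabelMask
from .orientation import BIN_EDGES_DEG

__all__ = [
    "MonolayerParams",
    "GroundTruth",
    "MonolayerSample",
    "generate_monolayer",
    "generate_fiber_patch",
    "generate_tracks",
    "generate_wound_series",
]


# ---------------------------------------------------------------------------
# parameters and ground truth


@dataclass
class MonolayerParams:
    """Generation parameters for one synthetic monolayer field.

    Intensities are arbitrary fluorescence units; the defaults give a
    high-SNR field of ~60 cells in a 256-px field at 0.5 um/px.
    """

    field_size_px: int = 256
    pixel_size_um: float = 0.5
    n_cells: int = 60
    junction_width_um: float = 1.5
    junction_jaggedness: float = 0.0  # displacement amplitude, um
    vecad_junction_intensity: float = 100.0
    ncad_interior_intensity: float = 40.0
    ncad_enrichment: float = 2.0  # junction / interior mean intensity
    yap_cytoplasm_intensity: float = 50.0
    yap_nc_ratio: float = 2.0  # nuclear / cytoplasmic intensity
    nucleus_axes_um: tuple[float, float] = (7.0, 5.0)
    marker_positive_fraction: float = 0.2
    marker_intensity: tuple[float, float] = (10.0, 100.0)  # dim, bright
    leak_fraction: float = 0.05
    leak_intensity: float = 120.0
    leak_patch_radius_um: float = 1.5
    gaussian_sigma: float = 2.0
    poisson_scale: float = 0.0  # 0 disables shot noise
    seed: int = 0

    def validate(self) -> None:
        if self.field_size_px < 32:
            raise ValueError("field_size_px must be >= 32")
        for name in ("pixel_size_um", "junction_width_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.junction_jaggedness < 0:
            raise ValueError("junction_jaggedness must be >= 0")
        if self.ncad_enrichment < 1:
            raise ValueError("ncad_enrichment must be >= 1")
        if self.yap_nc_ratio <= 0:
            raise ValueError("yap_nc_ratio must be > 0")
        if not (0 <= self.marker_positive_fraction <= 1):
            raise ValueError("marker_positive_fraction must be in [0, 1]")
        if not (0 <= self.leak_fraction <= 1):
            raise ValueError("leak_fraction must be in [0, 1]")
        # nuclei must fit inside cells
        field_um = self.field_size_px * self.pixel_size_um
        cell_radius_um = field_um / math.sqrt(math.pi * self.n_cells)
        if max(self.nucleus_axes_um) / 2 >= cell_radius_um:
            raise ValueError(
                "nuclei larger than cells: reduce nucleus_axes_um or n_cells"
            )


@dataclass
class GroundTruth:
    """True masks and realized parameter values of a synthetic sample."""

    junction_skeleton: BinaryMask
    junction_band: BinaryMask
    nuclei: LabelMask
    true_values: dict = field(default_factory=dict)


@dataclass
class MonolayerSample:
    """Generated multichannel field: channel-role -> Image2D, plus truth."""

    channels: dict
    ground_truth: GroundTruth

    def __getitem__(self, role: str) -> Image2D:
        return self.channels[role]


# ---------------------------------------------------------------------------
# helpers


def _poisson_disk_centers(
    n: int, size: float, rng: np.random.Generator
) -> np.ndarray:
    """Dart-throwing blue-noise centres: n points with a soft minimum spacing."""
    min_dist = 0.7 * size / math.sqrt(n)
    pts: list[np.ndarray] = []
    attempts = 0
    while len(pts) < n and attempts < 20000:
        cand = rng.uniform(0, size, 2)
        if not pts or np.min(
            np.hypot(*(np.asarray(pts) - cand).T)
        ) >= min_dist:
            pts.append(cand)
        attempts += 1
    while len(pts) < n:  # degenerate fallback: pure uniform
        pts.append(rng.uniform(0, size, 2))
    return np.array(pts)


def _displacement_field(
    shape: tuple[int, int],
    amplitude_px: float,
    smoothness_px: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Smooth random warp with the requested RMS amplitude (in px)."""
    if amplitude_px == 0:
        zero = np.zeros(shape)
        return zero, zero
    out = []
    for _ in range(2):
        f = ndi.gaussian_filter(rng.standard_normal(shape), smoothness_px)
        rms = float(np.sqrt(np.mean(f**2)))
        out.append(f * (amplitude_px / rms) if rms > 0 else f)
    return out[0], out[1]


def _apply_noise(
    pixels: np.ndarray,
    gaussian_sigma: float,
    poisson_scale: float,
    rng: np.random.Generator,
) -> np.ndarray:
    out = pixels.astype(float)
    if poisson_scale > 0:
        out = rng.poisson(out * poisson_scale) / poisson_scale
    if gaussian_sigma > 0:
        out = out + rng.normal(0.0, gaussian_sigma, out.shape)
    return np.clip(out, 0.0, None)


def _channel_rngs(seed: int, names: list[str]) -> dict[str, np.random.Generator]:
    """Split one seed into an independent stream per channel."""
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(s) for n, s in zip(names, children)}


# ---------------------------------------------------------------------------
# monolayer


def generate_monolayer(params: MonolayerParams) -> MonolayerSample:
    """Generate one multichannel monolayer field with ground truth.

    See the module docstring for the construction.  Channel roles present:
    VE-Cadherin, N-Cadherin, YAP, DAPI, streptavidin and a Ki-67/EdU-style
    marker stored under the role ``other``.
    """
    params.validate()
    size = params.field_size_px
    px = params.pixel_size_um
    rngs = _channel_rngs(
        params.seed,
        ["geometry", "jaggedness", "ncad", "marker", "leak",
         "noise_vecad", "noise_ncad", "noise_yap", "noise_dapi",
         "noise_marker", "noise_strep"],
    )

    centers = _poisson_disk_centers(params.n_cells, float(size), rngs["geometry"])

    rows, cols = np.mgrid[0:size, 0:size].astype(float)
    dx, dy = _displacement_field(
        (size, size),
        params.junction_jaggedness / px,
        smoothness_px=8.0,
        rng=rngs["jaggedness"],
    )
    warped = np.column_stack([(cols + dx).ravel(), (rows + dy).ravel()])

    tree = cKDTree(centers)
    dists, owners = tree.query(warped, k=2)
    d1 = dists[:, 0].reshape(size, size)
    d2 = dists[:, 1].reshape(size, size)
    cell_of = owners[:, 0].reshape(size, size)  # Voronoi cell index per pixel

    width_px = params.junction_width_um / px
    band = (d2 - d1) <= width_px
    skeleton = (d2 - d1) <= 1.0

    # nuclei: one ellipse per cell centre, random axial orientation
    labels = np.zeros((size, size), dtype=np.int32)
    a_px = params.nucleus_axes_um[0] / (2 * px)
    b_px = params.nucleus_axes_um[1] / (2 * px)
    geom_rng = rngs["geometry"]
    nucleus_ids = []
    for k, (cx, cy) in enumerate(centers, start=1):
        phi = geom_rng.uniform(0, math.pi)
        u = (cols - cx) * math.cos(phi) + (rows - cy) * math.sin(phi)
        v = -(cols - cx) * math.sin(phi) + (rows - cy) * math.cos(phi)
        inside = (u / a_px) ** 2 + (v / b_px) ** 2 <= 1.0
        inside &= cell_of == (k - 1)  # clip to the owning cell
        if inside.any():
            labels[inside] = k
            nucleus_ids.append(k)

    # --- channels (noise-free first, realized truths measured on these) ---
    vecad = np.where(band, params.vecad_junction_intensity, 0.0)

    # punctate cytoplasmic N-Cadherin pool: granules with true zero gaps so
    # rolling-ball background removal preserves the interior mean
    granules = rngs["ncad"].random((size, size)) < 0.15
    granules = ndi.binary_dilation(granules, structure=np.ones((2, 2)))
    coverage = float(granules.mean())
    interior = np.where(granules, params.ncad_interior_intensity / coverage, 0.0)
    junction_level = params.ncad_enrichment * params.ncad_interior_intensity
    ncad = np.where(band, junction_level, interior)
    realized_enrichment = float(ncad[band].mean() / ncad[~band].mean())

    nuclear_mask = labels > 0
    yap = np.where(
        nuclear_mask,
        params.yap_nc_ratio * params.yap_cytoplasm_intensity,
        params.yap_cytoplasm_intensity,
    )

    dapi = np.where(nuclear_mask, 100.0, 0.0)

    n_nuc = len(nucleus_ids)
    n_pos = int(round(params.marker_positive_fraction * n_nuc))
    pos_ids = set(
        rngs["marker"].choice(nucleus_ids, size=n_pos, replace=False).tolist()
    ) if n_pos else set()
    dim, bright = params.marker_intensity
    marker = np.where(nuclear_mask, dim, 0.0)
    for k in pos_ids:
        marker[labels == k] = bright
    realized_marker_fraction = n_pos / n_nuc if n_nuc else 0.0

    # leak patches: disks seeded on junction pixels, non-overlapping,
    # placed until the next disk would overshoot the target fraction
    strep = np.zeros((size, size))
    leak_mask = np.zeros((size, size), dtype=bool)
    target_px = params.leak_fraction * size * size
    r_px = max(1, int(round(params.leak_patch_radius_um / px)))
    band_idx = np.column_stack(np.nonzero(band))
    leak_rng = rngs["leak"]
    if len(band_idx) and target_px >= 1:
        patch = disk_fp = None
        yy, xx = np.mgrid[-r_px:r_px + 1, -r_px:r_px + 1]
        disk_fp = (xx**2 + yy**2) <= r_px**2
        patch_area = int(disk_fp.sum())
        for _ in range(20000):
            if leak_mask.sum() + patch_area > target_px + patch_area / 2:
                break
            r, c = band_idx[leak_rng.integers(len(band_idx))]
            r0, r1 = r - r_px, r + r_px + 1
            if r0 < 0 or c - r_px < 0 or r1 > size or c + r_px + 1 > size:
                continue
            window = (slice(r0, r1), slice(c - r_px, c + r_px + 1))
            if (leak_mask[window] & disk_fp).any():
                continue
            leak_mask[window] |= disk_fp
        strep[leak_mask] = params.leak_intensity
    realized_leak_fraction = float(leak_mask.mean())

    def make(pixels: np.ndarray, role: str, noise_key: str) -> Image2D:
        noisy = _apply_noise(
            pixels, params.gaussian_sigma, params.poisson_scale, rngs[noise_key]
        )
        return Image2D(noisy, px, role)

    channels = {
        "VE-Cadherin": make(vecad, "VE-Cadherin", "noise_vecad"),
        "N-Cadherin": make(ncad, "N-Cadherin", "noise_ncad"),
        "YAP": make(yap, "YAP", "noise_yap"),
        "DAPI": make(dapi, "DAPI", "noise_dapi"),
        "marker": make(marker, "other", "noise_marker"),
        "streptavidin": make(strep, "streptavidin", "noise_strep"),
    }

    truth = GroundTruth(
        junction_skeleton=BinaryMask(skeleton, px),
        junction_band=BinaryMask(band, px),
        nuclei=LabelMask(labels, px),
        true_values={
            "centers_xy": centers,
            "n_nuclei": n_nuc,
            "ncad_enrichment": realized_enrichment,
            "yap_nc_ratio": params.yap_nc_ratio,
            "marker_positive_fraction": realized_marker_fraction,
            "marker_positive_ids": sorted(pos_ids),
            "leak_fraction": realized_leak_fraction,
            "nominal": params,
        },
    )
    return MonolayerSample(channels, truth)


# ---------------------------------------------------------------------------
# fiber patches


def _axial_von_mises(
    mean_deg: float, kappa: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Axial (period-180) von Mises angles in degrees within [-90, 90).

    ``kappa = 0`` is the isotropic limit; kappa >= 1e4 is treated as the
    degenerate limit (every angle exactly at the mean).
    """
    if kappa <= 0:
        ang = rng.uniform(-90.0, 90.0, n)
    elif kappa >= 1e4:
        ang = np.full(n, float(mean_deg))
    else:
        two_theta = rng.vonmises(0.0, kappa, n)
        ang = np.degrees(two_theta) / 2.0 + mean_deg
    return (ang + 90.0) % 180.0 - 90.0


def analytic_axial_vm_histogram(mean_deg: float, kappa: float) -> np.ndarray:
    """Exact 18-bin mass of the axial von Mises density (for oracles)."""
    if kappa <= 0:
        return np.full(18, 1.0 / 18.0)
    from scipy.integrate import quad
    from scipy.special import i0

    def dens(theta_deg: float) -> float:
        d = np.radians(2 * (theta_deg - mean_deg))
        return math.exp(kappa * math.cos(d)) / (180.0 * i0(kappa))

    masses = []
    for lo, hi in zip(BIN_EDGES_DEG[:-1], BIN_EDGES_DEG[1:]):
        masses.append(quad(dens, lo, hi, limit=200)[0])
    m = np.array(masses)
    return m / m.sum()


def generate_fiber_patch(
    angle_deg: float,
    kappa: float,
    n_fibers: int = 150,
    size_px: int = 128,
    intensity: float = 100.0,
    noise_sigma: float = 0.0,
    psf_sigma_px: float = 1.0,
    seed: int = 0,
) -> tuple[Image2D, dict]:
    """Straight-fiber field with axial von Mises orientations.

    Angles are measured counterclockwise from +x with y up (the orientation
    module's convention).  ``kappa = 0`` gives isotropy; large kappa
    concentrates all fibers at ``angle_deg``.  Returns the image and a
    ground-truth dict holding the drawn angles and the analytic 18-bin
    density.
    """
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    angles = _axial_von_mises(angle_deg, kappa, n_fibers, rng)
    img = np.zeros((size_px, size_px))
    half_len = size_px * 0.4
    for ang in angles:
        cx, cy = rng.uniform(0.1 * size_px, 0.9 * size_px, 2)
        a = math.radians(ang)
        dx, dy = math.cos(a) * half_len, -math.sin(a) * half_len  # y-up
        # shorten symmetrically along the fiber so it fits the patch;
        # clipping endpoints independently would change the drawn angle
        t = 1.0
        for centre, delta in ((cy, dy), (cx, dx)):
            if delta != 0:
                t = min(
                    t,
                    abs((size_px - 1 - centre) / delta),
                    abs(centre / delta),
                )
        r0, c0 = int(round(cy - t * dy)), int(round(cx - t * dx))
        r1, c1 = int(round(cy + t * dy)), int(round(cx + t * dx))
        rr, cc, val = line_aa(r0, c0, r1, c1)
        img[rr, cc] = np.maximum(img[rr, cc], val * intensity)
    if psf_sigma_px > 0:
        # diffraction-limited optics: without this the raster stair-steps of
        # the drawn lines alias into spurious orientations
        img = ndi.gaussian_filter(img, psf_sigma_px, mode="nearest")
    if noise_sigma > 0:
        img = np.clip(img + rng.normal(0, noise_sigma, img.shape), 0, None)
    truth = {
        "angle_deg": angle_deg,
        "kappa": kappa,
        "drawn_angles_deg": angles,
        "analytic_histogram": analytic_axial_vm_histogram(angle_deg, kappa),
    }
    return Image2D(img, 1.0, "actin"), truth


def generate_stripe_patch(
    angle_deg: float,
    size_px: int = 128,
    period_px: float = 8.0,
    intensity: float = 100.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> Image2D:
    """Sinusoidal stripes at a known angle (sharpest orientation target)."""
    rows, cols = np.mgrid[0:size_px, 0:size_px].astype(float)
    a = math.radians(angle_deg)
    # phase varies along the stripe normal; y up means y = -row
    phase = (-cols * math.sin(a) - rows * math.cos(a)) * 2 * math.pi / period_px
    img = intensity * 0.5 * (1.0 + np.cos(phase))
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        img = np.clip(img + rng.normal(0, noise_sigma, img.shape), 0, None)
    return Image2D(img, 1.0, "actin")


# ---------------------------------------------------------------------------
# tracks


def generate_tracks(
    n_tracks: int,
    n_steps: int,
    speed_um_min: float = 0.5,
    persistence: float = 0.5,
    frame_interval_min: float = 10.0,
    seed: int = 0,
    origin_context: str = "monolayer",
) -> tuple[list[Track], dict]:
    """Persistent (correlated) random-walk tracks.

    Step length is ``speed * frame_interval``; headings evolve by
    wrapped-normal turns with standard deviation ``pi * (1 - persistence)``
    so persistence 0 is an (effectively) isotropic walk and persistence -> 1
    a straight line.  Persistence >= 1 is capped to exactly straight tracks.
    """
    if n_tracks < 1 or n_steps < 1:
        raise ValueError("need n_tracks >= 1 and n_steps >= 1")
    if speed_um_min <= 0 or frame_interval_min <= 0:
        raise ValueError("speed and frame interval must be positive")
    if persistence < 0:
        raise ValueError("persistence must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    step = speed_um_min * frame_interval_min
    turn_sigma = 0.0 if persistence >= 1 else math.pi * (1.0 - persistence)

    headings = np.empty((n_tracks, n_steps))
    headings[:, 0] = rng.uniform(0, 2 * math.pi, n_tracks)
    if turn_sigma > 0:
        turns = rng.normal(0.0, turn_sigma, (n_tracks, n_steps - 1))
        headings[:, 1:] = headings[:, :1] + np.cumsum(turns, axis=1)
    else:
        headings[:, 1:] = headings[:, :1]

    x = np.concatenate(
        [np.zeros((n_tracks, 1)), np.cumsum(step * np.cos(headings), axis=1)], axis=1
    )
    y = np.concatenate(
        [np.zeros((n_tracks, 1)), np.cumsum(step * np.sin(headings), axis=1)], axis=1
    )
    t = np.arange(n_steps + 1, dtype=float) * frame_interval_min
    tracks = [
        Track(i, t, x[i], y[i], origin_context) for i in range(n_tracks)
    ]
    truth = {
        "speed_um_min": speed_um_min,
        "persistence": persistence,
        "step_um": step,
        "turn_sigma_rad": turn_sigma,
    }
    return tracks, truth


# ---------------------------------------------------------------------------
# wound series


def generate_wound_series(
    field_size_px: tuple[int, int] = (128, 512),
    pixel_size_um: float = 1.0,
    wound_half_width_um: float = 128.0,
    closure_speed_um_min: float = 1.0,
    n_frames: int = 20,
    frame_interval_min: float = 10.0,
    cell_texture_sigma: float = 20.0,
    cell_baseline: float = 100.0,
    wound_level: float = 100.0,
    seed: int = 0,
) -> tuple[ImageStack, dict]:
    """Brightfield-like wound-healing time lapse with linear closure.

    The wound is a vertical smooth band centred in the field whose
    half-width shrinks at ``closure_speed_um_min`` per edge; the monolayer
    region carries per-frame speckle (temporal texture) on a static
    baseline.  True per-frame wound areas (um^2) are recorded; frames after
    full closure have area 0.
    """
    h, w = field_size_px
    if 2 * wound_half_width_um >= w * pixel_size_um:
        raise ValueError("wound wider than the field")
    if closure_speed_um_min < 0:
        raise ValueError("closure speed must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    cx_um = w * pixel_size_um / 2.0
    cols_um = (np.arange(w) + 0.5) * pixel_size_um

    slices = []
    true_areas = []
    for i in range(n_frames):
        t = i * frame_interval_min
        half = max(wound_half_width_um - closure_speed_um_min * t, 0.0)
        in_wound = np.abs(cols_um - cx_um) <= half
        frame = np.empty((h, w))
        # monolayer: static baseline + per-frame speckle (temporal texture)
        frame[:, :] = cell_baseline + rng.normal(0, cell_texture_sigma, (h, w))
        frame[:, in_wound] = wound_level
        slices.append(Image2D(np.clip(frame, 0, None), pixel_size_um, "brightfield"))
        # analytic truth from the continuous geometry, not the pixel grid
        true_areas.append(2.0 * half * h * pixel_size_um)
    stack = ImageStack(slices, "time", frame_interval_min)
    truth = {
        "areas_um2": np.array(true_areas),
        "times_min": np.arange(n_frames, dtype=float) * frame_interval_min,
        "closure_rate_um2_per_min": -2.0 * closure_speed_um_min * h * pixel_size_um,
    }
    return stack, truth
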