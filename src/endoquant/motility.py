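"""Trajectory metrics and wound-closure dynamics.

Tracks (nuclear positions over time, e.g. TrackMate exports) are summarized
per cell by

* path length — sum of Euclidean step lengths over every recorded time
  step,
* net displacement — distance between first and last position,
* directionality index (DI) — path length / net displacement, 1 for
  perfectly straight motion and larger the more a cell meanders,
* signed axis displacements dx, dy (x is taken perpendicular to the wound
  edge — the closure direction — and y parallel to it; rotate inputs to
  this frame upstream if needed).

Wound closure is measured on brightfield time-lapse stacks: the per-pixel
temporal median is subtracted to remove static background, a local-texture
map flags cell-covered (high-variance) regions, an isodata threshold on the
texture separates the smooth wound, and the largest connected low-texture
region is the wound whose area is tracked per frame; the closure rate is
the least-squares slope of area versus time.
"""

from __future__ import annotations

import math
import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .imgproc import ImageStack, isodata_threshold, subtract_median_projection

__all__ = [
    "Track",
    "TrackMetrics",
    "WoundSeries",
    "parse_tracks",
    "write_tracks_csv",
    "track_metrics",
    "directionality_by_group",
    "wound_area_series",
]


@dataclass
class Track:
    """One cell's time-ordered positions (t in minutes, x/y in um)."""

    track_id: str | int
    t_min: np.ndarray
    x_um: np.ndarray
    y_um: np.ndarray
    origin_context: str = "monolayer"

    def __post_init__(self) -> None:
        self.t_min = np.asarray(self.t_min, dtype=float)
        self.x_um = np.asarray(self.x_um, dtype=float)
        self.y_um = np.asarray(self.y_um, dtype=float)
        n = len(self.t_min)
        if n < 2 or len(self.x_um) != n or len(self.y_um) != n:
            raise ValueError("Track needs >= 2 points with equal-length t/x/y")
        if np.any(np.diff(self.t_min) <= 0):
            raise ValueError("Track times must be strictly increasing")
        if self.origin_context not in ("monolayer", "wound_edge"):
            raise ValueError("origin_context must be 'monolayer' or 'wound_edge'")

    def __len__(self) -> int:
        return len(self.t_min)


@dataclass
class TrackMetrics:
    """Scalar summary of one track; DI is NaN for zero net displacement."""

    track_id: str | int
    path_length_um: float
    net_displacement_um: float
    directionality_index: float
    dx_um: float
    dy_um: float


@dataclass
class WoundSeries:
    """Per-frame wound areas and the fitted linear closure rate."""

    times_min: np.ndarray
    areas_um2: np.ndarray
    closure_rate_um2_per_min: float

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.areas_um2 = np.asarray(self.areas_um2, dtype=float)
        if len(self.times_min) != len(self.areas_um2):
            raise ValueError("times and areas must have equal length")
        if np.any(self.areas_um2 < 0):
            raise ValueError("areas must be non-negative")


# ---------------------------------------------------------------------------
# track I/O

_CSV_COLUMN_ALIASES = {
    "track_id": ("track_id", "track-id", "TRACK_ID"),
    "frame": ("frame", "FRAME", "t"),
    "x": ("x_px", "x", "POSITION_X"),
    "y": ("y_px", "y", "POSITION_Y"),
}


def _resolve_columns(df: pd.DataFrame) -> dict[str, str]:
    resolved = {}
    missing = []
    for key, aliases in _CSV_COLUMN_ALIASES.items():
        for a in aliases:
            if a in df.columns:
                resolved[key] = a
                break
        else:
            missing.append(f"{key} (any of {', '.join(aliases)})")
    if missing:
        raise ValueError("track CSV missing required columns: " + "; ".join(missing))
    return resolved


def parse_tracks(
    path: str | Path,
    dialect: str = "csv",
    pixel_size: float = 1.0,
    frame_interval: float = 1.0,
    origin_context: str = "monolayer",
) -> list[Track]:
    """Read tracks from a CSV or TrackMate-style XML file.

    Positions are converted to micrometres via ``pixel_size`` and frames to
    minutes via ``frame_interval``.  Tracks with fewer than two points are
    dropped (logged via a warning with the count).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "csv":
        df = pd.read_csv(path)
        cols = _resolve_columns(df)
        groups = df.groupby(cols["track_id"], sort=True)
        raw = [
            (
                tid,
                g.sort_values(cols["frame"])[cols["frame"]].to_numpy(float),
                g.sort_values(cols["frame"])[cols["x"]].to_numpy(float),
                g.sort_values(cols["frame"])[cols["y"]].to_numpy(float),
            )
            for tid, g in groups
        ]
    elif dialect == "trackmate_xml":
        root = ET.parse(path).getroot()
        raw = []
        for particle in root.iter("particle"):
            tid = particle.get("id", len(raw))
            pts = [
                (float(d.get("t")), float(d.get("x")), float(d.get("y")))
                for d in particle.iter("detection")
            ]
            pts.sort()
            arr = np.array(pts, dtype=float).reshape(-1, 3)
            raw.append((tid, arr[:, 0], arr[:, 1], arr[:, 2]))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    tracks: list[Track] = []
    n_dropped = 0
    for tid, frames, xs, ys in raw:
        if len(frames) < 2:
            n_dropped += 1
            continue
        tracks.append(
            Track(
                track_id=tid,
                t_min=frames * frame_interval,
                x_um=xs * pixel_size,
                y_um=ys * pixel_size,
                origin_context=origin_context,
            )
        )
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} track(s) with < 2 points", stacklevel=2)
    return tracks


def write_tracks_csv(
    tracks: list[Track],
    path: str | Path,
    pixel_size: float = 1.0,
    frame_interval: float = 1.0,
) -> None:
    """Write tracks in the CSV dialect read by :func:`parse_tracks`."""
    rows = []
    for tr in tracks:
        for t, x, y in zip(tr.t_min, tr.x_um, tr.y_um):
            rows.append(
                {
                    "track_id": tr.track_id,
                    "frame": t / frame_interval,
                    "x_px": x / pixel_size,
                    "y_px": y / pixel_size,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# metrics


def track_metrics(track: Track, stride: int = 1) -> TrackMetrics:
    """Path length, net displacement, DI and axis displacements of a track.

    ``stride`` subsamples the time steps for sensitivity analysis; the
    default 1 uses every recorded step.  DI = path / net; a track returning
    exactly to its start has undefined (NaN) DI while the other metrics are
    still reported.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    x = track.x_um[::stride]
    y = track.y_um[::stride]
    if len(x) < 2 or x[-1] != track.x_um[-1]:
        # always include the final position so net displacement is exact
        x = np.append(x, track.x_um[-1])
        y = np.append(y, track.y_um[-1])
    steps = np.hypot(np.diff(x), np.diff(y))
    path = float(steps.sum())
    dx = float(track.x_um[-1] - track.x_um[0])
    dy = float(track.y_um[-1] - track.y_um[0])
    net = math.hypot(dx, dy)
    di = path / net if net > 0 else math.nan
    return TrackMetrics(track.track_id, path, net, di, dx, dy)


def directionality_by_group(
    tracks: list[Track],
    group_labels: list,
    stride: int = 1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group summary (median, quartiles, n) of DI and displacements.

    Returns ``(summary, per_track)`` data frames; groups with no tracks are
    omitted with a warning.  NaN DIs (zero net displacement) are excluded
    from the DI summary but their tracks still contribute displacement
    statistics.
    """
    if len(tracks) != len(group_labels):
        raise ValueError("one group label per track required")
    if not tracks:
        raise ValueError("no tracks supplied")
    rows = []
    for tr, grp in zip(tracks, group_labels):
        m = track_metrics(tr, stride)
        rows.append(
            {
                "group": grp,
                "track_id": m.track_id,
                "path_length_um": m.path_length_um,
                "net_displacement_um": m.net_displacement_um,
                "directionality_index": m.directionality_index,
                "dx_um": m.dx_um,
                "dy_um": m.dy_um,
            }
        )
    per_track = pd.DataFrame(rows)
    summaries = []
    for grp, g in per_track.groupby("group", sort=True):
        entry = {"group": grp, "n_tracks": len(g)}
        for col in (
            "directionality_index",
            "net_displacement_um",
            "path_length_um",
            "dx_um",
            "dy_um",
        ):
            vals = g[col].dropna()
            entry[f"{col}_median"] = vals.median() if len(vals) else math.nan
            entry[f"{col}_q1"] = vals.quantile(0.25) if len(vals) else math.nan
            entry[f"{col}_q3"] = vals.quantile(0.75) if len(vals) else math.nan
        summaries.append(entry)
    return pd.DataFrame(summaries), per_track


# ---------------------------------------------------------------------------
# wound closure


def _local_variance(pixels: np.ndarray, window_px: int) -> np.ndarray:
    mean = ndi.uniform_filter(pixels, size=window_px, mode="nearest")
    mean_sq = ndi.uniform_filter(pixels**2, size=window_px, mode="nearest")
    return np.clip(mean_sq - mean**2, 0.0, None)


def wound_area_series(
    stack: ImageStack,
    texture_window_px: int = 3,
    smooth_sigma_px: float = 2.0,
    min_contrast: float = 0.5,
) -> WoundSeries:
    """Wound area per frame and the fitted linear closure rate.

    Per frame, after temporal-median background removal, a local-variance
    texture map is thresholded (isodata); the wound is the largest connected
    low-texture region.  The variance profile crosses its midpoint at the
    cell/wound boundary, which keeps the edge localization unbiased.  If the
    mean texture inside the candidate wound exceeds ``min_contrast`` times
    the mean outside (no real smooth region, e.g. a confluent field), the
    frame's area is 0 with a warning.  The closure rate is the least-squares
    slope of area versus time (negative while the wound closes).
    """
    if stack.axis_meaning != "time":
        raise ValueError("wound_area_series requires a time stack")
    cleaned = subtract_median_projection(stack)
    px = stack.pixel_size
    times = np.arange(len(stack), dtype=float) * stack.frame_interval
    areas = np.zeros(len(stack))
    textures = []
    for frame in cleaned.slices:
        tex = _local_variance(frame.pixels, texture_window_px)
        if smooth_sigma_px > 0:
            # symmetric smoothing suppresses speckle in the variance map
            # without shifting the midpoint crossing at the wound edge
            tex = ndi.gaussian_filter(tex, smooth_sigma_px, mode="nearest")
        textures.append(tex)
    # one movie-wide threshold: pooling all frames keeps the wound/monolayer
    # split well-defined even in frames where the wound has become small
    t = isodata_threshold(np.stack(textures))
    if t is None:
        warnings.warn("flat texture maps: wound areas set to 0", stacklevel=2)
        return WoundSeries(times, areas, 0.0)
    for i, tex in enumerate(textures):
        low = tex <= t
        if not low.any() or low.all():
            continue
        labels, n = ndi.label(low)
        if n == 0:
            continue
        sizes = ndi.sum_labels(low, labels, index=np.arange(1, n + 1))
        wound = labels == (int(np.argmax(sizes)) + 1)
        mean_in = float(tex[wound].mean())
        mean_out = float(tex[~wound].mean()) if (~wound).any() else 0.0
        if mean_out > 0 and mean_in > min_contrast * mean_out:
            warnings.warn(
                f"frame {i}: no low-texture region distinct from the "
                "monolayer, wound area set to 0",
                stacklevel=2,
            )
            continue
        areas[i] = float(wound.sum()) * px**2
    if len(times) >= 2 and np.ptp(times) > 0:
        slope = float(np.polyfit(times, areas, 1)[0])
    else:
        slope = math.nan
    return WoundSeries(times, areas, slope)
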