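"""Retinotopic map quality metrics: tilt, phase scatter, magnification.

Map tilt is the acute angle between the cortical representation of the
monitor's central (zero visual-angle) line and a reference axis on the
cortex: the mediolateral axis (image columns) for elevation maps, the
anteroposterior axis (image rows) for azimuth maps.

Phase scatter is the standard deviation of per-pixel deviations from the
mean of a circular neighborhood (radius 2.9 pixels, a full 5 x 5 footprint,
center included) over the highest-amplitude pixels (at most 20,000).
It is computed on the visual-angle field in visual degrees with plain
arithmetic means — after delay cancellation and angle conversion the values
stay far from the wrap boundary, so no circular statistics are needed.

The magnification factor is the visual angle spanned per millimeter of
cortex, measured between the sub-pixel positions where the map attains
-span/2 and +span/2 degrees (default span 10) along the steepest-ascent
line perpendicular to the zero-level line through its centroid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .retinotopy import AbsoluteRetinotopicMap

__all__ = [
    "MapMetrics",
    "circular_footprint",
    "compute_map_tilt",
    "compute_phase_scatter",
    "compute_magnification",
    "compute_map_metrics",
]


@dataclass
class MapMetrics:
    """The three retinotopy measurements for one absolute map."""

    axis: str
    tilt_deg: float
    scatter_sd: float
    magnification_deg_per_mm: float
    n_pixels_used: int

    def to_dict(self) -> dict:
        return {
            "axis": self.axis,
            "tilt_deg": float(self.tilt_deg),
            "scatter_sd": float(self.scatter_sd),
            "magnification_deg_per_mm": float(self.magnification_deg_per_mm),
            "n_pixels_used": int(self.n_pixels_used),
        }


def circular_footprint(radius: float = 2.9) -> np.ndarray:
    """Boolean mask of integer offsets within Euclidean ``radius`` of 0.

    Radius 2.9 admits every offset of the 5 x 5 square (corner distance
    2*sqrt(2) ~ 2.83), i.e. a 25-pixel footprint including the center.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    r = int(math.floor(radius))
    dr, dc = np.meshgrid(np.arange(-r, r + 1), np.arange(-r, r + 1), indexing="ij")
    return dr**2 + dc**2 <= radius**2


def _default_roi(amap: AbsoluteRetinotopicMap) -> np.ndarray:
    # Responsive region: pixels at >= half the maximum response amplitude.
    amp = amap.amplitude
    if amp.max() <= 0:
        raise ValueError("map has no response amplitude; supply an ROI")
    return amp >= 0.5 * amp.max()


def _fit_zero_line(
    amap: AbsoluteRetinotopicMap, roi: np.ndarray, rel_threshold: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Total-least-squares fit of the zero-visual-angle line inside the ROI.

    Returns (centroid (r, c), unit line direction, unit steepest-ascent
    direction).  Pixels with |visual_angle| within ``rel_threshold`` of the
    ROI's angle range define the zero band; its principal axis is the line.
    """
    v = amap.visual_angle
    vals = v[roi]
    if vals.size == 0:
        raise ValueError("ROI is empty")
    if vals.min() > 0 or vals.max() < 0:
        raise ValueError("zero-phase line absent: no sign change inside the ROI")
    vrange = float(vals.max() - vals.min())
    band = roi & (np.abs(v) <= rel_threshold * vrange)
    coords = np.column_stack(np.nonzero(band)).astype(float)
    if coords.shape[0] < 2:
        raise ValueError("zero-phase band too small to fit a line")
    centroid = coords.mean(axis=0)
    _, _, vt = np.linalg.svd(coords - centroid, full_matrices=False)
    line_dir = vt[0]
    # Steepest ascent is perpendicular to the zero line; orient it toward
    # increasing visual angle using a least-squares plane fit over the ROI.
    perp = np.array([-line_dir[1], line_dir[0]])
    rr, cc = np.nonzero(roi)
    design = np.column_stack([np.ones(rr.size), rr, cc])
    beta, *_ = np.linalg.lstsq(design, v[roi], rcond=None)
    grad = beta[1:]
    if grad @ perp < 0:
        perp = -perp
    return centroid, line_dir, perp


def compute_map_tilt(
    amap: AbsoluteRetinotopicMap,
    roi: np.ndarray | None = None,
    rel_threshold: float = 0.02,
) -> float:
    """Acute angle (degrees, in [0, 90]) of the zero-level line vs the
    reference axis: mediolateral (columns) for elevation maps,
    anteroposterior (rows) for azimuth maps."""
    roi = _default_roi(amap) if roi is None else np.asarray(roi, dtype=bool)
    _, line_dir, _ = _fit_zero_line(amap, roi, rel_threshold)
    ref = np.array([0.0, 1.0]) if amap.axis == "elevation" else np.array([1.0, 0.0])
    cos_angle = abs(float(line_dir @ ref)) / float(np.linalg.norm(line_dir))
    return math.degrees(math.acos(min(cos_angle, 1.0)))


def compute_phase_scatter(
    amap: AbsoluteRetinotopicMap,
    roi: np.ndarray | None = None,
    radius: float = 2.9,
    max_pixels: int = 20000,
) -> tuple[float, int]:
    """SD of pixel-minus-neighborhood-mean deviations over the strongest pixels.

    Center pixels are the at most ``max_pixels`` highest-amplitude ROI pixels
    whose full footprint lies inside the map (ties at the cutoff broken by
    row-major order).  Returns ``(scatter_sd, n_pixels_used)``; the SD is the
    population standard deviation, in visual degrees.
    """
    roi = _default_roi(amap) if roi is None else np.asarray(roi, dtype=bool)
    fp = circular_footprint(radius)
    r = fp.shape[0] // 2
    nr, nc = amap.visual_angle.shape

    interior = np.zeros((nr, nc), dtype=bool)
    if nr > 2 * r and nc > 2 * r:
        interior[r : nr - r, r : nc - r] = True
    candidates = roi & interior
    if not candidates.any():
        raise ValueError("ROI smaller than one footprint")

    neigh_mean = ndimage.correlate(
        amap.visual_angle, fp.astype(float) / fp.sum(), mode="constant"
    )
    deviation = amap.visual_angle - neigh_mean

    flat = np.flatnonzero(candidates)
    amp = amap.amplitude.ravel()[flat]
    # Highest amplitude first; ties broken by row-major (flat) index.
    order = np.lexsort((flat, -amp))
    chosen = flat[order[:max_pixels]]
    dev = deviation.ravel()[chosen]
    return float(dev.std()), int(dev.size)


def compute_magnification(
    amap: AbsoluteRetinotopicMap,
    roi: np.ndarray | None = None,
    span_deg: float = 10.0,
    rel_threshold: float = 0.02,
    step_px: float = 0.25,
) -> float:
    """Visual degrees per millimeter along the steepest-ascent line.

    Locates, by linear interpolation along the line perpendicular to the
    zero-level line through its centroid, the sub-pixel positions where the
    visual angle equals -span_deg/2 and +span_deg/2, and returns
    ``span_deg / separation_mm``.
    """
    if span_deg <= 0:
        raise ValueError("span_deg must be positive")
    if amap.pixel_size_mm <= 0:
        raise ValueError("pixel_size_mm must be positive")
    roi = _default_roi(amap) if roi is None else np.asarray(roi, dtype=bool)
    vals = amap.visual_angle[roi]
    if float(np.ptp(vals)) < 1e-12:
        raise ValueError("zero gradient: flat map")
    centroid, _, ascent = _fit_zero_line(amap, roi, rel_threshold)

    nr, nc = amap.visual_angle.shape
    s_max = math.hypot(nr, nc)
    s = np.arange(-s_max, s_max + step_px, step_px)
    points = centroid[None, :] + s[:, None] * ascent[None, :]
    inside = (
        (points[:, 0] >= 0)
        & (points[:, 0] <= nr - 1)
        & (points[:, 1] >= 0)
        & (points[:, 1] <= nc - 1)
    )
    in_roi = np.zeros_like(inside)
    if inside.any():
        in_roi[inside] = (
            ndimage.map_coordinates(
                roi.astype(float), points[inside].T, order=0, mode="constant"
            )
            > 0.5
        )
    valid = inside & in_roi
    if valid.sum() < 2:
        raise ValueError("steepest-ascent line does not traverse the ROI")
    v_line = np.full(s.size, np.nan)
    v_line[valid] = ndimage.map_coordinates(
        amap.visual_angle, points[valid].T, order=1, mode="nearest"
    )

    def crossing(level: float) -> float:
        with np.errstate(invalid="ignore"):
            below = v_line <= level
            above = v_line >= level
        idx = np.flatnonzero(below[:-1] & above[1:] & valid[:-1] & valid[1:])
        if idx.size == 0:
            raise ValueError(
                f"visual-angle level {level:+g} deg not attained inside the ROI"
            )
        # Crossing nearest the zero-line centroid (s = 0).
        mid = idx[np.argmin(np.abs(s[idx]))]
        v0, v1 = v_line[mid], v_line[mid + 1]
        frac = 0.0 if v1 == v0 else (level - v0) / (v1 - v0)
        return float(s[mid] + frac * step_px)

    s_minus = crossing(-span_deg / 2.0)
    s_plus = crossing(+span_deg / 2.0)
    separation_mm = (s_plus - s_minus) * amap.pixel_size_mm
    if separation_mm <= 0:
        raise ValueError("zero gradient: degenerate level separation")
    return span_deg / separation_mm


def compute_map_metrics(
    amap: AbsoluteRetinotopicMap,
    roi: np.ndarray | None = None,
    radius: float = 2.9,
    max_pixels: int = 20000,
    span_deg: float = 10.0,
) -> MapMetrics:
    """Compute all three metrics for one absolute retinotopic map."""
    roi = _default_roi(amap) if roi is None else np.asarray(roi, dtype=bool)
    tilt = compute_map_tilt(amap, roi)
    scatter, n_used = compute_phase_scatter(amap, roi, radius, max_pixels)
    mag = compute_magnification(amap, roi, span_deg)
    return MapMetrics(
        axis=amap.axis,
        tilt_deg=tilt,
        scatter_sd=scatter,
        magnification_deg_per_mm=mag,
        n_pixels_used=n_used,
    )
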