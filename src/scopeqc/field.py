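"""Field-of-view calibration from grid targets and bath images.

A fixed-pitch grid target imaged in a fluorescent film gives the local
image scale (μm/px) across the field and, by comparing center to edges, a
distortion figure. A uniform fluorescein bath measures combined
excitation/collection flatness; its statistic is the percent deviation
(sd/mean) over a central region of interest plus row/column profiles.

Grid lines are detected from projection profiles: the image is cut into
strips, each strip is averaged into a 1-D profile, and dark bar centers are
localized to sub-pixel precision by parabolic interpolation around profile
minima. Each pair of adjacent lines yields one measurement cell with local
scale = pitch / spacing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .optics import ObjectiveSpec, RelaySpec, predicted_fov_diameter

__all__ = [
    "ScaleMap",
    "UniformityResult",
    "FovSummary",
    "grid_scale_map",
    "distortion_metric",
    "uniformity_stats",
    "fov_summary",
    "GridDetectionError",
]


class GridDetectionError(ValueError):
    """Raised when too few grid lines are found to calibrate."""


@dataclass(frozen=True)
class ScaleMap:
    """Local image scale (μm/px) measured on a grid of cells.

    ``cells`` has columns ``x_px, y_px, scale_um_per_px, axis`` where axis
    is "x" for spacings of vertical lines and "y" for horizontal lines,
    and (x_px, y_px) is the cell center in pixel coordinates.
    """

    cells: pd.DataFrame = field(repr=False)
    image_shape: tuple[int, int]
    pitch_um: float
    scale_mean: float
    scale_sd: float
    grid_angle_deg: float = 0.0
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if (self.cells["scale_um_per_px"] <= 0).any():
            raise ValueError("all scales must be > 0")


@dataclass(frozen=True)
class UniformityResult:
    """Illumination/collection uniformity over a central ROI."""

    roi_um: tuple[float, float]
    mean_counts: float
    sd_counts: float
    percent_deviation: float
    row_profile: np.ndarray = field(repr=False)
    col_profile: np.ndarray = field(repr=False)
    n_saturated_excluded: int = 0
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class FovSummary:
    """Physical extent of the imaged field."""

    width_mm: float
    height_mm: float
    diagonal_mm: float
    area_mm2: float
    predicted_diameter_mm: float | None = None
    measured_over_predicted: float | None = None


# ---------------------------------------------------------------------------
# grid detection internals


def _profile_minima(profile: np.ndarray, min_prominence: float) -> np.ndarray:
    """Sub-pixel positions of profile valleys via parabolic interpolation."""
    p = profile
    idx = np.nonzero((p[1:-1] < p[:-2]) & (p[1:-1] <= p[2:]))[0] + 1
    depth = np.median(p) - p[idx]
    idx = idx[depth > min_prominence]
    centers = []
    for i in idx:
        a, b, c = p[i - 1], p[i], p[i + 1]
        denom = a - 2 * b + c
        shift = 0.5 * (a - c) / denom if denom != 0 else 0.0
        centers.append(i + float(np.clip(shift, -0.5, 0.5)))
    return np.asarray(centers)


def _estimate_period_px(profile: np.ndarray) -> float:
    """Dominant period of a 1-D profile from its autocorrelation peak."""
    p = profile - profile.mean()
    ac = np.correlate(p, p, mode="full")[p.size - 1 :]
    # first local max after the zero-lag peak has decayed
    lag_min = max(3, int(np.argmax(ac < 0)) or 3)
    if lag_min >= ac.size - 2:
        raise GridDetectionError("projection profile shows no periodicity")
    seg = ac[lag_min:]
    rel = np.nonzero((seg[1:-1] >= seg[:-2]) & (seg[1:-1] >= seg[2:]))[0]
    if rel.size == 0:
        raise GridDetectionError("no autocorrelation peak; is a grid visible?")
    return float(lag_min + 1 + rel[np.argmax(seg[rel + 1])])


def _estimate_grid_angle(image: np.ndarray, max_deg: float = 2.0) -> float:
    """Grid rotation from the sharpness of projection profiles.

    Scans candidate angles and keeps the one maximizing the variance of the
    column-mean profile of a central crop (projections of an aligned grid
    are sharpest). Only small rotations (±``max_deg``) are considered.
    """
    ny, nx = image.shape
    crop = image[ny // 4 : 3 * ny // 4, nx // 4 : 3 * nx // 4]
    best_angle, best_score = 0.0, -np.inf
    for angle in np.arange(-max_deg, max_deg + 1e-9, 0.25):
        rot = (
            crop
            if angle == 0.0
            else ndimage.rotate(crop, angle, reshape=False, order=1, mode="nearest")
        )
        score = float(np.var(rot.mean(axis=0)) + np.var(rot.mean(axis=1)))
        if score > best_score:
            best_angle, best_score = float(angle), score
    return best_angle


def _cells_along_axis(
    image: np.ndarray, pitch_um: float, axis: str
) -> tuple[list[tuple[float, float, float]], int]:
    """Measurement cells from strip-wise projections along one axis.

    For axis "x", the image is cut into horizontal strips; each strip's
    column-mean profile localizes the vertical grid lines, and adjacent
    line pairs give local x-scale at the strip's center row.
    Returns (cells, n_lines_global) with cells as (x_px, y_px, scale).
    """
    img = image if axis == "x" else image.T
    ny, nx = img.shape
    period = _estimate_period_px(img.mean(axis=0))
    strip = max(int(round(2 * period)), 8)
    n_strips = max(ny // strip, 1)
    prominence = 0.1 * float(np.ptp(img))
    cells: list[tuple[float, float, float]] = []
    n_lines_global = 0
    for s in range(n_strips):
        rows = slice(s * strip, ny if s == n_strips - 1 else (s + 1) * strip)
        profile = ndimage.gaussian_filter1d(
            img[rows].mean(axis=0), max(period / 12.0, 1.0)
        )
        centers = _profile_minima(profile, prominence)
        # discard spurious detections closer than half a period
        if centers.size >= 2:
            keep = np.concatenate([[True], np.diff(centers) > period / 2.0])
            centers = centers[keep]
        n_lines_global = max(n_lines_global, centers.size)
        mid_row = (rows.start + (rows.stop - 1)) / 2.0
        for left, right in zip(centers[:-1], centers[1:]):
            spacing = right - left
            cells.append(((left + right) / 2.0, mid_row, pitch_um / spacing))
    if axis == "y":  # transpose back: (x, y) were swapped
        cells = [(y, x, sc) for (x, y, sc) in cells]
    return cells, n_lines_global


# ---------------------------------------------------------------------------
# operations


def grid_scale_map(
    image: np.ndarray, pitch_um: float, correct_rotation: bool = True
) -> ScaleMap:
    """Local magnification map from a fixed-pitch grid-target image.

    Requires at least four grid periods visible along each axis. A small
    grid rotation (up to ±2°) is estimated first and removed before line
    detection. Raises :class:`GridDetectionError` when fewer than three
    lines are found along an axis; an irregular map (spacing coefficient of
    variation above 20 %) is flagged ``"irregular"``, not rejected.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("grid image must be 2-D")
    angle = _estimate_grid_angle(image) if correct_rotation else 0.0
    work = (
        ndimage.rotate(image, angle, reshape=False, order=1, mode="nearest")
        if angle != 0.0
        else image
    )
    all_cells: list[tuple[float, float, float, str]] = []
    for axis in ("x", "y"):
        cells, n_lines = _cells_along_axis(work, pitch_um, axis)
        if n_lines < 3:
            raise GridDetectionError(
                f"only {n_lines} grid lines detected along {axis}; need >= 3"
            )
        all_cells += [(x, y, s, axis) for (x, y, s) in cells]
    df = pd.DataFrame(all_cells, columns=["x_px", "y_px", "scale_um_per_px", "axis"])
    scales = df["scale_um_per_px"].to_numpy()
    mean, sd = float(scales.mean()), float(scales.std(ddof=1))
    flags = ("irregular",) if sd / mean > 0.20 else ()
    return ScaleMap(
        cells=df,
        image_shape=image.shape,
        pitch_um=pitch_um,
        scale_mean=mean,
        scale_sd=sd,
        grid_angle_deg=angle,
        flags=flags,
    )


def distortion_metric(
    scale_map: ScaleMap, center_frac: float = 0.3, edge_frac: float = 0.75
) -> float:
    """Center-vs-edge scale deviation, in percent of the mean scale.

    ΔS = |mean scale of the central cell block − mean scale of the outer
    cell ring|, returned as 100·ΔS/S̄. Cells belong to the central block
    when their max-norm distance from the image center is ≤ ``center_frac``
    of the half-field, and to the edge ring when it is ≥ ``edge_frac``.
    Requires at least a 3×3 arrangement of cells.
    """
    df = scale_map.cells
    ny, nx = scale_map.image_shape
    u = (df["x_px"] - (nx - 1) / 2.0) / (nx / 2.0)
    v = (df["y_px"] - (ny - 1) / 2.0) / (ny / 2.0)
    m = np.maximum(np.abs(u), np.abs(v))
    n_cols = df.loc[df["axis"] == "x", "x_px"].round(-1).nunique()
    n_rows = df.loc[df["axis"] == "y", "y_px"].round(-1).nunique()
    if min(n_cols, n_rows) < 3:
        raise ValueError("scale map needs at least 3x3 measurement cells")
    center = df.loc[m <= center_frac, "scale_um_per_px"]
    edge = df.loc[m >= edge_frac, "scale_um_per_px"]
    if center.empty or edge.empty:
        raise ValueError("center block or edge ring contains no cells")
    delta = abs(float(center.mean()) - float(edge.mean()))
    return 100.0 * delta / scale_map.scale_mean


def uniformity_stats(
    image: np.ndarray,
    roi_um: float | tuple[float, float],
    pixel_size_um: float,
    saturation: float | None = None,
) -> UniformityResult:
    """Uniformity statistics of a bath image over a centered ROI.

    Returns the mean, sd and percent deviation (100·sd/mean) over a
    ``roi_um`` (width, height) box centered on the image, plus full-image
    row- and column-mean profiles. Pixels at or above ``saturation`` are
    excluded from the statistics and counted. A single-pixel ROI is
    reported as 0 % and flagged degenerate.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("bath image must be 2-D")
    if np.isscalar(roi_um):
        roi_um = (float(roi_um), float(roi_um))  # type: ignore[assignment]
    ny, nx = image.shape
    half_w = int(round(roi_um[0] / pixel_size_um / 2.0))
    half_h = int(round(roi_um[1] / pixel_size_um / 2.0))
    cy, cx = ny // 2, nx // 2
    if half_h > cy or half_w > cx:
        raise ValueError(
            f"roi {roi_um} um exceeds image extent "
            f"({nx * pixel_size_um:.0f} x {ny * pixel_size_um:.0f} um)"
        )
    roi = image[cy - half_h : cy + half_h + 1, cx - half_w : cx + half_w + 1]
    flags: list[str] = []
    vals = roi.ravel()
    n_sat = 0
    if saturation is not None:
        sat_mask = vals >= saturation
        n_sat = int(sat_mask.sum())
        if n_sat:
            vals = vals[~sat_mask]
            flags.append("saturated_pixels_excluded")
    mean = float(vals.mean())
    if vals.size < 2:
        sd, pct = 0.0, 0.0
        flags.append("degenerate_roi")
    else:
        sd = float(vals.std(ddof=1))
        pct = 100.0 * sd / mean
    return UniformityResult(
        roi_um=tuple(roi_um),  # type: ignore[arg-type]
        mean_counts=mean,
        sd_counts=sd,
        percent_deviation=pct,
        row_profile=image.mean(axis=1),
        col_profile=image.mean(axis=0),
        n_saturated_excluded=n_sat,
        flags=tuple(flags),
    )


def fov_summary(
    scale_map: ScaleMap,
    relay: RelaySpec | None = None,
    objective: ObjectiveSpec | None = None,
) -> FovSummary:
    """Physical field-of-view extent implied by a measured scale map.

    Width/height = pixel counts × mean scale; the diagonal and area follow.
    When relay and objective specs are given, the first-order prediction
    2·f_O·tan(θ/M) is attached for comparison against the measured diagonal.
    """
    ny, nx = scale_map.image_shape
    width_mm = nx * scale_map.scale_mean * 1e-3
    height_mm = ny * scale_map.scale_mean * 1e-3
    diagonal = math.hypot(width_mm, height_mm)
    predicted = ratio = None
    if relay is not None and objective is not None:
        predicted = predicted_fov_diameter(relay, objective)
        ratio = diagonal / predicted
    return FovSummary(
        width_mm=width_mm,
        height_mm=height_mm,
        diagonal_mm=diagonal,
        area_mm2=width_mm * height_mm,
        predicted_diameter_mm=predicted,
        measured_over_predicted=ratio,
    )
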