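"""ROI statistics, photobleaching metrics and drug-release kinetics.

Concentration maps from the fluorescence pipeline are summarized over
polygonal regions of interest (tumor, periphery, injection site).  The
module provides the descriptive statistics the dosimetry workflow needs:
ROI mean/std, percent change (photobleaching fraction), contrast ratios
(tumor-to-normal uptake), and time-resolved release curves with a simple
plateau detector for "release leveled off" calls.

A pixel belongs to a polygon ROI when its center lies inside the polygon
(even-odd rule); standard deviations are population (divide by n).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from matplotlib.path import Path as _MplPath

__all__ = [
    "RegionOfInterest",
    "KineticsSeries",
    "roi_stats",
    "percent_change",
    "contrast_ratio",
    "release_curve",
    "DEFAULT_PLATEAU_THRESHOLD",
]

DEFAULT_PLATEAU_THRESHOLD = 0.02


@dataclass
class RegionOfInterest:
    """A named region given as a polygon in (row, col) pixel coordinates,
    or as an explicit boolean mask."""

    name: str
    vertices: np.ndarray | None = None
    mask: np.ndarray | None = None

    def __post_init__(self):
        if (self.vertices is None) == (self.mask is None):
            raise ValueError("provide exactly one of vertices or mask")
        if self.vertices is not None:
            self.vertices = np.asarray(self.vertices, dtype=float)
            if self.vertices.ndim != 2 or self.vertices.shape[1] != 2 or self.vertices.shape[0] < 3:
                raise ValueError("vertices must be an (N>=3, 2) array of (row, col)")
            if _self_intersects(self.vertices):
                raise ValueError(f"ROI {self.name!r} polygon is self-intersecting")
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if not self.mask.any():
                raise ValueError(f"ROI {self.name!r} mask is empty")

    def rasterize(self, shape) -> np.ndarray:
        """Boolean mask of pixels whose centers fall inside the ROI."""
        if self.mask is not None:
            if self.mask.shape != tuple(shape):
                raise ValueError(f"ROI mask shape {self.mask.shape} does not match image shape {tuple(shape)}")
            return self.mask
        rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
        pts = np.column_stack([rows.ravel(), cols.ravel()])
        path = _MplPath(self.vertices)
        inside = path.contains_points(pts).reshape(shape)
        if not inside.any():
            raise ValueError(f"ROI {self.name!r} rasterizes to an empty mask on shape {tuple(shape)}")
        return inside


def _segments_cross(p1, p2, p3, p4):
    def orient(a, b, c):
        return np.sign((b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0]))

    return (
        orient(p1, p2, p3) * orient(p1, p2, p4) < 0
        and orient(p3, p4, p1) * orient(p3, p4, p2) < 0
    )


def _self_intersects(verts) -> bool:
    """True if any two non-adjacent polygon edges properly cross."""
    n = len(verts)
    edges = [(verts[i], verts[(i + 1) % n]) for i in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            if j == i + 1 or (i == 0 and j == n - 1):
                continue  # adjacent edges share a vertex
            if _segments_cross(*edges[i], *edges[j]):
                return True
    return False


@dataclass
class KineticsSeries:
    """Time-ordered ROI summary of a sequence of concentration maps."""

    times: np.ndarray
    roi_name: str
    means: np.ndarray
    stds: np.ndarray
    n_pixels: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.stds = np.asarray(self.stds, dtype=float)
        self.n_pixels = np.asarray(self.n_pixels, dtype=int)
        if not (self.times.size == self.means.size == self.stds.size == self.n_pixels.size):
            raise ValueError("times, means, stds, n_pixels must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.stds < 0):
            raise ValueError("standard deviations must be non-negative")


def roi_stats(image, roi: RegionOfInterest):
    """Mean, population std and pixel count over the unmasked ROI pixels.

    NaN pixels (masked upstream: saturated, unconverged ...) are excluded
    from both the statistics and the count.
    """
    image = np.asarray(image, dtype=float)
    mask = roi.rasterize(image.shape)
    values = image[mask]
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValueError(f"ROI {roi.name!r} contains no unmasked pixels")
    return float(values.mean()), float(values.std()), int(values.size)


def percent_change(pre_mean: float, post_mean: float) -> float:
    """Percent decrease from pre to post: 100 * (pre - post) / pre.

    Positive values are decreases (photobleaching); negative values are
    increases (drug release).
    """
    if not (np.isfinite(pre_mean) and pre_mean > 0):
        raise ValueError(f"pre_mean must be positive, got {pre_mean}")
    return 100.0 * (pre_mean - post_mean) / pre_mean


def contrast_ratio(roi_a_mean: float, roi_b_mean: float) -> float:
    """Ratio of ROI means, e.g. tumor-to-normal uptake."""
    if not (np.isfinite(roi_b_mean) and roi_b_mean > 0):
        raise ValueError(f"denominator mean must be positive, got {roi_b_mean}")
    return roi_a_mean / roi_b_mean


def release_curve(
    times,
    maps,
    roi: RegionOfInterest,
    plateau_threshold: float = DEFAULT_PLATEAU_THRESHOLD,
):
    """ROI time course of a concentration-map sequence, with plateau call.

    Parameters
    ----------
    times : sequence of float
        Minutes from treatment start; strictly increasing, >= 2 points.
    maps : sequence of 2-D arrays
        Concentration maps, one per time point, common shape.
    roi : RegionOfInterest
    plateau_threshold : float
        Relative per-step increase below which the curve counts as flat.

    Returns
    -------
    (KineticsSeries, plateau_time)
        ``plateau_time`` is the earliest time after which every
        consecutive relative increase stays below the threshold, or None
        when the curve is still rising at the end (plateau not reached).
    """
    times = np.asarray(times, dtype=float)
    maps = list(maps)
    if times.size < 2 or len(maps) != times.size:
        raise ValueError("need >= 2 time points with one map per time point")
    shape = np.asarray(maps[0]).shape
    for m in maps:
        if np.asarray(m).shape != shape:
            raise ValueError("all maps must share one shape")
    stats_ = [roi_stats(m, roi) for m in maps]
    means = np.array([s[0] for s in stats_])
    stds = np.array([s[1] for s in stats_])
    n_pix = np.array([s[2] for s in stats_])
    series = KineticsSeries(times=times, roi_name=roi.name, means=means, stds=stds, n_pixels=n_pix)

    with np.errstate(divide="ignore", invalid="ignore"):
        prev = means[:-1]
        rel_inc = np.where(prev > 0, (means[1:] - prev) / prev, np.where(means[1:] > 0, np.inf, 0.0))
    above = np.flatnonzero(rel_inc >= plateau_threshold)
    if above.size == 0:
        plateau_time = float(times[0])
    elif above[-1] == rel_inc.size - 1:
        plateau_time = None  # still rising at the last step
    else:
        plateau_time = float(times[above[-1] + 1])
    return series, plateau_time
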