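"""The six vascular parameters for one binary mask + ROI.

* vascular area fraction — vessel pixels / ROI pixels, unitless
* length density — skeleton length per ROI area, mm/mm²
* branch density — junction clusters per ROI area, 1/mm²
* nearest-vessel distance (NND) — mean over segments of the distance from a
  segment's centroid to the nearest other segment centroid, µm
* NND variability — sample standard deviation of those distances, µm
* vascular outgrowth — radial extent of the vessel front relative to the
  ROI radius, measured from the optic-nerve-head center, unitless
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import pdist, squareform

from vesselmetrics.images import BinaryMask, InputError, ParameterError
from vesselmetrics.skeleton import SkeletonGraph, count_branch_points, total_length


class UndefinedResultError(ValueError):
    """The requested statistic is undefined for this input."""


@dataclass
class MorphometryResult:
    """The six scalar parameters for one 2D projection/ROI."""

    area_fraction: float
    length_density: float  # mm / mm^2
    branch_density: float  # 1 / mm^2
    nnd_mean: float  # µm
    nnd_sd: float  # µm
    outgrowth: float | None  # unitless in [0, 1], None when no center given
    roi_area: float  # mm^2
    n_segments: int
    label: str = ""
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.area_fraction <= 1.0):
            raise ValueError(f"area_fraction out of [0,1]: {self.area_fraction}")
        if self.length_density < 0 or self.branch_density < 0 or self.nnd_sd < 0:
            raise ValueError("densities and nnd_sd must be non-negative")
        if self.outgrowth is not None and not (0.0 <= self.outgrowth <= 1.0):
            raise ValueError(f"outgrowth out of [0,1]: {self.outgrowth}")

    def to_row(self) -> dict[str, Any]:
        """Tidy, unit-suffixed record for CSV export."""
        return {
            "label": self.label,
            "area_fraction": self.area_fraction,
            "length_density_mm_per_mm2": self.length_density,
            "branch_density_per_mm2": self.branch_density,
            "nnd_mean_um": self.nnd_mean,
            "nnd_sd_um": self.nnd_sd,
            "outgrowth": self.outgrowth,
            "roi_area_mm2": self.roi_area,
            "n_segments": self.n_segments,
        }


def area_fraction(mask: BinaryMask) -> float:
    """Fraction of ROI pixels covered by vessels: |foreground ∩ roi| / |roi|."""
    roi = mask.roi_or_full
    n_roi = int(np.count_nonzero(roi))
    if n_roi == 0:
        raise InputError("empty ROI")
    return int(np.count_nonzero(mask.pixels & roi)) / n_roi


def length_density(graph: SkeletonGraph, roi_area: float) -> float:
    """Skeleton length per ROI area, mm/mm²."""
    if roi_area <= 0:
        raise InputError(f"roi_area must be positive, got {roi_area}")
    return (total_length(graph) / 1000.0) / roi_area


def branch_density(graph: SkeletonGraph, roi_area: float) -> float:
    """Junction clusters per ROI area, 1/mm²."""
    if roi_area <= 0:
        raise InputError(f"roi_area must be positive, got {roi_area}")
    return count_branch_points(graph) / roi_area


def nnd(graph: SkeletonGraph) -> tuple[float, float]:
    """Nearest-neighbor distance between vessel segments.

    Each positive-length segment is represented by its centroid (in µm);
    for segment *i* the statistic is ``d_i = min_{j != i} ||c_i - c_j||``.
    Returns the mean and the sample (n−1) standard deviation of the ``d_i``.
    Zero-length (isolated single-pixel) segments are noise artifacts and
    are excluded.
    """
    cents = np.array(
        [s.centroid_um for s in graph.segments if s.length_um > 0], dtype=float
    )
    if len(cents) < 2:
        raise UndefinedResultError(
            f"NND needs at least 2 positive-length segments, got {len(cents)}"
        )
    return nnd_from_centroids(cents)


def nnd_from_centroids(centroids: np.ndarray) -> tuple[float, float]:
    """NND mean and sample SD from an (n, 2) array of µm centroids."""
    centroids = np.asarray(centroids, dtype=float)
    if len(centroids) < 2:
        raise UndefinedResultError("need at least 2 centroids")
    d = squareform(pdist(centroids))
    np.fill_diagonal(d, np.inf)
    nearest = d.min(axis=1)
    return float(nearest.mean()), float(nearest.std(ddof=1))


def outgrowth(
    mask: BinaryMask,
    center: tuple[float, float] | None = None,
    roi: np.ndarray | None = None,
    min_object_px: int = 25,
) -> float:
    """Radial vascular extent relative to the ROI radius.

    Ratio of the maximal Euclidean distance from the center (optic-nerve-head
    analogue, ``(x, y)`` in px) to any foreground pixel, over the maximal
    distance from the center to any ROI pixel; clamped to [0, 1].

    The vascular front is defined by vessels, so connected components
    smaller than ``min_object_px`` pixels are ignored: a max-distance
    statistic is otherwise dominated by any single noise speck that
    survives despeckling. Set ``min_object_px=0`` to disable.
    """
    center = center if center is not None else mask.center
    if center is None:
        raise ParameterError(
            "outgrowth requires a center point; supply one via the mask's "
            "`center` attribute or the `center` argument"
        )
    roi = roi if roi is not None else mask.roi_or_full
    roi = np.asarray(roi).astype(bool)
    cx, cy = center
    if not roi.any():
        raise InputError("empty ROI")

    def _max_dist(m: np.ndarray) -> float:
        ys, xs = np.nonzero(m)
        if len(ys) == 0:
            return 0.0
        return float(np.sqrt((xs - cx) ** 2 + (ys - cy) ** 2).max())

    denom = _max_dist(roi)
    if denom == 0:
        raise InputError("ROI has zero radial extent around the center")
    fg = mask.pixels & roi
    if min_object_px > 0:
        labels, n = ndimage.label(fg, structure=np.ones((3, 3), dtype=bool))
        if n > 0:
            sizes = np.bincount(labels.ravel())
            keep = sizes >= min_object_px
            keep[0] = False
            fg = keep[labels]
    return float(np.clip(_max_dist(fg) / denom, 0.0, 1.0))


@dataclass
class Heatmap:
    """Tiled area-fraction grid over the ROI bounding box."""

    tiles: np.ndarray  # float grid, NaN where a tile is not valid
    tile_um: float
    tile_px: int
    histogram: np.ndarray  # counts over 20 equal bins on [0, 1]
    bin_edges: np.ndarray

    @property
    def valid_values(self) -> np.ndarray:
        return self.tiles[~np.isnan(self.tiles)]


def heatmap(mask: BinaryMask, tile_um: float = 100.0) -> Heatmap:
    """Area fraction in square tiles across the ROI.

    The ROI bounding box is partitioned into tiles of side ``tile_um``
    (converted to a whole number of pixels). A tile is valid when at least
    50% of its pixels lie inside the ROI; its value is the area fraction
    within tile ∩ ROI. Invalid tiles are NaN. The histogram counts valid
    tile values in 20 equal bins over [0, 1].
    """
    ps = mask.pixel_size
    if tile_um <= ps:
        raise ParameterError(f"tile_um ({tile_um}) must exceed pixel_size ({ps})")
    roi = mask.roi_or_full
    if not roi.any():
        raise InputError("empty ROI")
    tile_px = max(1, int(round(tile_um / ps)))

    ys, xs = np.nonzero(roi)
    y0, y1 = ys.min(), ys.max() + 1
    x0, x1 = xs.min(), xs.max() + 1
    if tile_px >= (y1 - y0) and tile_px >= (x1 - x0):
        warnings.warn(
            "tile is larger than the ROI bounding box; returning a single tile",
            UserWarning,
            stacklevel=2,
        )
    ny = max(1, int(np.ceil((y1 - y0) / tile_px)))
    nx = max(1, int(np.ceil((x1 - x0) / tile_px)))

    tiles = np.full((ny, nx), np.nan)
    fg = mask.pixels & roi
    for iy in range(ny):
        for ix in range(nx):
            ta, tb = y0 + iy * tile_px, min(y0 + (iy + 1) * tile_px, y1)
            tc, td = x0 + ix * tile_px, min(x0 + (ix + 1) * tile_px, x1)
            roi_tile = roi[ta:tb, tc:td]
            n_total = roi_tile.size
            n_in = int(np.count_nonzero(roi_tile))
            if n_total == 0 or n_in / n_total < 0.5:
                continue
            tiles[iy, ix] = int(np.count_nonzero(fg[ta:tb, tc:td])) / n_in

    valid = tiles[~np.isnan(tiles)]
    hist, edges = np.histogram(valid, bins=20, range=(0.0, 1.0))
    return Heatmap(tiles, tile_um, tile_px, hist, edges)
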