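"""Whole-retina vs. single-plexus analysis of vascular z-stacks.

A collapsed (whole-retina) analysis runs the 2D pipeline on the maximum
projection of the full stack, merging the primary, intermediate and deep
plexuses into one plane. A single-plexus analysis projects each plexus
separately, measures it, and combines the three results: lengths and branch
counts are extensive and are summed; area fraction, nearest-vessel distance,
its variability and outgrowth are intensive and are averaged. Because
vessels of different layers overlap in the x–y plane, the collapsed
projection merges them and systematically undercounts length and branching
— the percent deviation between the two modes quantifies that bias.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Any

import numpy as np
from scipy.signal import argrelmax
from skimage.filters import threshold_otsu

from vesselmetrics.config import AnalysisConfig
from vesselmetrics.images import BinaryMask, CalibratedImage, InputError
from vesselmetrics.morphometry import (
    MorphometryResult,
    UndefinedResultError,
    area_fraction,
    branch_density,
    length_density,
    nnd,
    outgrowth,
)
from vesselmetrics.preprocess import binarize
from vesselmetrics.skeleton import build_graph, skeletonize

PLEXUS_NAMES = ("primary", "intermediate", "deep")


class SeparationError(ValueError):
    """Automatic plexus separation could not find three layers."""


def _round_half_away(value: float, decimals: int) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def percent_deviation(whole: float, single: float, decimals: int = 2) -> float:
    """Percent deviation of the single-plexus value from the whole-retina value.

    ``(single - whole) / whole * 100``, rounded half away from zero.
    """
    if whole == 0:
        raise UndefinedResultError("percent deviation undefined for whole == 0")
    return _round_half_away((single - whole) / whole * 100.0, decimals)


def percent_change(early: float, late: float, decimals: int = 1) -> float:
    """Percent reduction from an early to a late value (reduction positive).

    ``(early - late) / early * 100``, rounded half away from zero.
    """
    if early == 0:
        raise UndefinedResultError("percent change undefined for early == 0")
    return _round_half_away((early - late) / early * 100.0, decimals)


def collapse_stack(stack: CalibratedImage) -> CalibratedImage:
    """Maximum projection of a (z, y, x) stack; calibration preserved."""
    if not stack.is_stack:
        return stack
    return CalibratedImage(
        stack.pixels.max(axis=0),
        stack.pixel_size_yx,
        roi=stack.roi,
        center=stack.center,
        metadata=dict(stack.metadata),
    )


def _project_range(stack: CalibratedImage, z0: int, z1: int) -> CalibratedImage:
    return CalibratedImage(
        stack.pixels[z0 : z1 + 1].max(axis=0),
        stack.pixel_size_yx,
        roi=stack.roi,
        center=stack.center,
        metadata={**stack.metadata, "z_range": (int(z0), int(z1))},
    )


def foreground_z_profile(stack: CalibratedImage, smooth_window: int = 3) -> np.ndarray:
    """Per-slice foreground pixel count (global Otsu threshold), smoothed.

    Smoothing is a centered moving average over ``smooth_window`` slices.
    """
    px = stack.pixels
    thresh = threshold_otsu(px)
    counts = (px > thresh).sum(axis=(1, 2)).astype(float)
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        counts = np.convolve(counts, kernel, mode="same")
    return counts


def separate_plexuses(
    stack: CalibratedImage,
    mode: str = "auto",
    z_ranges: list[tuple[int, int]] | None = None,
    smooth_window: int = 3,
) -> list[CalibratedImage]:
    """Split a z-stack into three separately projected plexus images.

    ``auto`` mode locates the three highest local maxima of the smoothed
    per-slice foreground profile and cuts at the minima between them;
    ``manual`` mode takes three caller-supplied inclusive z-ranges. Either
    way the ranges partition the z-extent without overlap, and each plexus
    is max-projected over its range.
    """
    if not stack.is_stack:
        raise InputError("separate_plexuses expects a 3D stack")
    n_z = stack.pixels.shape[0]

    if mode == "manual":
        if z_ranges is None or len(z_ranges) != 3:
            raise InputError("manual mode requires exactly three z-ranges")
        for a, b in z_ranges:
            if not (0 <= a <= b < n_z):
                raise InputError(f"z-range {a}:{b} outside stack of {n_z} slices")
        for (_, b), (a2, _) in zip(z_ranges, z_ranges[1:]):
            if a2 <= b:
                raise InputError("z-ranges must be increasing and non-overlapping")
        return [_project_range(stack, a, b) for a, b in z_ranges]

    if mode != "auto":
        raise InputError(f"unknown separation mode {mode!r}")

    profile = foreground_z_profile(stack, smooth_window)
    (peaks,) = argrelmax(profile, order=1)
    # plateau-tolerant fallback: strict argrelmax misses flat-topped peaks
    if len(peaks) < 3:
        peaks = np.array(
            [
                k
                for k in range(1, n_z - 1)
                if profile[k] >= profile[k - 1] and profile[k] > profile[k + 1]
            ],
            dtype=int,
        )
    if len(peaks) < 3:
        raise SeparationError(
            f"found {len(peaks)} foreground peaks along z, expected 3; "
            "supply manual z-ranges"
        )
    # the three highest peaks, in z order
    top = np.sort(peaks[np.argsort(profile[peaks])[-3:]])
    cut1 = int(top[0] + np.argmin(profile[top[0] : top[1] + 1]))
    cut2 = int(top[1] + np.argmin(profile[top[1] : top[2] + 1]))
    ranges = [(0, cut1), (cut1 + 1, cut2), (cut2 + 1, n_z - 1)]
    return [_project_range(stack, a, b) for a, b in ranges]


def analyze_image(
    image: CalibratedImage, config: AnalysisConfig | None = None, label: str = ""
) -> tuple[MorphometryResult, BinaryMask]:
    """Run the full 2D pipeline on one projection: binarize → skeleton → metrics."""
    config = config or AnalysisConfig()
    mask = binarize(image, config.threshold_window_px, config.threshold_offset)
    graph = build_graph(skeletonize(mask))
    roi_area = mask.roi_area_mm2()
    try:
        nnd_mean, nnd_sd = nnd(graph)
    except UndefinedResultError:
        # degenerate (near-empty) projection: report zero spacing so that
        # plexus averages over three layers remain defined
        nnd_mean, nnd_sd = 0.0, 0.0
        warnings.warn(
            f"fewer than 2 segments in {label or 'image'}; NND set to 0",
            UserWarning,
            stacklevel=2,
        )
    og = outgrowth(mask) if mask.center is not None else None
    result = MorphometryResult(
        area_fraction=area_fraction(mask),
        length_density=length_density(graph, roi_area),
        branch_density=branch_density(graph, roi_area),
        nnd_mean=nnd_mean,
        nnd_sd=nnd_sd,
        outgrowth=og,
        roi_area=roi_area,
        n_segments=graph.n_segments,
        label=label,
    )
    return result, mask


# parameters combined across plexuses by mean (intensive) vs. sum (extensive)
_MEAN_PARAMS = ("area_fraction", "nnd_mean", "nnd_sd", "outgrowth")
_SUM_PARAMS = ("length_density", "branch_density")


def aggregate_plexuses(per_plexus: list[MorphometryResult]) -> MorphometryResult:
    """Combine three per-plexus results into one single-plexus-analysis record.

    Length and branch densities are summed (extensive quantities); area
    fraction, NND mean/SD and outgrowth are arithmetic means over the three
    plexuses (zero-valued plexuses included).
    """
    if len(per_plexus) != 3:
        raise InputError(f"expected 3 per-plexus results, got {len(per_plexus)}")
    ogs = [r.outgrowth for r in per_plexus]
    og = None if any(v is None for v in ogs) else float(np.mean(ogs))
    return MorphometryResult(
        area_fraction=float(np.mean([r.area_fraction for r in per_plexus])),
        length_density=float(sum(r.length_density for r in per_plexus)),
        branch_density=float(sum(r.branch_density for r in per_plexus)),
        nnd_mean=float(np.mean([r.nnd_mean for r in per_plexus])),
        nnd_sd=float(np.mean([r.nnd_sd for r in per_plexus])),
        outgrowth=og,
        roi_area=per_plexus[0].roi_area,
        n_segments=int(sum(r.n_segments for r in per_plexus)),
        label="single_plexus_aggregated",
    )


@dataclass
class PlexusComparison:
    """Per-plexus, aggregated and collapsed results with percent deviations."""

    per_plexus: list[MorphometryResult]
    aggregated: MorphometryResult
    collapsed: MorphometryResult
    deviations: dict[str, float]
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        # the aggregation identities hold by construction; assert them anyway
        assert np.isclose(
            self.aggregated.length_density,
            sum(r.length_density for r in self.per_plexus),
        )
        assert np.isclose(
            self.aggregated.branch_density,
            sum(r.branch_density for r in self.per_plexus),
        )
        assert np.isclose(
            self.aggregated.area_fraction,
            np.mean([r.area_fraction for r in self.per_plexus]),
        )

    def to_dict(self) -> dict:
        return {
            "per_plexus": {
                name: r.to_row() for name, r in zip(PLEXUS_NAMES, self.per_plexus)
            },
            "aggregated": self.aggregated.to_row(),
            "collapsed": self.collapsed.to_row(),
            "deviations_percent": self.deviations,
            "metadata": {
                k: v for k, v in self.metadata.items() if isinstance(v, (str, int, float, list))
            },
        }


def compare(
    per_plexus: list[MorphometryResult],
    collapsed: MorphometryResult,
    decimals: int = 2,
) -> PlexusComparison:
    """Aggregate per-plexus results and compute deviations from the collapsed run."""
    aggregated = aggregate_plexuses(per_plexus)
    deviations: dict[str, float] = {}
    for param in _MEAN_PARAMS + _SUM_PARAMS:
        whole = getattr(collapsed, param)
        single = getattr(aggregated, param)
        if whole is None or single is None:
            continue
        if whole == 0:
            continue
        deviations[param] = percent_deviation(whole, single, decimals)
    return PlexusComparison(per_plexus, aggregated, collapsed, deviations)


def analyze_plexuses(
    stack: CalibratedImage, config: AnalysisConfig | None = None
) -> PlexusComparison:
    """Whole-retina vs. single-plexus comparison for one z-stack.

    Separates the stack into three plexus projections (auto peak finding or
    manual z-ranges per the config), runs the 2D pipeline on each and on
    the full maximum projection, aggregates the per-plexus results, and
    computes the percent deviation of the single-plexus analysis from the
    collapsed analysis for every parameter.
    """
    config = config or AnalysisConfig()

    def _staged(stage: str, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise type(exc)(f"[{stage}] {exc}") from exc

    projections = _staged(
        "separate_plexuses",
        separate_plexuses,
        stack,
        mode=config.separation_mode,
        z_ranges=config.z_ranges,
        smooth_window=config.smooth_window,
    )
    per_plexus = []
    for name, proj in zip(PLEXUS_NAMES, projections):
        result, _ = _staged(f"analyze:{name}", analyze_image, proj, config, label=name)
        per_plexus.append(result)
    collapsed_img = _staged("collapse_stack", collapse_stack, stack)
    collapsed, _ = _staged(
        "analyze:collapsed", analyze_image, collapsed_img, config, label="whole_retina"
    )
    comparison = compare(per_plexus, collapsed, config.deviation_decimals)
    comparison.metadata["z_ranges"] = [
        list(map(int, p.metadata.get("z_range", (-1, -1)))) for p in projections
    ]
    return comparison
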