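"""Shared fixtures: synthetic networks, measurement runs, helpers.

The expensive synthetic generations are session-scoped so that unit,
property and acceptance tests measure the same objects.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pytest

from vesselmetrics import analyze_image, generate_network, rasterize
from vesselmetrics.config import AnalysisConfig
from vesselmetrics.images import CalibratedImage
from vesselmetrics.morphometry import MorphometryResult
from vesselmetrics.plexus import analyze_plexuses
from vesselmetrics.synth import PRESETS, SynthParams, VesselGraph, rasterize_stack


def circular_roi(shape: tuple[int, int], center: tuple[float, float], radius_px: float) -> np.ndarray:
    """Boolean disk ROI; center is (x, y) in px."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    cx, cy = center
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= radius_px**2


def attach_field_roi(image: CalibratedImage, field_size_um: float) -> CalibratedImage:
    """Attach a circular ROI covering the whole synthetic field."""
    radius_px = field_size_um / 2.0 / image.pixel_size_yx
    image.roi = circular_roi(image.footprint, image.center, radius_px)
    return image


# conditions for the ground-truth recovery checks: sparse enough that the
# enforced junction separation (5 vessel widths) is resolvable in the raster
RECOVERY_OUTGROWTH = 0.8


def recovery_params(branch_rate: float, seed: int) -> SynthParams:
    return SynthParams(
        field_size=600.0,
        outgrowth_fraction=RECOVERY_OUTGROWTH,
        branch_rate=branch_rate,
        anastomosis_probability=1.0,
        capture_radius=18.0,
        vessel_radius_range=(2.0, 2.5),
        n_initial_tips=3,
        heading_jitter=0.1,
        branch_angle=1.2,
        noise_sd=0.0,
        illumination_gradient=0.0,
        min_junction_separation=25.0,  # 5 x the 5 µm maximum stroke width
        seed=seed,
    )


@dataclass
class RecoveryCase:
    params: SynthParams
    graph: VesselGraph
    result: MorphometryResult
    mask_center: tuple[float, float]


@pytest.fixture(scope="session")
def recovery_cases() -> list[RecoveryCase]:
    """Sparse networks at two densities x three seeds, run through the pipeline."""
    cases = []
    for rate in (0.004, 0.008):
        for seed in (1, 2, 3):
            params = recovery_params(rate, seed)
            graph = generate_network(params)
            image = rasterize(graph, pixel_size=1.0, seed=seed)
            attach_field_roi(image, params.field_size)
            result, _ = analyze_image(image, AnalysisConfig())
            cases.append(RecoveryCase(params, graph, result, image.center))
    return cases


@pytest.fixture(scope="session")
def overlap_stack_comparison():
    """Three-depth stack of one network (full x-y overlap) and its analysis."""
    params = replace(PRESETS["p10"], seed=5, field_size=500.0)
    graph = generate_network(params)
    stack = rasterize_stack(
        [graph, graph, graph],
        pixel_size=1.0,
        pixel_size_z=1.0,
        layer_z_positions=(10.0, 30.0, 50.0),
        layer_sigma_z=2.5,
        noise_sd=5.0,
        illumination_gradient=0.1,
        seed=5,
    )
    attach_field_roi(stack, params.field_size)
    return graph, stack, analyze_plexuses(stack)


def preset_measurement(name: str, seed: int) -> MorphometryResult:
    params = replace(PRESETS[name], seed=seed)
    graph = generate_network(params)
    image = rasterize(
        graph,
        pixel_size=1.0,
        noise_sd=params.noise_sd,
        illumination_gradient=params.illumination_gradient,
        seed=seed,
    )
    attach_field_roi(image, params.field_size)
    result, _ = analyze_image(image, AnalysisConfig(), label=name)
    return result


@pytest.fixture(scope="session")
def developmental_groups():
    """Three immature-like and three adult-like retinas, measured."""
    p10 = [preset_measurement("p10", seed) for seed in (11, 12, 13)]
    p60 = [preset_measurement("p60", seed) for seed in (11, 12, 13)]
    return p10, p60
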