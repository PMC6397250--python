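"""Stack collapse, plexus separation, aggregation and deviation arithmetic."""

import numpy as np
import pytest

from vesselmetrics.config import AnalysisConfig
from vesselmetrics.images import CalibratedImage, InputError
from vesselmetrics.morphometry import MorphometryResult, UndefinedResultError
from vesselmetrics.plexus import (
    SeparationError,
    aggregate_plexuses,
    analyze_plexuses,
    collapse_stack,
    compare,
    percent_change,
    percent_deviation,
    separate_plexuses,
)
from vesselmetrics.preprocess import binarize
from vesselmetrics.synth import Edge, VesselGraph, rasterize, rasterize_stack

from conftest import attach_field_roi


def vessel(y_um, radius=3.0, field=200.0):
    nodes = [np.array([30.0, y_um]), np.array([170.0, y_um])]
    return VesselGraph(
        nodes=nodes,
        edges=[Edge(0, 1, np.asarray([n.copy() for n in nodes]), radius)],
        center=np.array([field / 2, field / 2]),
        field_size=field,
    )


class TestPercentArithmetic:
    def test_deviation_formula_and_rounding(self):
        # (2.25-2)/2*100 = 12.5 exactly; ties round half away from zero
        assert percent_deviation(2.0, 2.25, decimals=0) == 13.0
        assert percent_deviation(2.0, 1.75, decimals=0) == -13.0
        assert percent_deviation(100.0, 100.0) == 0.0
        assert percent_deviation(3.0, 2.9) == -3.33

    def test_deviation_undefined_for_zero_whole(self):
        with pytest.raises(UndefinedResultError):
            percent_deviation(0.0, 1.0)

    def test_change_reduction_positive(self):
        assert percent_change(10.0, 7.5) == 25.0
        assert percent_change(10.0, 12.0) == -20.0
        assert percent_change(5.0, 5.0) == 0.0

    def test_change_undefined_for_zero_early(self):
        with pytest.raises(UndefinedResultError):
            percent_change(0.0, 1.0)


class TestCollapse:
    def test_single_slice_identity(self):
        px = np.arange(12, dtype=np.uint8).reshape(1, 3, 4)
        out = collapse_stack(CalibratedImage(px, (1.0, 1.0, 1.0)))
        assert np.array_equal(out.pixels, px[0])
        assert out.pixel_size == 1.0

    def test_any_slice_foreground_survives_projection(self):
        px = np.zeros((3, 4, 4), dtype=np.uint8)
        px[1, 2, 2] = 200
        out = collapse_stack(CalibratedImage(px, (1.0, 1.0, 1.0)))
        assert out.pixels[2, 2] == 200

    def test_projection_foreground_is_union_of_layers(self):
        layers = [vessel(60.0), vessel(100.0), vessel(140.0)]
        stack = rasterize_stack(layers, 1.0, 1.0, (10.0, 30.0, 50.0))
        proj = collapse_stack(stack)
        union = np.zeros(proj.pixels.shape, dtype=bool)
        for g in layers:
            union |= rasterize(g, 1.0).pixels > 100
        assert np.array_equal(proj.pixels > 100, union)


class TestSeparatePlexuses:
    @pytest.fixture()
    def layered_stack(self):
        layers = [vessel(60.0), vessel(100.0), vessel(140.0)]
        return layers, rasterize_stack(layers, 1.0, 1.0, (10.0, 30.0, 50.0))

    def test_auto_ranges_contain_layer_depths(self, layered_stack):
        _, stack = layered_stack
        projections = separate_plexuses(stack, mode="auto")
        ranges = [p.metadata["z_range"] for p in projections]
        for (a, b), z in zip(ranges, (10, 30, 50)):
            assert a <= z <= b
        # ranges partition the stack without overlap
        assert ranges[0][0] == 0 and ranges[2][1] == stack.pixels.shape[0] - 1
        assert ranges[1][0] == ranges[0][1] + 1 and ranges[2][0] == ranges[1][1] + 1

    def test_manual_ranges_recover_layer_masks(self, layered_stack):
        layers, stack = layered_stack
        projections = separate_plexuses(stack, mode="manual", z_ranges=[(0, 19), (20, 39), (40, 57)])
        for proj, layer in zip(projections, layers):
            assert np.array_equal(proj.pixels > 100, rasterize(layer, 1.0).pixels > 100)

    def test_two_layer_stack_raises_in_auto_mode(self):
        layers = [vessel(60.0), vessel(140.0)]
        stack = rasterize_stack(layers, 1.0, 1.0, (10.0, 40.0))
        with pytest.raises(SeparationError, match="manual"):
            separate_plexuses(stack, mode="auto")

    def test_manual_validation(self, layered_stack):
        _, stack = layered_stack
        with pytest.raises(InputError):
            separate_plexuses(stack, mode="manual", z_ranges=[(0, 30), (20, 40), (41, 57)])
        with pytest.raises(InputError):
            separate_plexuses(stack, mode="manual", z_ranges=[(0, 10), (11, 20)])


def result(**kw):
    base = dict(
        area_fraction=0.3, length_density=50.0, branch_density=1000.0,
        nnd_mean=15.0, nnd_sd=5.0, outgrowth=0.9, roi_area=0.5, n_segments=100,
    )
    base.update(kw)
    return MorphometryResult(**base)


class TestAggregation:
    def test_sums_and_means(self):
        per = [
            result(length_density=10, branch_density=100, area_fraction=0.2, nnd_mean=10, nnd_sd=2, outgrowth=0.8),
            result(length_density=20, branch_density=300, area_fraction=0.4, nnd_mean=14, nnd_sd=4, outgrowth=0.9),
            result(length_density=30, branch_density=500, area_fraction=0.6, nnd_mean=18, nnd_sd=6, outgrowth=1.0),
        ]
        agg = aggregate_plexuses(per)
        assert agg.length_density == 60
        assert agg.branch_density == 900
        assert agg.area_fraction == pytest.approx(0.4)
        assert agg.nnd_mean == pytest.approx(14)
        assert agg.nnd_sd == pytest.approx(4)
        assert agg.outgrowth == pytest.approx(0.9)

    def test_empty_plexus_contributes_zero_to_means(self):
        per = [
            result(),
            result(area_fraction=0.0, length_density=0.0, branch_density=0.0, nnd_mean=0.0, nnd_sd=0.0),
            result(),
        ]
        agg = aggregate_plexuses(per)
        assert agg.area_fraction == pytest.approx(0.2)
        assert agg.nnd_mean == pytest.approx(10.0)
        assert agg.length_density == pytest.approx(100.0)

    def test_needs_exactly_three(self):
        with pytest.raises(InputError):
            aggregate_plexuses([result(), result()])

    def test_compare_computes_rounded_deviations(self):
        per = [result(length_density=20.0)] * 3
        collapsed = result(length_density=25.16)
        cmp = compare(per, collapsed)
        assert cmp.deviations["length_density"] == pytest.approx(
            round((60.0 - 25.16) / 25.16 * 100, 2)
        )
        assert cmp.aggregated.length_density == 60.0


class TestAnalyzePlexuses:
    def test_undercount_on_overlapping_layers(self, overlap_stack_comparison):
        """Projection merges co-localized vessels, so the collapsed analysis
        undercounts length and branching relative to the per-plexus sum."""
        _, _, comparison = overlap_stack_comparison
        assert comparison.aggregated.length_density >= comparison.collapsed.length_density
        assert comparison.aggregated.branch_density >= comparison.collapsed.branch_density

    def test_aggregation_identities_hold_on_real_run(self, overlap_stack_comparison):
        _, _, c = overlap_stack_comparison
        assert c.aggregated.length_density == pytest.approx(
            sum(r.length_density for r in c.per_plexus)
        )
        assert c.aggregated.branch_density == pytest.approx(
            sum(r.branch_density for r in c.per_plexus)
        )
        assert c.aggregated.area_fraction == pytest.approx(
            np.mean([r.area_fraction for r in c.per_plexus])
        )
        assert c.aggregated.nnd_mean == pytest.approx(
            np.mean([r.nnd_mean for r in c.per_plexus])
        )

    def test_rerun_is_bit_identical(self, overlap_stack_comparison):
        _, stack, first = overlap_stack_comparison
        again = analyze_plexuses(stack, AnalysisConfig())
        assert again.to_dict() == first.to_dict()

    def test_identical_layers_triple_the_length_density(self):
        layers = [vessel(60.0), vessel(100.0), vessel(140.0)]
        same = [layers[0], layers[0], layers[0]]
        stack = rasterize_stack(same, 1.0, 1.0, (10.0, 30.0, 50.0))
        attach_field_roi(stack, 200.0)
        c = analyze_plexuses(stack, AnalysisConfig())
        assert c.aggregated.length_density == pytest.approx(
            3 * c.collapsed.length_density, rel=0.05
        )

    def test_errors_carry_stage_name(self):
        layers = [vessel(60.0), vessel(140.0)]
        stack = rasterize_stack(layers, 1.0, 1.0, (10.0, 40.0))
        with pytest.raises(SeparationError, match=r"\[separate_plexuses\]"):
            analyze_plexuses(stack, AnalysisConfig())
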