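"""The six vascular parameters: values on analytic geometries, invariances."""

import math

import numpy as np
import pytest

from vesselmetrics.images import BinaryMask, InputError, ParameterError
from vesselmetrics.morphometry import (
    MorphometryResult,
    UndefinedResultError,
    area_fraction,
    branch_density,
    heatmap,
    length_density,
    nnd,
    nnd_from_centroids,
    outgrowth,
)
from vesselmetrics.skeleton import build_graph


def disk(shape, center, radius):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (xx - center[0]) ** 2 + (yy - center[1]) ** 2 <= radius**2


class TestAreaFraction:
    def test_full_and_empty(self):
        roi = np.ones((10, 10), dtype=bool)
        assert area_fraction(BinaryMask(np.ones((10, 10), bool), 1.0, roi=roi)) == 1.0
        assert area_fraction(BinaryMask(np.zeros((10, 10), bool), 1.0, roi=roi)) == 0.0

    def test_half_block(self):
        fg = np.zeros((100, 100), dtype=bool)
        fg[:, :50] = True
        assert area_fraction(BinaryMask(fg, 1.0)) == 0.5

    def test_normalized_to_roi_not_image(self):
        fg = np.zeros((100, 100), dtype=bool)
        fg[:50, :50] = True
        roi = np.zeros((100, 100), dtype=bool)
        roi[:50, :] = True
        assert area_fraction(BinaryMask(fg, 1.0, roi=roi)) == 0.5

    def test_empty_roi_rejected(self):
        with pytest.raises(InputError):
            area_fraction(BinaryMask(np.ones((5, 5), bool), 1.0, roi=np.zeros((5, 5), bool)))


class TestDensities:
    def test_length_density_units(self):
        # 10 mm of skeleton in a 1 mm^2 ROI
        m = np.zeros((3, 10002), dtype=bool)
        m[1, 1:10002] = True  # 10001 px line -> 10000 µm
        g = build_graph(BinaryMask(m, 1.0))
        assert length_density(g, 1.0) == pytest.approx(10.0)

    def test_empty_skeleton_zero(self):
        g = build_graph(BinaryMask(np.zeros((5, 5), bool), 1.0))
        assert length_density(g, 1.0) == 0.0
        assert branch_density(g, 1.0) == 0.0

    def test_branch_density_scaling(self):
        m = np.zeros((25, 25), dtype=bool)  # one Y junction
        m[12, 2:13] = True
        m[2:12, 12] = True
        m[13:23, 12] = True
        g = build_graph(BinaryMask(m, 1.0))
        assert branch_density(g, 0.01) == pytest.approx(100.0)

    def test_zero_area_rejected(self):
        g = build_graph(BinaryMask(np.zeros((5, 5), bool), 1.0))
        with pytest.raises(InputError):
            length_density(g, 0.0)


class TestNnd:
    def test_two_parallel_segments(self):
        m = np.zeros((20, 30), dtype=bool)
        m[2, 5:26] = True
        m[17, 5:26] = True
        g = build_graph(BinaryMask(m, 1.0))
        mean, sd = nnd(g)
        assert mean == pytest.approx(15.0)
        assert sd == pytest.approx(0.0)

    def test_regular_grid_constant_spacing(self):
        m = np.zeros((50, 30), dtype=bool)
        for y in (5, 15, 25, 35, 45):
            m[y, 5:26] = True
        g = build_graph(BinaryMask(m, 1.0))
        mean, sd = nnd(g)
        assert mean == pytest.approx(10.0)
        assert sd == pytest.approx(0.0)

    def test_three_collinear_centroids(self):
        mean, sd = nnd_from_centroids(np.array([[0, 0], [0, 10], [0, 25]], dtype=float))
        assert mean == pytest.approx(35 / 3)
        assert sd == pytest.approx(np.std([10, 10, 15], ddof=1))

    def test_single_segment_undefined(self):
        m = np.zeros((5, 20), dtype=bool)
        m[2, 2:18] = True
        with pytest.raises(UndefinedResultError):
            nnd(build_graph(BinaryMask(m, 1.0)))

    @pytest.mark.parametrize("angle_deg,shift", [(0, (0, 0)), (30, (5, -3)), (120, (-7, 11))])
    def test_translation_and_rotation_invariance(self, angle_deg, shift):
        rng = np.random.default_rng(3)
        pts = rng.uniform(0, 100, size=(20, 2))
        base = nnd_from_centroids(pts)
        a = math.radians(angle_deg)
        rot = np.array([[math.cos(a), -math.sin(a)], [math.sin(a), math.cos(a)]])
        moved = pts @ rot.T + np.asarray(shift)
        got = nnd_from_centroids(moved)
        assert got[0] == pytest.approx(base[0])
        assert got[1] == pytest.approx(base[1])


class TestOutgrowth:
    def test_half_grown_disk(self):
        shape = (220, 220)
        fg = disk(shape, (110, 110), 50)
        roi = disk(shape, (110, 110), 100)
        v = outgrowth(BinaryMask(fg, 1.0, roi=roi), center=(110, 110))
        assert v == pytest.approx(0.5, abs=0.01)

    def test_full_roi_coverage(self):
        shape = (220, 220)
        roi = disk(shape, (110, 110), 100)
        assert outgrowth(BinaryMask(roi, 1.0, roi=roi), center=(110, 110)) == 1.0

    def test_missing_center_instructs_caller(self):
        with pytest.raises(ParameterError, match="center"):
            outgrowth(BinaryMask(np.ones((5, 5), bool), 1.0))

    def test_noise_speck_does_not_move_the_front(self):
        shape = (220, 220)
        fg = disk(shape, (110, 110), 50)
        fg[110, 205] = fg[110, 206] = fg[111, 205] = True  # 3-px speck near rim
        roi = disk(shape, (110, 110), 100)
        v = outgrowth(BinaryMask(fg, 1.0, roi=roi), center=(110, 110))
        assert v == pytest.approx(0.5, abs=0.01)

    def test_recovers_generator_outgrowth(self, recovery_cases):
        for case in recovery_cases:
            assert case.result.outgrowth == pytest.approx(
                case.params.outgrowth_fraction, abs=0.02
            )


class TestHeatmap:
    def test_one_solid_quadrant(self):
        fg = np.zeros((200, 200), dtype=bool)
        fg[:100, :100] = True
        hm = heatmap(BinaryMask(fg, 1.0), tile_um=100.0)
        assert sorted(hm.tiles.ravel().tolist()) == [0.0, 0.0, 0.0, 1.0]
        assert hm.histogram[-1] == 1 and hm.histogram[0] == 3

    def test_uniform_half_density_texture(self):
        rng = np.random.default_rng(1)
        fg = rng.random((300, 300)) < 0.5
        hm = heatmap(BinaryMask(fg, 1.0), tile_um=50.0)
        assert np.nanmax(np.abs(hm.tiles - 0.5)) < 0.05
        # unimodal: every tile falls in the two bins around 0.5
        assert hm.histogram[9] + hm.histogram[10] == hm.histogram.sum()

    def test_empty_mask_all_zero_tiles(self):
        hm = heatmap(BinaryMask(np.zeros((200, 200), bool), 1.0), tile_um=50.0)
        assert (hm.valid_values == 0).all()

    def test_histogram_counts_sum_to_valid_tiles(self):
        rng = np.random.default_rng(2)
        fg = rng.random((250, 250)) < 0.3
        roi = disk((250, 250), (125, 125), 110)
        hm = heatmap(BinaryMask(fg, 1.0, roi=roi), tile_um=40.0)
        assert hm.histogram.sum() == hm.valid_values.size

    def test_border_tiles_outside_roi_marked_missing(self):
        roi = disk((200, 200), (100, 100), 90)
        hm = heatmap(BinaryMask(np.zeros((200, 200), bool), 1.0, roi=roi), tile_um=40.0)
        assert np.isnan(hm.tiles[0, 0])

    def test_tile_larger_than_roi_warns(self):
        roi = np.zeros((200, 200), dtype=bool)
        roi[90:110, 90:110] = True
        with pytest.warns(UserWarning, match="single tile"):
            heatmap(BinaryMask(np.zeros((200, 200), bool), 1.0, roi=roi), tile_um=150.0)

    def test_tile_not_larger_than_pixel(self):
        with pytest.raises(ParameterError):
            heatmap(BinaryMask(np.zeros((10, 10), bool), 2.0), tile_um=1.0)


def test_result_field_validation():
    with pytest.raises(ValueError):
        MorphometryResult(1.2, 0, 0, 0, 0, None, 1.0, 0)
    with pytest.raises(ValueError):
        MorphometryResult(0.5, -1, 0, 0, 0, None, 1.0, 0)
    row = MorphometryResult(0.5, 1.0, 2.0, 3.0, 4.0, 0.9, 1.0, 7, label="x").to_row()
    assert row["length_density_mm_per_mm2"] == 1.0
    assert row["nnd_sd_um"] == 4.0
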