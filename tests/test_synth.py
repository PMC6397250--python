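"""Generator: ground-truth invariants, determinism, rasterization oracle."""

import numpy as np
import pytest

from vesselmetrics.images import ParameterError
from vesselmetrics.synth import (
    Edge,
    PRESETS,
    SynthParams,
    VesselGraph,
    _stroke_mask,
    generate_network,
    rasterize,
    rasterize_stack,
)


def single_vessel_graph(radius=3.0):
    nodes = [np.array([50.0, 100.0]), np.array([150.0, 100.0])]
    return VesselGraph(
        nodes=nodes,
        edges=[Edge(0, 1, np.array([[50.0, 100.0], [150.0, 100.0]]), radius)],
        center=np.array([100.0, 100.0]),
        field_size=200.0,
    )


class TestGenerateNetwork:
    def test_single_tip_without_branching_gives_one_unbranched_polyline(self):
        params = SynthParams(
            field_size=400,
            branch_rate=0.0,
            anastomosis_probability=0.0,
            capture_radius=0.0,
            n_initial_tips=1,
            seed=1,
        )
        graph = generate_network(params)
        assert len(graph.edges) == 1
        assert graph.junction_count() == 0
        graph.check()

    def test_no_point_grows_beyond_outgrowth_radius(self):
        params = SynthParams(field_size=1000, outgrowth_fraction=0.5, n_initial_tips=4, seed=2)
        graph = generate_network(params)
        max_r = 0.5 * params.field_size / 2.0
        for e in graph.edges:
            d = np.sqrt(((np.asarray(e.points) - graph.center) ** 2).sum(axis=1))
            assert d.max() <= max_r + 1e-6

    def test_same_seed_gives_identical_graphs(self):
        params = SynthParams(field_size=400, branch_rate=0.02, seed=7)
        g1, g2 = generate_network(params), generate_network(params)
        assert len(g1.nodes) == len(g2.nodes)
        assert len(g1.edges) == len(g2.edges)
        for e1, e2 in zip(g1.edges, g2.edges):
            assert (e1.a, e1.b, e1.radius) == (e2.a, e2.b, e2.radius)
            assert np.array_equal(e1.points, e2.points)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_junction_count_nondecreasing_in_branch_rate(self, seed):
        counts = [
            generate_network(
                SynthParams(
                    field_size=500,
                    branch_rate=rate,
                    anastomosis_probability=0.0,
                    capture_radius=8.0,
                    seed=seed,
                )
            ).junction_count()
            for rate in (0.0, 0.005, 0.02, 0.05)
        ]
        assert counts == sorted(counts)

    def test_total_length_invariant_under_rasterization(self):
        params = SynthParams(field_size=400, seed=3)
        graph = generate_network(params)
        before = graph.total_length()
        for pixel_size in (0.5, 1.0, 2.0):
            rasterize(graph, pixel_size=pixel_size, noise_sd=4.0, seed=1)
        assert graph.total_length() == before

    def test_parameter_validation(self):
        with pytest.raises(ParameterError):
            generate_network(SynthParams(outgrowth_fraction=1.5))
        with pytest.raises(ParameterError):
            generate_network(SynthParams(branch_rate=-1))
        with pytest.raises(ParameterError):
            SynthParams(vessel_radius_range=(3.0, 2.0)).validate()
        with pytest.raises(ParameterError):
            SynthParams(n_layers=2).validate()

    def test_graph_dict_roundtrip(self):
        graph = generate_network(SynthParams(field_size=400, seed=4))
        back = VesselGraph.from_dict(graph.to_dict())
        assert back.total_length() == pytest.approx(graph.total_length())
        assert back.junction_count() == graph.junction_count()
        back.check()


class TestRasterize:
    def test_empty_graph_is_pure_background(self):
        empty = VesselGraph([], [], np.array([100.0, 100.0]), 200.0)
        image = rasterize(empty, pixel_size=1.0, noise_sd=3.0, seed=1)
        assert image.pixels.mean() < 60  # background plus noise only

    def test_single_horizontal_vessel_stroke_count(self):
        # 100 µm vessel, radius 3 -> 7 px tall bar, 101 columns, plus end caps
        image = rasterize(single_vessel_graph(radius=3.0), pixel_size=1.0)
        fg = image.pixels > 100
        assert 101 * 7 <= fg.sum() <= 101 * 7 + 40
        rows_hit = np.unique(np.nonzero(fg)[0])
        assert np.array_equal(rows_hit, np.arange(97, 104))

    def test_stroke_mask_matches_analytic_distance_oracle(self):
        graph = generate_network(
            SynthParams(field_size=250, branch_rate=0.01, n_initial_tips=3, seed=9)
        )
        mask = _stroke_mask(graph, pixel_size=1.0)
        h, w = mask.shape
        yy, xx = np.mgrid[0:h, 0:w]
        px = np.stack([xx, yy], axis=-1).astype(float)
        oracle = np.zeros((h, w), dtype=bool)
        for e in graph.edges:
            pts = np.asarray(e.points)
            for a, b in zip(pts[:-1], pts[1:]):
                v = b - a
                vv = float(v @ v)
                if vv == 0:
                    d2 = ((px - a) ** 2).sum(-1)
                else:
                    t = np.clip(((px - a) @ v) / vv, 0, 1)
                    d2 = ((px - (a + t[..., None] * v)) ** 2).sum(-1)
                oracle |= d2 <= e.radius**2
        assert np.array_equal(mask, oracle)

    def test_noise_free_binarization_recovers_stroke_mask(self):
        graph = single_vessel_graph()
        image = rasterize(graph, pixel_size=1.0, noise_sd=0.0)
        mid = (image.pixels > 100)
        assert np.array_equal(mid, _stroke_mask(graph, 1.0))

    def test_identical_params_give_bit_identical_images(self):
        graph = generate_network(SynthParams(field_size=300, seed=5))
        i1 = rasterize(graph, 1.0, noise_sd=5.0, illumination_gradient=0.1, seed=11)
        i2 = rasterize(graph, 1.0, noise_sd=5.0, illumination_gradient=0.1, seed=11)
        assert np.array_equal(i1.pixels, i2.pixels)

    def test_vanishing_vessel_width_recorded_as_warning(self):
        image = rasterize(single_vessel_graph(radius=0.4), pixel_size=1.0)
        assert any("vanish" in w for w in image.metadata["warnings"])

    def test_16bit_output_range(self):
        image = rasterize(single_vessel_graph(), pixel_size=1.0, bit_depth=16)
        assert image.pixels.dtype == np.uint16
        assert image.pixels.max() > 255


class TestRasterizeStack:
    def test_three_layers_peak_at_stated_depths(self):
        graph = single_vessel_graph()
        stack = rasterize_stack(
            [graph, graph, graph], 1.0, 1.0, (10.0, 30.0, 50.0), layer_sigma_z=2.5
        )
        profile = (stack.pixels > 100).sum(axis=(1, 2))
        for z in (10, 30, 50):
            assert profile[z] == profile.max()
            assert profile[z - 5] < profile[z]
            assert profile[z + 5] < profile[z]

    def test_empty_layer_band_stays_background(self):
        graph = single_vessel_graph()
        empty = VesselGraph([], [], graph.center.copy(), graph.field_size)
        stack = rasterize_stack([graph, empty, graph], 1.0, 1.0, (10.0, 30.0, 50.0))
        assert not (stack.pixels[28:33] > 100).any()

    def test_overlapping_bands_warn(self):
        graph = single_vessel_graph()
        with pytest.warns(UserWarning, match="overlap"):
            rasterize_stack([graph, graph, graph], 1.0, 1.0, (10.0, 14.0, 18.0), layer_sigma_z=2.5)

    def test_nonincreasing_z_positions_rejected(self):
        graph = single_vessel_graph()
        with pytest.raises(ParameterError):
            rasterize_stack([graph, graph, graph], 1.0, 1.0, (30.0, 10.0, 50.0))


def test_presets_cover_both_developmental_conditions():
    assert set(PRESETS) == {"p10", "p60"}
    assert PRESETS["p10"].branch_rate > PRESETS["p60"].branch_rate
    assert PRESETS["p10"].heading_jitter > PRESETS["p60"].heading_jitter
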