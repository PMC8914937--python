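"""Fill paths, pixel mapping, mask rendering, coloring, PNG I/O."""

import numpy as np
import pytest

from imucanvas.layout import CanvasSpec, augmented_layout, baseline_layout
from imucanvas.patterns import PatternVector
from imucanvas.render import (
    CalibrationError,
    CalibrationStats,
    PixelBudget,
    StrokesContext,
    calibrate,
    color_multi_sensor,
    color_neighbor,
    color_simple_spans,
    compose_tiles,
    fill_path,
    map_to_pixels,
    read_image,
    render_bw,
    render_region,
    write_image,
)

AXES = ("sx", "sy", "sz")


def make_pv(axis, osc=0.0, steady=0.0, rmax=0.0, rmin=0.0, idx=0):
    return PatternVector(
        window_index=idx, axis=axis, vp_osc=osc, vp_steady=steady,
        range_max=rmax, range_min=rmin, range_diff=rmax - rmin,
    )


def flat_patterns(values_by_offset=None):
    """Neighborhood where every window has the same pattern values."""
    out = {}
    for axis in AXES:
        five = []
        for off in (-2, -1, 0, 1, 2):
            v = 1.0 if values_by_offset is None else values_by_offset[off]
            five.append(make_pv(axis, osc=v, steady=v, rmax=v, rmin=0.0, idx=off + 2))
        out[axis] = tuple(five)
    return out


def unit_stats():
    """Calibration bounds [0, 1] for every (kind, axis)."""
    kinds = ("osc", "steady", "range_max", "range_diff")
    return CalibrationStats({(k, a): (0.0, 1.0) for k in kinds for a in AXES})


class TestCalibrate:
    def test_min_max_over_set(self):
        pvs = [make_pv("sx", osc=v) for v in (1.0, 2.0, 3.0)]
        stats = calibrate(pvs)
        assert stats.get("osc", "sx") == (1.0, 3.0)

    def test_single_value_is_flat(self):
        stats = calibrate([make_pv("sx", osc=5.0)])
        assert stats.get("osc", "sx") == (5.0, 5.0)
        assert stats.is_flat("osc", "sx")

    def test_matches_scan_oracle(self, rng):
        vals = rng.normal(size=50)
        pvs = [make_pv("sy", steady=v) for v in vals]
        stats = calibrate(pvs)
        assert stats.get("steady", "sy") == (vals.min(), vals.max())

    def test_missing_key_is_calibration_error(self):
        stats = calibrate([make_pv("sx")])
        with pytest.raises(CalibrationError):
            stats.get("osc", "missing_axis")


class TestMapToPixels:
    def test_endpoints(self):
        budget = PixelBudget(3, 400)
        assert map_to_pixels(0.0, (0.0, 10.0), budget) == 3
        assert map_to_pixels(10.0, (0.0, 10.0), budget) == 400

    def test_direct_evaluation(self):
        assert map_to_pixels(2.5, (0.0, 10.0), PixelBudget(0, 400)) == 100

    def test_flat_stats_give_minpx(self):
        assert map_to_pixels(7.0, (5.0, 5.0), PixelBudget(2, 100)) == 2

    def test_out_of_range_values_clamped(self):
        budget = PixelBudget(0, 100)
        assert map_to_pixels(-99.0, (0.0, 1.0), budget) == 0
        assert map_to_pixels(99.0, (0.0, 1.0), budget) == 100

    def test_monotone_and_integer_on_random_sweep(self, rng):
        for _ in range(200):
            lo = float(rng.normal())
            hi = lo + float(rng.uniform(0.1, 5))
            budget = PixelBudget(int(rng.integers(0, 5)), int(rng.integers(5, 400)))
            pas = np.sort(rng.uniform(lo - 1, hi + 1, size=10))
            ms = [map_to_pixels(p, (lo, hi), budget) for p in pas]
            assert all(isinstance(m, int) for m in ms)
            assert all(a <= b for a, b in zip(ms, ms[1:]))
            assert all(budget.minpx <= m <= budget.maxpx for m in ms)


class TestFillPaths:
    def test_ccw_starts_at_center(self):
        path = fill_path("CCW", 3, 3)
        assert path.pixels[0] == (1, 1)
        assert len(set(path.pixels)) == 9

    def test_ccw_even_region_starts_next_to_center(self):
        assert fill_path("CCW", 4, 4).pixels[0] == (2, 2)

    def test_cw_starts_top_left(self):
        for px, py in [(3, 3), (5, 7), (1, 4)]:
            assert fill_path("CW", px, py).pixels[0] == (0, 0)

    def test_diag_traverses_antidiagonals_upward(self):
        path = fill_path("Diag", 3, 3)
        assert path.pixels[:3] == ((0, 0), (1, 0), (0, 1))

    @pytest.mark.parametrize("strategy", ["CCW", "CW", "Diag", "Strk"])
    @pytest.mark.parametrize("px,py", [(1, 1), (3, 5), (7, 7), (12, 12)])
    def test_paths_are_permutations(self, strategy, px, py):
        path = fill_path(strategy, px, py)
        assert sorted(path.pixels) == [(r, c) for r in range(py) for c in range(px)]

    @pytest.mark.parametrize("strategy", ["CCW", "CW"])
    def test_spirals_are_4_adjacent_on_square_regions(self, strategy):
        for n in range(1, 13):
            pix = fill_path(strategy, n, n).pixels
            for (r1, c1), (r2, c2) in zip(pix, pix[1:]):
                assert abs(r1 - r2) + abs(c1 - c2) == 1

    @pytest.mark.parametrize("strategy,line_id", [
        ("Diag", lambda r, c: r + c),
        ("Strk", lambda r, c: r - c),  # family 0: reverse diagonals
    ])
    def test_lines_are_contiguous_and_8_adjacent(self, strategy, line_id):
        pix = fill_path(strategy, 8, 8).pixels
        ids = [line_id(r, c) for r, c in pix]
        # each line appears as one contiguous block of the path
        seen = set()
        for i, d in enumerate(ids):
            if i and d != ids[i - 1]:
                assert d not in seen
                seen.add(ids[i - 1])
            if i and d == ids[i - 1]:
                (r1, c1), (r2, c2) = pix[i - 1], pix[i]
                assert max(abs(r1 - r2), abs(c1 - c2)) == 1

    def test_strokes_start_chains_to_previous_region(self):
        prev = np.zeros((6, 6), dtype=np.uint8)
        prev[3, 5] = 255  # highest marked pixel in the last column is row 3
        ctx = StrokesContext(position_in_triple=1, prev_mask=prev)
        path = fill_path("Strk", 6, 6, ctx)
        assert path.pixels[0] == (3, 0)

    def test_strokes_without_adjacent_marks_start_top_left(self):
        ctx = StrokesContext(position_in_triple=2, prev_mask=np.zeros((6, 6), np.uint8))
        assert fill_path("Strk", 6, 6, ctx).pixels[0] == (0, 0)

    def test_unknown_strategy_raises(self):
        with pytest.raises(ValueError):
            fill_path("Zigzag", 3, 3)


class TestRenderRegion:
    def test_endpoint_masks(self):
        path = fill_path("CW", 4, 4)
        assert render_region(path, 0).sum() == 0
        assert (render_region(path, 16) == 255).all()

    def test_popcount_equals_marked_count(self, rng):
        path = fill_path("CCW", 5, 5)
        for m in rng.integers(0, 26, size=20):
            mask = render_region(path, int(m))
            assert int((mask > 0).sum()) == m

    def test_out_of_budget_raises(self):
        with pytest.raises(ValueError):
            render_region(fill_path("CW", 3, 3), 10)


class TestRenderBW:
    def setup_method(self):
        self.spec = CanvasSpec(Px=4, Py=4, C=1)
        self.layout = baseline_layout()

    def test_constant_signal_gives_minpx_marks_per_region(self):
        # all pattern values 0 with flat calibration -> minpx marks everywhere
        patterns = flat_patterns({off: 0.0 for off in (-2, -1, 0, 1, 2)})
        kinds = ("osc", "steady", "range_max", "range_diff")
        stats = CalibrationStats({(k, a): (0.0, 0.0) for k in kinds for a in AXES})
        img = render_bw(patterns, self.layout, self.spec, stats,
                        budget=PixelBudget(2, 16))
        for r in range(6):
            for c in range(6):
                block = img.pixels[r * 4:(r + 1) * 4, c * 4:(c + 1) * 4]
                assert int((block > 0).sum()) == 2

    def test_rendering_is_deterministic(self):
        patterns = flat_patterns()
        a = render_bw(patterns, self.layout, self.spec, unit_stats())
        b = render_bw(patterns, self.layout, self.spec, unit_stats())
        np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_different_patterns_give_different_images(self):
        a = render_bw(flat_patterns({o: 0.25 for o in (-2, -1, 0, 1, 2)}),
                      self.layout, self.spec, unit_stats())
        b = render_bw(flat_patterns({o: 0.75 for o in (-2, -1, 0, 1, 2)}),
                      self.layout, self.spec, unit_stats())
        assert (a.pixels != b.pixels).any()

    def test_span_values_average_their_two_windows(self):
        # u = mean(p[-2], p[-1]) = 0.5, w = 1.0, v = mean(0, 0) = 0
        patterns = flat_patterns({-2: 1.0, -1: 0.0, 0: 1.0, 1: 0.0, 2: 0.0})
        img = render_bw(patterns, self.layout, self.spec, unit_stats())
        px = self.spec.pixels_per_region
        u_block = img.pixels[0:4, 0:4]    # (osc, sx, u)
        w_block = img.pixels[0:4, 4:8]    # (osc, sx, w)
        v_block = img.pixels[0:4, 8:12]   # (osc, sx, v)
        assert int((u_block > 0).sum()) == px // 2
        assert int((w_block > 0).sum()) == px
        assert int((v_block > 0).sum()) == 0


class TestColorNeighbor:
    def setup_method(self):
        self.spec = CanvasSpec(Px=4, Py=4, C=3)
        self.layout = baseline_layout()

    def test_identical_windows_give_grayscale(self):
        img = color_neighbor(flat_patterns(), self.layout, self.spec, unit_stats())
        r, g, b = img.pixels[..., 0], img.pixels[..., 1], img.pixels[..., 2]
        np.testing.assert_array_equal(r, g)
        np.testing.assert_array_equal(g, b)

    def test_zero_values_are_black_marked_white_unmarked(self):
        patterns = flat_patterns({off: 0.0 for off in (-2, -1, 0, 1, 2)})
        # make the mask nontrivial: minpx=5 marked pixels per region
        img = color_neighbor(patterns, self.layout, self.spec, unit_stats(),
                             budget=PixelBudget(5, 16))
        mask = render_bw(patterns, self.layout, self.spec, unit_stats(),
                         budget=PixelBudget(5, 16)).pixels > 0
        assert (img.pixels[mask] == 0).all()
        assert (img.pixels[~mask] == 255).all()

    def test_channel_values_match_hand_formulas(self):
        values = {-2: 0.2, -1: 0.4, 0: 0.6, 1: 0.8, 2: 1.0}
        patterns = flat_patterns(values)
        img = color_neighbor(patterns, self.layout, self.spec, unit_stats())
        mask = render_bw(patterns, self.layout, self.spec, unit_stats()).pixels > 0
        p = {off: int(np.floor(255 * v)) for off, v in values.items()}
        expected_marked = (p[-2], p[0], p[2])
        expected_unmarked = (255 - p[-1], 255 - p[0], 255 - p[1])
        for ch in range(3):
            chan = img.pixels[..., ch]
            assert (chan[mask] == expected_marked[ch]).all()
            assert (chan[~mask] == expected_unmarked[ch]).all()

    def test_all_channels_share_the_mask(self):
        patterns = flat_patterns({-2: 0.1, -1: 0.9, 0: 0.5, 1: 0.3, 2: 0.7})
        img = color_neighbor(patterns, self.layout, self.spec, unit_stats())
        mask = render_bw(patterns, self.layout, self.spec, unit_stats()).pixels > 0
        # marked pixels take the "0 + p'" value, unmarked the "255 - p'" value,
        # uniformly within each region and channel
        for ch in range(3):
            chan = img.pixels[..., ch]
            assert len(np.unique(chan[mask])) <= 36
            assert len(np.unique(chan[~mask])) <= 36


class TestColorSimpleSpans:
    def test_channels_are_span_restricted_renders(self):
        spec = CanvasSpec(Px=4, Py=4, C=3)
        layout = baseline_layout()
        patterns = flat_patterns({-2: 0.6, -1: 0.6, 0: 1.0, 1: 0.3, 2: 0.3})
        img = color_simple_spans(patterns, layout, spec, unit_stats())
        full = render_bw(patterns, layout, spec, unit_stats()).pixels
        for ch, span in enumerate(("u", "w", "v")):
            expected = np.zeros_like(full)
            for (r, c), (_k, _a, s) in layout.mapping.items():
                if s == span:
                    sl = np.s_[r * 4:(r + 1) * 4, c * 4:(c + 1) * 4]
                    expected[sl] = full[sl]
            np.testing.assert_array_equal(img.pixels[..., ch], expected)


class TestColorMultiSensor:
    def test_two_sensors_fill_r_and_g(self):
        spec = CanvasSpec(Px=4, Py=4, C=3)
        layout = baseline_layout()
        pa = flat_patterns({o: 0.8 for o in (-2, -1, 0, 1, 2)})
        pb = flat_patterns({o: 0.2 for o in (-2, -1, 0, 1, 2)})
        stats = {"acc": unit_stats(), "gyro": unit_stats()}
        img = color_multi_sensor({"acc": pa, "gyro": pb}, layout, spec, stats)
        np.testing.assert_array_equal(
            img.pixels[..., 0], render_bw(pa, layout, spec, unit_stats()).pixels
        )
        np.testing.assert_array_equal(
            img.pixels[..., 1], render_bw(pb, layout, spec, unit_stats()).pixels
        )
        assert (img.pixels[..., 2] == 0).all()

    def test_more_than_three_sensors_rejected(self):
        spec = CanvasSpec(Px=4, Py=4, C=3)
        neighs = {f"s{i}": flat_patterns() for i in range(4)}
        with pytest.raises(ValueError, match="augmented"):
            color_multi_sensor(neighs, baseline_layout(), spec,
                               {k: unit_stats() for k in neighs})


class TestComposeTiles:
    def test_strip_and_blank_slots(self):
        spec = CanvasSpec(Px=2, Py=2, C=1)
        layout = baseline_layout()
        imgs = [render_bw(flat_patterns(), layout, spec, unit_stats())
                for _ in range(3)]
        aug = augmented_layout(["a", "b", "c"], spec, tiles_x=2)
        big = compose_tiles(imgs, aug)
        assert big.pixels.shape == (24, 24)  # 2x2 tiles of 12x12
        # 4th slot is blank
        assert (big.pixels[12:, 12:] == 0).all()
        np.testing.assert_array_equal(big.pixels[:12, :12], imgs[0].pixels)


class TestPngIO:
    def test_roundtrip_pixels_and_provenance(self, tmp_path):
        spec = CanvasSpec(Px=4, Py=4, C=3)
        img = color_neighbor(flat_patterns(), baseline_layout(), spec, unit_stats(),
                             provenance={"config_hash": "abc123"})
        path = write_image(img, tmp_path / "w.png")
        back = read_image(path)
        np.testing.assert_array_equal(back.pixels, img.pixels)
        assert back.provenance["config_hash"] == "abc123"
        assert back.provenance["layout"] == "baseline"

    def test_bytes_are_stable_across_writes(self, tmp_path):
        spec = CanvasSpec(Px=4, Py=4, C=1)
        img = render_bw(flat_patterns(), baseline_layout(), spec, unit_stats())
        p1 = write_image(img, tmp_path / "a.png")
        p2 = write_image(img, tmp_path / "b.png")
        assert p1.read_bytes() == p2.read_bytes()
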