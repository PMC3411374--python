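import numpy as np
import pytest

import _oracles
from dendrotrace.errors import BoundsError, ParameterError
from dendrotrace.preprocess import (
    AUTO,
    EditStroke,
    apply_filter,
    draw_edit,
    otsu_threshold,
    threshold_global,
    threshold_local,
    white_halo,
)
from dendrotrace.raster_io import Rect


class TestGlobalThreshold:
    def test_all_dark_is_foreground(self):
        assert threshold_global(np.zeros((4, 4), dtype=np.uint8), 128).all()

    def test_all_light_is_background(self):
        assert not threshold_global(np.full((4, 4), 255, dtype=np.uint8), 128).any()

    def test_auto_separates_bimodal_image(self):
        # 40% of pixels at 20, 60% at 220: Otsu must cut between the modes
        img = np.full((10, 10), 220, dtype=np.uint8)
        img[:4] = 20
        binary = threshold_global(img, AUTO)
        assert binary[img == 20].all()
        assert not binary[img == 220].any()

    def test_auto_equals_brute_force_scan(self, rng):
        for _ in range(30):
            img = rng.integers(0, 256, size=(16, 16), dtype=np.uint8)
            assert otsu_threshold(img) == _oracles.otsu_brute_force(img)

    def test_constant_image_all_background(self):
        img = np.full((8, 8), 77, dtype=np.uint8)
        assert not threshold_global(img, AUTO).any()


class TestLocalThreshold:
    def test_constant_image_yields_no_foreground(self):
        img = np.full((6, 6), 100, dtype=np.uint8)
        assert not threshold_local(img, 3, 0).any()

    def test_single_dark_pixel_detected(self):
        img = np.full((5, 5), 255, dtype=np.uint8)
        img[2, 2] = 0
        out = threshold_local(img, 3, 0)
        assert out[2, 2]
        # its neighbors sit above their window means
        assert out.sum() == 1

    def test_huge_offset_suppresses_everything(self, rng):
        img = rng.integers(0, 256, size=(8, 8), dtype=np.uint8)
        assert not threshold_local(img, 3, 255).any()

    def test_even_window_rejected(self):
        with pytest.raises(ParameterError):
            threshold_local(np.zeros((4, 4), dtype=np.uint8), 4)


class TestFilters:
    def test_invert_is_involution(self, rng):
        img = rng.integers(0, 256, size=(9, 9), dtype=np.uint8)
        assert np.array_equal(apply_filter(apply_filter(img, "invert"), "invert"), img)

    def test_minimum_filter_dilates_dark(self):
        img = np.full((7, 7), 255, dtype=np.uint8)
        img[3, 3] = 0
        out = apply_filter(img, "minimum", 3)
        assert (out[2:5, 2:5] == 0).all()
        assert (out == 0).sum() == 9

    def test_histogram_stretch_endpoints(self):
        img = np.array([[50, 100], [50, 100]], dtype=np.uint8)
        out = apply_filter(img, "histogram_stretch")
        assert set(np.unique(out)) == {0, 255}

    @pytest.mark.parametrize(
        "kind,param",
        [("median", 3), ("minimum", 3), ("blur", 3), ("sharpen", 3),
         ("lighten", 10), ("darken", 10), ("invert", None), ("histogram_stretch", None)],
    )
    def test_filters_preserve_shape(self, rng, kind, param):
        img = rng.integers(0, 256, size=(11, 13), dtype=np.uint8)
        assert apply_filter(img, kind, param).shape == img.shape

    def test_unknown_kind_rejected(self):
        with pytest.raises(ParameterError):
            apply_filter(np.zeros((3, 3), dtype=np.uint8), "emboss")


class TestDrawEdit:
    def test_rubber_on_empty_image_is_noop(self):
        img = np.zeros((6, 6), dtype=bool)
        stroke = EditStroke(kind="rubber", points=[(1, 1), (4, 4)], radius=1)
        assert not draw_edit(img, stroke).any()

    def test_horizontal_line_rasterizes_exactly(self):
        img = np.zeros((3, 6), dtype=bool)
        out = draw_edit(img, EditStroke(kind="line", points=[(0, 0), (0, 4)]))
        assert out.sum() == 5
        assert out[0, 0:5].all()

    def test_fill_flips_exactly_one_region(self):
        img = np.zeros((7, 7), dtype=bool)
        img[:, 3] = True  # wall splits background in two
        out = draw_edit(img, EditStroke(kind="fill", points=[(0, 0)]))
        assert out[:, :3].all()
        assert out[:, 3].all()
        assert not out[:, 4:].any()

    def test_fill_region_matches_bfs_oracle(self, rng):
        img = _oracles.random_blobs(rng, shape=(24, 24))
        seed = (0, 0) if not img[0, 0] else (0, int(np.argwhere(~img[0])[0][0]))
        out = draw_edit(img, EditStroke(kind="fill", points=[seed]))
        # oracle: 4-connected BFS on the seed's state
        h, w = img.shape
        state = img[seed]
        seen = {seed}
        queue = [seed]
        while queue:
            r, c = queue.pop(0)
            for rr, cc in [(r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)]:
                if 0 <= rr < h and 0 <= cc < w and img[rr, cc] == state and (rr, cc) not in seen:
                    seen.add((rr, cc))
                    queue.append((rr, cc))
        expected = img.copy()
        for p in seen:
            expected[p] = not state
        assert np.array_equal(out, expected)

    def test_point_outside_image_rejected(self):
        img = np.zeros((4, 4), dtype=bool)
        with pytest.raises(BoundsError):
            draw_edit(img, EditStroke(kind="pencil", points=[(5, 1)]))


class TestWhiteHalo:
    def test_isolated_dot_keeps_itself_clears_ring(self):
        img = np.zeros((9, 9), dtype=bool)
        img[4, 4] = True
        img[4, 6] = True  # a neighbor glyph inside the halo distance? no: distance 2
        out = white_halo(img, Rect(2, 2, 5, 5), thickness=1)
        assert out[4, 4]
        assert not out[3:6, 3:6].sum() - 1  # only the dot survives in its ring
        assert out[4, 6]  # outside chessboard distance 1 of the dot

    def test_region_without_foreground_unchanged(self):
        img = np.zeros((8, 8), dtype=bool)
        img[0, 0] = True
        out = white_halo(img, Rect(3, 3, 4, 4), thickness=2)
        assert np.array_equal(out, img)

    def test_component_crossing_boundary_produces_no_halo(self):
        img = np.zeros((8, 8), dtype=bool)
        img[4, :] = True  # line crossing the region
        out = white_halo(img, Rect(2, 2, 4, 4), thickness=1)
        assert np.array_equal(out, img)

    def test_halo_detaches_glyph_from_passing_line(self):
        # a tree line passes two pixels below a glyph: a thickness-2 halo
        # cuts the line where it comes close, leaving the rest intact
        img = np.zeros((9, 12), dtype=bool)
        img[5, :] = True  # tree line, crosses the region boundary
        img[3, 5:7] = True  # glyph, entirely inside the region
        out = white_halo(img, Rect(1, 2, 5, 8), thickness=2)
        assert out[3, 5] and out[3, 6]  # glyph keeps its own pixels
        assert not out[5, 3:9].any()  # line cut inside the halo
        assert out[5, 2] and out[5, 9]  # beyond chessboard distance 2
        assert out[5, 0] and out[5, 11]  # outside the region untouched

    def test_inner_components_keep_their_own_pixels(self, rng):
        img = _oracles.random_blobs(rng, shape=(32, 32), density=0.2)
        region = Rect(4, 4, 24, 24)
        out = white_halo(img, region, thickness=1)
        # pixels may only be cleared, never set
        assert not (out & ~img).any()
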